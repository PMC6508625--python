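"""Per-read quality and composition statistics.

The mean q-score of a read is defined in the error-probability domain:
each Phred+33 character encodes q_i = codepoint - 33, the per-base error
probability is p_i = 10**(-q_i/10), and the read-level score is

    Q = -10 * log10( mean_i p_i )

This matches the convention of the basecaller's stored ``mean_qscore``
attribute, so scores computed from a quality string and scores read from
file metadata live on the same scale. Note Q is *not* the arithmetic mean
of the q_i: low-quality bases dominate, so Q <= mean(q_i) always.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

PHRED_OFFSET = 33

#: Sentinel used in the metadata table when GC content was not computed.
GC_NOT_COMPUTED = float("nan")


def mean_qscore(quality_string: str) -> float:
    """Error-probability-domain mean Phred score of a quality string.

    Parameters
    ----------
    quality_string : str
        Sanger (Phred+33) encoded per-base qualities; non-empty.

    Returns
    -------
    float
        ``-10*log10(mean(10**(-q/10)))`` over per-base scores ``q``.

    Raises
    ------
    DomainError
        On an empty string or a character below the Phred+33 range.
    """
    if not quality_string:
        raise DomainError("mean_qscore of an empty quality string is undefined")
    codes = np.frombuffer(quality_string.encode("ascii"), dtype=np.uint8)
    if codes.min() < PHRED_OFFSET:
        raise DomainError(
            f"quality character below Phred+33 range: {chr(codes.min())!r}"
        )
    q = codes.astype(np.float64) - PHRED_OFFSET
    return float(-10.0 * np.log10(np.mean(np.power(10.0, -q / 10.0))))


def phred_to_string(qs) -> str:
    """Encode an iterable of integer per-base q-scores as Phred+33."""
    return "".join(chr(int(q) + PHRED_OFFSET) for q in qs)


def gc_content(sequence: str) -> float:
    """GC fraction of a nucleotide sequence.

    G and C (case-insensitive, plus S, the IUPAC strong code, is *not*
    counted — only literal G/C count in the numerator) over the full
    length; ambiguous bases count in the denominator only.

    Raises
    ------
    DomainError
        On an empty sequence.
    """
    if not sequence:
        raise DomainError("GC content of an empty sequence is undefined")
    upper = sequence.upper()
    return (upper.count("G") + upper.count("C")) / len(upper)
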