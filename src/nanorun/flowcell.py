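"""Physical flow-cell geometry and per-position activity.

A MinION flow cell exposes 512 channels; each channel can switch among 4
physical pore wells (muxes), addressing 2048 pores in total. Channels
are laid out on a 16x32 grid, loaded from a packaged, version-stamped
layout table built from 64-channel blocks. For mux maps every channel
cell subdivides into a 2x2 block, giving a 32x64 grid.

Exact cell-for-cell fidelity to the vendor's physical diagram is not
claimed; the contract is the grid shape, the injectivity of the maps,
and conservation of totals, which is what positional diagnostics need.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DomainError

N_CHANNELS = 512
N_MUXES = 4
CHANNEL_GRID_SHAPE = (16, 32)
MUX_GRID_SHAPE = (32, 64)

_LAYOUT_RESOURCE = "flowcell_layout_minion_v1.tsv"


@lru_cache(maxsize=1)
def _layout() -> dict[int, tuple[int, int]]:
    with resources.files("nanorun.data").joinpath(_LAYOUT_RESOURCE).open() as handle:
        frame = pd.read_csv(handle, sep="\t", comment="#")
    return {
        int(row.channel): (int(row.row), int(row.col))
        for row in frame.itertuples(index=False)
    }


def channel_to_coord(channel: int) -> tuple[int, int]:
    """Grid position (row, col) of a channel on the 16x32 layout."""
    if not 1 <= channel <= N_CHANNELS:
        raise DomainError(f"channel must be in 1..{N_CHANNELS}, got {channel}")
    return _layout()[int(channel)]


def mux_to_coord(channel: int, mux: int) -> tuple[int, int]:
    """Grid position of one pore well: channel cell split into a 2x2 block."""
    if not 1 <= mux <= N_MUXES:
        raise DomainError(f"mux must be in 1..{N_MUXES}, got {mux}")
    row, col = channel_to_coord(channel)
    return 2 * row + (mux - 1) // 2, 2 * col + (mux - 1) % 2


@dataclass
class FlowcellMatrix:
    """Aggregated activity on the physical grid.

    ``mask`` is True where a position saw no reads (rendered grey in
    heatmaps). The sum of unmasked values equals the run total of the
    chosen metric over the reads that map onto the grid.
    """

    grid: np.ndarray
    mask: np.ndarray
    per: str  # "channel" | "mux"
    metric: str  # "bases" | "reads"


def activity_matrix(
    table: pd.DataFrame, per: str = "channel", metric: str = "bases"
) -> FlowcellMatrix:
    """Sum reads or bases onto channel or mux grid positions.

    Reads with unknown mux (``mux == 0``) are excluded from mux maps;
    they always contribute to channel maps.
    """
    if per not in ("channel", "mux"):
        raise DomainError(f"per must be 'channel' or 'mux', got {per!r}")
    if metric not in ("bases", "reads"):
        raise DomainError(f"metric must be 'bases' or 'reads', got {metric!r}")
    shape = CHANNEL_GRID_SHAPE if per == "channel" else MUX_GRID_SHAPE
    grid = np.zeros(shape, dtype=np.float64)
    counts = np.zeros(shape, dtype=np.int64)
    for channel, mux, length in zip(
        table["channel"].to_numpy(),
        table["mux"].to_numpy(),
        table["length"].to_numpy(),
    ):
        if per == "mux":
            if mux < 1:
                continue
            coord = mux_to_coord(int(channel), int(mux))
        else:
            coord = channel_to_coord(int(channel))
        grid[coord] += length if metric == "bases" else 1
        counts[coord] += 1
    return FlowcellMatrix(grid=grid, mask=counts == 0, per=per, metric=metric)
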