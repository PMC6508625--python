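import shutil

import pytest

from nanorun.simulate import RunSpec, generate_run


@pytest.fixture(scope="session")
def run_factory(tmp_path_factory):
    """Session-cached synthetic runs: ``make(flavor, n_reads=..., seed=...)``.

    Returns ``(out_path, ground_truth)``. Tests that mutate files must
    copy the tree first (see ``copy_run``).
    """
    cache = {}

    def make(flavor, n_reads=40, seed=7, **kwargs):
        key = (flavor, n_reads, seed, tuple(sorted(kwargs.items())))
        if key not in cache:
            out = tmp_path_factory.mktemp(f"run_{flavor}_{n_reads}_{seed}")
            cache[key] = generate_run(
                RunSpec(n_reads=n_reads, seed=seed, **kwargs), flavor, out
            )
        return cache[key]

    return make


@pytest.fixture
def copy_run(tmp_path):
    """Copy a generated run tree into a writable per-test directory."""

    def copy(src):
        dest = tmp_path / "mutable_run"
        shutil.copytree(src, dest)
        return dest

    return copy


def passed_truth(truth):
    """Ground-truth rows for passed reads, in canonical table order."""
    sub = truth[truth["passed"]]
    return sub.sort_values(["start_time", "read_id"]).reset_index(drop=True)
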