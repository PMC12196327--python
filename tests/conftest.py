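"""Shared fixtures: a scaled-down synthetic experiment for fast
integration tests.  The full-scale study conditions live only in the
acceptance suite."""

from __future__ import annotations

import pytest

from mirforge.pipeline import simulate_and_run
from mirforge.synthetic_data import SimConfig


SMALL_KW = dict(
    seed=5,
    n_scaffolds=2,
    scaffold_len=30_000,
    n_true_mirnas=12,
    n_decoys=6,
    n_mirna_reads=30_000,
    n_background_reads=1_500,
    n_decoy_reads_each=120,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(**SMALL_KW)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_cfg):
    """(truth, report, evaluation, outdir) of a small end-to-end run."""
    outdir = tmp_path_factory.mktemp("small_run")
    truth, report, ev = simulate_and_run(small_cfg, outdir)
    return truth, report, ev, outdir
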