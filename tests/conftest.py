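"""Shared fixtures: the canonical seeded dataset and one full pipeline run."""

import pytest

from acetylscape.pipeline import run, validate_config
from acetylscape.simulate import SimConfig, generate_genome, simulate_counts, simulate_dataset

CANONICAL_SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic experiment used by the recovery tests."""
    return simulate_dataset(SimConfig(seed=CANONICAL_SEED))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default dataset; returns (report, outdir)."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = validate_config({"mode": "simulate", "seed": CANONICAL_SEED})
    report = run(cfg, outdir)
    return report, outdir


@pytest.fixture(scope="session")
def null_experiment():
    """2,000 genes simulated with every planted effect set to zero.

    Returns (rna_counts, chip_counts, truth) for calibration checks.
    """
    zero = {k: 0.0 for k in SimConfig(seed=0).effect_log2fc}
    cfg = SimConfig(seed=11, n_genes=2000, effect_log2fc=zero)
    genes, template, tg, tpk = generate_genome(cfg)
    rna, chip, truth, _ = simulate_counts(cfg, genes, template, tg, tpk)
    return rna, chip, truth
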