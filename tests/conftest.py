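import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from trendsig.synthdata import SynthExpressionConfig, default_planted
from trendsig.pipeline import simulate_bundle


def small_expr_config(seed: int = 7) -> SynthExpressionConfig:
    return SynthExpressionConfig(
        n_norm=12, n_dtc=12, n_atc=10, n_studies=3, n_genes=150,
        planted=default_planted(n_per_cell=3, n_genes=150),
        within_sd=0.4, batch_sd=0.2, seed=seed)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A compact simulated input bundle shared by I/O and CLI tests."""
    out = tmp_path_factory.mktemp("bundle")
    paths = simulate_bundle(
        out, seed=11, expr_config=small_expr_config(seed=11),
        n_module_genes=6, n_background_genes=30, n_model_genes=12,
        n_chip_targets=6, reproducible_frac=0.5, n_noise_peaks=8,
        n_core=10, n_line_specific=8, n_null=12, n_pairs=4)
    return paths
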