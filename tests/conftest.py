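import pandas as pd
import pytest

from ctdnamon.config import PanelDefinition, ThresholdConfig
from ctdnamon.synthetic import SimulationConfig, generate_cohort


def make_variants(rows):
    """Build a variant table from (chrom, pos, ref, alt, gene, effect, af) tuples."""
    recs = []
    for chrom, pos, ref, alt, gene, effect, af in rows:
        recs.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "gene": gene, "effect": effect, "af": af,
                "alt_reads": int(round(af * 3000)), "depth": 3000,
            }
        )
    cols = ["chrom", "pos", "ref", "alt", "gene", "effect", "af", "alt_reads", "depth"]
    return pd.DataFrame(recs, columns=cols)


@pytest.fixture
def thresholds():
    return ThresholdConfig()


@pytest.fixture
def panel():
    return PanelDefinition(coding_footprint_mb=1.2)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient noisy cohort shared across tests (fixed seed)."""
    return generate_cohort(SimulationConfig(n_patients=6, seed=11))


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Twelve-patient noise-free cohort for exact-recovery checks."""
    return generate_cohort(SimulationConfig(n_patients=12, seed=7).zero_noise())
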