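import numpy as np
import pandas as pd
import pytest

from oculoconcord.core import AnalysisConfig, BetaMatrix, ProbeAnnotation, SampleSheet
from oculoconcord.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def acfg():
    return AnalysisConfig(rng_seed=7)


@pytest.fixture(scope="session")
def default_sim():
    """One draw from the default study design (8 donors x 4 tissues)."""
    return simulate_dataset(SimConfig(n_probes=2000, seed=11))


@pytest.fixture(scope="session")
def quiet_sim():
    """No effects, no noise: every probe constant across all samples."""
    return simulate_dataset(
        SimConfig(n_probes=200, f_tissue=0.0, f_individual=0.0, noise_sd=0.0, seed=5)
    )


def make_beta(values, probe_ids=None, sample_ids=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:04d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))


def make_sheet(sample_ids, donors, tissues, chips=None) -> SampleSheet:
    chips = chips or ["chip1"] * len(sample_ids)
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "donor_id": donors,
                "tissue": tissues,
                "chip": chips,
                "age_at_death": [60.0] * len(sample_ids),
                "cause_of_death": ["cardiac"] * len(sample_ids),
                "preservation_interval": [6.0] * len(sample_ids),
            }
        )
    )


def make_annotation(
    probe_ids,
    feature="Body",
    island="OpenSea",
    chromosome="1",
    cross_reactive=False,
    snp=False,
) -> ProbeAnnotation:
    n = len(probe_ids)

    def expand(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    return ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "chromosome": expand(chromosome),
                "feature_class": expand(feature),
                "island_relation": expand(island),
                "cross_reactive": expand(cross_reactive),
                "snp_flag": expand(snp),
            }
        )
    )
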