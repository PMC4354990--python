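import numpy as np
import pandas as pd
import pytest

from trioepi.simulate import (
    DMRPlan,
    EKPlan,
    ScatterPlan,
    SimConfig,
    simulate_cohort,
)


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A fast, reduced-scale cohort (8 trios, 4,000 probes) used where the
    full study scale is not needed."""
    cfg = SimConfig(
        n_patients=8,
        n_probes=4000,
        frac_group1=5 / 8,
        kr_dmrs=DMRPlan(count=6, hyper_fraction=0.5),
        wt_dmrs=DMRPlan(count=6, hyper_fraction=0.5),
        kr_scatter=ScatterPlan(count=150, hyper_fraction=0.5),
        wt_scatter=ScatterPlan(count=150, hyper_fraction=0.5),
        ek_mvps=EKPlan(count=40),
        n_bilateral=3,
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """One full-scale cohort (20 trios x 20,000 probes) shared across tests."""
    return simulate_cohort(SimConfig(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def trio_sheet(cohort) -> pd.DataFrame:
    return cohort.samples[cohort.samples["tissue"].isin(("NK", "NR", "WT"))]


def truth_subgroup_patients(cohort, subgroup: str) -> list[str]:
    return sorted({
        v["patient"] for v in cohort.truth["samples"].values() if v["subgroup"] == subgroup
    })


def topology_labels(cohort, sample_ids) -> list[int]:
    """Ground-truth three-cluster labels: NK / (NR + group-2 WT) / group-1 WT."""
    out = []
    for s in sample_ids:
        rec = cohort.truth["samples"][s]
        if rec["tissue"] == "NK":
            out.append(0)
        elif rec["tissue"] == "WT" and rec["subgroup"] == "group1":
            out.append(2)
        else:
            out.append(1)
    return out
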