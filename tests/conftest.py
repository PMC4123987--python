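import numpy as np
import pandas as pd
import pytest

from methclonal.io import BetaMatrix, SampleAnnotation
from methclonal.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_2609)


@pytest.fixture(scope="session")
def fixtures():
    from methclonal.io import load_fixture_tables

    return load_fixture_tables()


@pytest.fixture(scope="session")
def ptam_cohort():
    """Small axillary-metastasis-like cohort with a progression signature."""
    cfg = CohortConfig(
        n_probes=1_200,
        n_pairs=10,
        cohort="PT/AM",
        clonal_fraction=1.0,
        progression_probes=80,
        progression_effect=0.18,
        n_missing_probes=0,
        seed=11,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def ptlr_cohort():
    """Mixed clonal/independent local-recurrence-like cohort with normals."""
    cfg = CohortConfig(
        n_probes=2_000,
        n_pairs=17,
        cohort="PT/LR",
        clonal_fraction=0.5,
        n_normals=6,
        n_missing_probes=5,
        seed=13,
    )
    return cfg, generate_cohort(cfg)


def tiny_beta(values, probe_ids=None, sample_ids=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))


def duo_annotation(pair_samples, cohort="PT/LR"):
    """Annotation for a list of (pt_sample, rec_sample) tuples."""
    from methclonal.io import RECURRENCE_ROLE

    rec_role = RECURRENCE_ROLE[cohort]
    rows = []
    for i, (pt, rec) in enumerate(pair_samples):
        rows.append((pt, f"P{i}", "PT", cohort))
        rows.append((rec, f"P{i}", rec_role, cohort))
    return SampleAnnotation(
        pd.DataFrame(rows, columns=["sample_id", "pair_id", "role", "cohort"])
    )
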