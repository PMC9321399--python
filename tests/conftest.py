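import numpy as np
import pandas as pd
import pytest

from npxpred import _solver
from npxpred.ingest import ClinicalTable, NpxDataset


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    # compile the coordinate-descent kernel once, up front
    _solver.warmup()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_dataset(values, panels=None, lod=None, qc=None, sample_ids=None):
    """Small NpxDataset builder for hand-constructed fixtures."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if panels is None:
        panels = ["A"] * p
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    protein_ids = [f"prot{j + 1}:{panels[j]}" for j in range(p)]
    if lod is None:
        lod = np.full(p, -100.0)
    qc_flag = pd.DataFrame(
        False, index=sample_ids, columns=sorted(set(panels))
    )
    if qc:
        for sample, panel in qc:
            qc_flag.loc[sample, panel] = True
    return NpxDataset(
        sample_ids=sample_ids,
        protein_ids=protein_ids,
        values=values,
        lod=np.asarray(lod, dtype=float),
        panels=list(panels),
        qc_flag=qc_flag,
    )


def make_clinical(n, rng=None, response=None, **overrides):
    rng = rng or np.random.default_rng(0)
    frame = pd.DataFrame(
        {
            "patient_id": [f"s{i + 1}" for i in range(n)],
            "gender": rng.integers(0, 2, n),
            "age": rng.normal(60, 10, n).round(1),
            "disease_duration": np.abs(rng.normal(9, 8, n)).round(1),
            "baseline_das": np.clip(rng.normal(5.4, 1.3, n), 0, 10).round(2),
            "delta_das": rng.normal(-2, 1.5, n).round(2),
            "response": response
            if response is not None
            else rng.integers(0, 2, n),
        }
    )
    for key, val in overrides.items():
        frame[key] = val
    return ClinicalTable(frame)


@pytest.fixture(scope="session")
def paper_cohort():
    from npxpred.synth import make_paper_like_cohort

    return make_paper_like_cohort(seed=0)
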