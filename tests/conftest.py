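import logging

import numpy as np
import pytest

from stagetraj import synthetic as syn
from stagetraj.types import RunConfig

logging.getLogger("stagetraj").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def parc():
    """Full synthetic 246-label parcellation (123 left / 123 right)."""
    return syn.make_parcellation(seed=0)


@pytest.fixture(scope="session")
def ground_truth(parc):
    return syn.default_ground_truth(parc, seed=11)


@pytest.fixture(scope="session")
def reference_cohort(parc, ground_truth):
    """The reference study cohort: 90 patients (~15/window at L=5), 120
    controls, parcel mode, planted 5-stage structure."""
    records, gt = syn.make_cohort(ground_truth, 90, 120, parc)
    patients = [r for r in records if r.is_patient]
    controls = [r for r in records if not r.is_patient]
    return records, patients, controls, gt


@pytest.fixture()
def cfg():
    return RunConfig(n_perm=199, n_boot=200, rng_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def subject_table(tmp_path, n_patients=86, n_controls=120, bad_control_dur=False,
                  drop_col=None, dup_id=False):
    """Write a cohort CSV mimicking a real subject table."""
    import pandas as pd

    g = np.random.default_rng(5)
    rows = []
    for i in range(n_patients):
        rows.append(dict(id=f"p{i}", group="patient", age=40 + g.normal(0, 10),
                         sex="M" if g.random() < 0.7 else "F",
                         tiv=1500 + g.normal(0, 100), motion=0.1,
                         duration_years=float(g.uniform(0, 30)),
                         panss_positive=13, panss_negative=20, panss_general=28,
                         panss_total=62, drug_equiv=330.0,
                         gm_volume=700.0, wm_volume=500.0, csf_volume=250.0))
    for i in range(n_controls):
        rows.append(dict(id=f"c{i}", group="control", age=38 + g.normal(0, 10),
                         sex="M", tiv=1500.0, motion=0.08,
                         duration_years=(3.0 if bad_control_dur and i == 0
                                         else None)))
    if dup_id and rows:
        rows[1]["id"] = rows[0]["id"]
    cols = ["id", "group", "age", "sex", "tiv", "motion", "duration_years"]
    df = pd.DataFrame(rows, columns=None if rows else cols)
    if drop_col:
        df = df.drop(columns=[drop_col])
    path = tmp_path / "subjects.csv"
    df.to_csv(path, index=False)
    return path
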