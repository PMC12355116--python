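"""Shared fixtures: synthetic datasets at several scales.

Everything is generated in memory at test time; nothing is read from disk.
"""

from __future__ import annotations

import pandas as pd
import pytest

import gabadose as g
from gabadose.simulate import build_tables


def _simulate(n, seed, **overrides):
    cfg = g.SimulationConfig(n_patients=n, seed=seed, **overrides)
    profiles = g.generate_population(cfg)
    disp, profiles = g.generate_dispensings(profiles, cfg, with_profiles=True)
    tables = build_tables(profiles, cfg)
    tables["dispensings"] = disp
    tables["truth"] = g.write_truth_table(profiles)
    tables["config"] = cfg
    return tables


@pytest.fixture(scope="session")
def sim_large():
    """Calibration-scale dataset (n=50,000, default study conditions)."""
    return _simulate(50_000, seed=11)


@pytest.fixture(scope="session")
def sim_small():
    """Small dataset for fast structural tests."""
    return _simulate(4_000, seed=7)


@pytest.fixture(scope="session")
def sim_clean():
    """Edge cases off: every generated patient is a true new user."""
    return _simulate(
        3_000,
        seed=5,
        edge_case_fractions={
            "prevalent": 0.0,
            "occasional": 0.0,
            "minor": 0.0,
            "missing_demographics": 0.0,
            "enrolment_gap": 0.0,
        },
    )


@pytest.fixture(scope="session")
def cohort_small(sim_small):
    """Pregabalin cohort with covariates built from the small dataset."""
    t = sim_small
    entries, attrition = g.select_new_users(
        t["dispensings"], t["patients"], t["enrolment"], t["deaths"],
        g.EligibilityConfig(index_drug="pregabalin"),
    )
    entries = g.baseline_covariates(entries, t["patients"], t["dispensings"])
    return {"entries": entries, "attrition": attrition, **t}


def make_dispensings(rows):
    """Tiny dispensing table from (patient_id, drug, date, mg[, presc]) rows."""
    recs = []
    for r in rows:
        pid, drug, date, mg = r[:4]
        presc = r[4] if len(r) > 4 else 1
        recs.append(
            {
                "patient_id": pid,
                "drug": drug,
                "date": pd.Timestamp(date),
                "quantity_mg": float(mg),
                "prescriber_id": presc,
                "prescriber_specialty": "general_practitioner",
            }
        )
    return pd.DataFrame(recs)
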