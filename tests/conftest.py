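"""Shared fixtures: tiny hand-built tables and a small simulated experiment."""

import pandas as pd
import pytest

from evmirna.io import build_cq_matrix, validate_sample_sheet, validate_wells
from evmirna.simulate import SimulationConfig, simulate_experiment


def make_wells(rows):
    """Build a validated wells frame from (sample, card, well, assay, cq, amp, conf) tuples."""
    frame = pd.DataFrame(
        rows,
        columns=["sample_id", "card", "well", "assay_id", "cq", "amp_score", "cq_conf"],
    )
    return validate_wells(frame)


def make_sheet(rows):
    """Build a validated sample sheet from (sample, receptor, group, pair, batch) tuples."""
    frame = pd.DataFrame(
        rows, columns=["sample_id", "receptor", "group", "pair_id", "batch"]
    )
    return validate_sheet_frame(frame)


def validate_sheet_frame(frame):
    return validate_sample_sheet(frame)


@pytest.fixture
def paired_sheet():
    """Three treated/VC pairs plus two media controls."""
    rows = []
    for p in (1, 2, 3):
        rows.append((f"T{p}", "ADORA1", "TREATED", p, "B1"))
        rows.append((f"V{p}", "ADORA1", "VEHICLE_CONTROL", p, "B1"))
    rows += [("M1", "ADORA1", "MEDIA_CONTROL", None, "B1"),
             ("M2", "ADORA1", "MEDIA_CONTROL", None, "B1")]
    return make_sheet(rows)


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated experiment reused across read-only tests."""
    cfg = SimulationConfig(n_assays=80, seed=11)
    wells, annotations, truth = simulate_experiment(cfg)
    return wells, annotations, truth


@pytest.fixture(scope="session")
def sim_matrix(sim_small):
    wells, annotations, _ = sim_small
    return build_cq_matrix(wells, annotations), wells, annotations
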