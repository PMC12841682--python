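import datetime as dt

import numpy as np
import pytest

from pinedemog import (
    CensusRecord,
    PRINTED_DENSITIES,
    build_matrix,
    printed_life_table,
)
from pinedemog.synth import DEFAULT_STAGE_DATES


def loop_lambda(fecundity: float, survivals) -> float:
    """Independent closed-form growth rate of a single-loop matrix.

    On a 6-cycle every eigenvalue has modulus (F·∏g)^(1/6); the Perron
    root is the positive real sixth root of the loop product.
    """
    return float((fecundity * np.prod(survivals)) ** (1.0 / 6.0))


@pytest.fixture
def printed_lt():
    return printed_life_table()


@pytest.fixture
def printed_model(printed_lt):
    return build_matrix(printed_lt)


@pytest.fixture
def table_equivalent_records():
    """Branch records whose densities reproduce the published n_x exactly.

    Two identical 1000 × 100 cm branches (area 100 000 cm²) per stage date
    carry counts of 100 × n_x, so each per-branch density equals n_x with
    zero sampling variance.
    """
    stage_class = {"E": "egg", "L1": "larva", "L2": "larva",
                   "L3": "larva", "L4": "larva", "P": "pupa"}
    records = []
    for (stage, date), n_x in zip(DEFAULT_STAGE_DATES.items(), PRINTED_DENSITIES):
        for position in ("upper", "lower"):
            records.append(
                CensusRecord(
                    survey_date=date,
                    tree_id="T01",
                    canopy_position=position,
                    branch_length_cm=1000.0,
                    branch_diameter_cm=100.0,
                    counts={stage_class[stage]: int(round(n_x * 100))},
                )
            )
    return records


@pytest.fixture
def unit_record():
    """A single branch of exactly 1000 cm² with known counts."""
    return CensusRecord(
        survey_date=dt.date(1998, 8, 5),
        tree_id="T01",
        canopy_position="upper",
        branch_length_cm=100.0,
        branch_diameter_cm=10.0,
        counts={"egg": 5, "larva": 2, "pupa": 0},
    )
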