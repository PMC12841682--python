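"""Per-branch field census records and stage densities.

The sampling protocol mirrors a standard branch-beating survey of pine
caterpillar (*Dendrolimus spectabilis*) on young pines: on each survey date
30 trees are selected and one branch is taken from the upper and one from
the lower canopy of each. Counts of eggs, larvae and pupae on each branch
are converted to densities per 1000 cm² of branch surface, where surface
area is approximated as ``length × diameter`` (a rectangle proxy; no
cylindrical correction is applied). Per-date densities are summarised as
mean ± standard error over branches.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Count classes recorded in the field. Larval instars are not
#: distinguished on the branch; the life-table stage of a larval count is
#: determined later by its survey date (see :mod:`pinedemog.lifetable`).
STAGE_CLASSES: tuple[str, ...] = ("egg", "larva", "pupa")

CANOPY_POSITIONS: tuple[str, ...] = ("upper", "lower")

#: Column schema of the census CSV (one row per branch per date).
CENSUS_COLUMNS: tuple[str, ...] = (
    "survey_date",
    "tree_id",
    "canopy_position",
    "branch_length_cm",
    "branch_diameter_cm",
    "egg_count",
    "larva_count",
    "pupa_count",
)

#: Column schema of the density CSV (one row per date per stage class).
DENSITY_COLUMNS: tuple[str, ...] = (
    "survey_date",
    "stage",
    "mean_density",
    "se_density",
    "n_branches",
)


def branch_area(length_cm: float, diameter_cm: float) -> float:
    """Branch surface area in cm² as length × diameter.

    Parameters
    ----------
    length_cm, diameter_cm
        Branch dimensions in centimetres; both must be positive.
    """
    if not length_cm > 0:
        raise ValueError(f"branch_length_cm must be positive, got {length_cm}")
    if not diameter_cm > 0:
        raise ValueError(f"branch_diameter_cm must be positive, got {diameter_cm}")
    return length_cm * diameter_cm


@dataclass(frozen=True)
class CensusRecord:
    """One branch observation: geometry plus stage counts."""

    survey_date: dt.date
    tree_id: str
    canopy_position: str
    branch_length_cm: float
    branch_diameter_cm: float
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.canopy_position not in CANOPY_POSITIONS:
            raise ValueError(
                f"canopy_position must be one of {CANOPY_POSITIONS}, "
                f"got {self.canopy_position!r}"
            )
        branch_area(self.branch_length_cm, self.branch_diameter_cm)
        for stage, count in self.counts.items():
            if stage not in STAGE_CLASSES:
                raise ValueError(
                    f"unknown stage {stage!r}; valid stages: {STAGE_CLASSES}"
                )
            if count < 0 or int(count) != count:
                raise ValueError(
                    f"count for stage {stage!r} must be a non-negative "
                    f"integer, got {count}"
                )
        # normalize: every stage class present, absent counts are zero
        object.__setattr__(
            self,
            "counts",
            {s: int(self.counts.get(s, 0)) for s in STAGE_CLASSES},
        )

    @property
    def area_cm2(self) -> float:
        return branch_area(self.branch_length_cm, self.branch_diameter_cm)


@dataclass(frozen=True)
class StageDensitySeries:
    """Mean ± SE density for one stage class on one survey date.

    Densities are individuals per 1000 cm² of branch surface; the SE is the
    sample standard deviation over branches divided by √n.
    """

    survey_date: dt.date
    stage: str
    mean_density: float
    se_density: float
    n_branches: int

    def __post_init__(self) -> None:
        if self.stage not in STAGE_CLASSES:
            raise ValueError(
                f"unknown stage {self.stage!r}; valid stages: {STAGE_CLASSES}"
            )
        if self.mean_density < 0 or self.se_density < 0:
            raise ValueError("densities and SEs must be non-negative")
        if self.n_branches < 1:
            raise ValueError("n_branches must be positive")
        if self.n_branches == 1 and self.se_density != 0:
            raise ValueError("se_density must be 0 when n_branches == 1")


def record_density(record: CensusRecord, stage: str) -> float:
    """Density of one stage class on one branch, per 1000 cm²."""
    if stage not in STAGE_CLASSES:
        raise ValueError(f"unknown stage {stage!r}; valid stages: {STAGE_CLASSES}")
    count = record.counts.get(stage, 0)
    return count / record.area_cm2 * 1000.0


def aggregate_densities(
    records: Iterable[CensusRecord], by_tree: bool = False
) -> list[StageDensitySeries]:
    """Per-date, per-stage mean ± SE densities over branches.

    By default the SE is taken over all branches observed on a date
    (n = trees × branches per tree). With ``by_tree=True`` branch densities
    are first averaged within each tree and the SE is taken over tree means.
    A single sampling unit yields SE = 0 with a logged warning.
    """
    rows = []
    for rec in records:
        for stage in STAGE_CLASSES:
            rows.append(
                {
                    "survey_date": rec.survey_date,
                    "tree_id": rec.tree_id,
                    "stage": stage,
                    "density": record_density(rec, stage),
                }
            )
    if not rows:
        raise ValueError("aggregate_densities requires at least one record")
    df = pd.DataFrame(rows)
    if by_tree:
        df = (
            df.groupby(["survey_date", "stage", "tree_id"], as_index=False)["density"]
            .mean()
        )
    out: list[StageDensitySeries] = []
    for (date, stage), grp in df.groupby(["survey_date", "stage"], sort=True):
        n = len(grp)
        mean = float(grp["density"].mean())
        if n == 1:
            logger.warning(
                "single sampling unit for %s on %s; SE reported as 0", stage, date
            )
            se = 0.0
        else:
            se = float(grp["density"].std(ddof=1)) / math.sqrt(n)
        out.append(StageDensitySeries(date, stage, mean, se, n))
    return out


def _parse_date(value: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"row {row}: unparseable survey_date {value!r}") from exc


def read_census_csv(path: str | Path) -> list[CensusRecord]:
    """Read per-branch census records from CSV (see :data:`CENSUS_COLUMNS`)."""
    df = pd.read_csv(path, dtype={"tree_id": str})
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census CSV missing column(s): {', '.join(missing)}")
    records: list[CensusRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        date = _parse_date(row.survey_date, i)
        counts = {}
        for stage in STAGE_CLASSES:
            raw = getattr(row, f"{stage}_count")
            if raw < 0 or int(raw) != raw:
                raise ValueError(
                    f"row {i}: {stage}_count must be a non-negative integer, got {raw}"
                )
            counts[stage] = int(raw)
        try:
            records.append(
                CensusRecord(
                    survey_date=date,
                    tree_id=str(row.tree_id),
                    canopy_position=str(row.canopy_position),
                    branch_length_cm=float(row.branch_length_cm),
                    branch_diameter_cm=float(row.branch_diameter_cm),
                    counts=counts,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return records


def write_census_csv(records: Sequence[CensusRecord], path: str | Path) -> None:
    """Write records in the census CSV schema (ISO dates, one row per branch)."""
    df = pd.DataFrame(
        {
            "survey_date": [r.survey_date.isoformat() for r in records],
            "tree_id": [r.tree_id for r in records],
            "canopy_position": [r.canopy_position for r in records],
            "branch_length_cm": [r.branch_length_cm for r in records],
            "branch_diameter_cm": [r.branch_diameter_cm for r in records],
            "egg_count": [r.counts.get("egg", 0) for r in records],
            "larva_count": [r.counts.get("larva", 0) for r in records],
            "pupa_count": [r.counts.get("pupa", 0) for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_density_csv(series: Sequence[StageDensitySeries], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "survey_date": [s.survey_date.isoformat() for s in series],
            "stage": [s.stage for s in series],
            "mean_density": [s.mean_density for s in series],
            "se_density": [s.se_density for s in series],
            "n_branches": [s.n_branches for s in series],
        }
    )
    df.to_csv(path, index=False)


def read_density_csv(path: str | Path) -> list[StageDensitySeries]:
    df = pd.read_csv(path)
    missing = [c for c in DENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"density CSV missing column(s): {', '.join(missing)}")
    return [
        StageDensitySeries(
            survey_date=_parse_date(row.survey_date, i),
            stage=str(row.stage),
            mean_density=float(row.mean_density),
            se_density=float(row.se_density),
            n_branches=int(row.n_branches),
        )
        for i, row in enumerate(df.itertuples(index=False), start=2)
    ]
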