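"""Stage-classified life table: n_x, g_x = n_x/n_{x-1}, l_x = n_x/n_a.

The pine caterpillar life cycle is divided into six censusable stages —
eggs (E), four larval classes (L1 autumn larvae soon after hatch, L2 autumn
larvae before overwintering, L3 early-spring larvae after diapause, L4 late
spring larvae) and pupae (P). Adults are not observable on branches, so
realized fecundity F is taken to be the observed egg density n_a itself.

Stage densities enter either from field series via calendar windows
(:func:`stage_schedule_from_series`) or directly as an ordered vector
(:func:`build_life_table`). All ratios are carried at full precision;
rounding happens only at presentation.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .census import StageDensitySeries

logger = logging.getLogger(__name__)

#: Ordered life-table stages.
STAGES: tuple[str, ...] = ("E", "L1", "L2", "L3", "L4", "P")

#: Which census count class each life stage is read from.
STAGE_SERIES: Mapping[str, str] = {
    "E": "egg",
    "L1": "larva",
    "L2": "larva",
    "L3": "larva",
    "L4": "larva",
    "P": "pupa",
}

# Published field estimates for the 1998-1999 Wando generation. The
# printed survivals are the rounded figures of the source table; note the
# pupal value (0.66) differs in the second decimal from the ratio of the
# rounded densities (0.16/0.25 = 0.64) because the original ratios were
# formed from unrounded densities.
PRINTED_DENSITIES: tuple[float, ...] = (69.45, 6.33, 3.39, 0.49, 0.25, 0.16)
PRINTED_SURVIVALS: tuple[float, ...] = (0.091, 0.54, 0.15, 0.50, 0.66)
PRINTED_FECUNDITY: float = 69.45

#: Eggs per egg mass (laboratory counts): biological context for the
#: fecundity sweeps; NOT used as the matrix fecundity, which is the
#: realized egg density per 1000 cm².
EGGS_PER_MASS_MEAN: float = 169.0
EGGS_PER_MASS_RANGE: tuple[int, int] = (139, 265)


@dataclass(frozen=True)
class LifeTable:
    """Ordered stage densities with survival ratios.

    ``g_x[0]`` is NaN (survival into the first stage is undefined);
    ``l_x[0]`` is 1 by construction. ``fecundity`` is the realized
    fecundity F — the egg density per 1000 cm².
    """

    stages: tuple[str, ...]
    n_x: np.ndarray
    g_x: np.ndarray
    l_x: np.ndarray
    fecundity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": self.stages, "n_x": self.n_x, "g_x": self.g_x, "l_x": self.l_x}
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["g_x"] = df["g_x"].map(lambda g: "" if math.isnan(g) else repr(g))
        df.to_csv(path, index=False)


def build_life_table(
    stage_densities: Sequence[float], stage_labels: Sequence[str] = STAGES
) -> LifeTable:
    """Construct a life table from ordered stage densities.

    g_x = n_x / n_{x-1}; l_x = n_x / n_a with n_a the first (egg) density;
    realized fecundity F = n_a. The first density must be positive and a
    stage of zero density cannot be followed by a positive one.
    """
    n = np.asarray(stage_densities, dtype=float)
    labels = tuple(stage_labels)
    if len(n) != len(labels):
        raise ValueError(
            f"{len(n)} densities supplied for {len(labels)} stage labels"
        )
    if len(n) < 2:
        raise ValueError("a life table needs at least 2 stages")
    if not n[0] > 0:
        raise ValueError("initial density must be positive")
    if np.any(n < 0):
        raise ValueError("stage densities must be non-negative")
    for i in range(1, len(n)):
        if n[i] > 0 and n[i - 1] == 0:
            raise ValueError(
                f"stage {labels[i]!r} has positive density after a zero-density "
                f"stage {labels[i - 1]!r}; resurrection is impossible"
            )
    g = np.empty_like(n)
    g[0] = np.nan
    with np.errstate(invalid="ignore"):
        g[1:] = np.where(n[:-1] > 0, n[1:] / n[:-1], 0.0)
    if np.any(g[1:] > 1):
        bad = [labels[i] for i in range(1, len(n)) if g[i] > 1]
        logger.warning(
            "survival ratio exceeds 1 for stage(s) %s; census noise can "
            "produce apparent g > 1",
            ", ".join(bad),
        )
    l = n / n[0]
    return LifeTable(stages=labels, n_x=n, g_x=g, l_x=l, fecundity=float(n[0]))


def printed_life_table() -> LifeTable:
    """The published life table with survivals pinned to their printed values.

    Densities are the printed n_x; g_x are the printed 2-figure survivals
    (not re-derived from the rounded densities), and l_x is their cumulative
    product so that the telescoping identity holds exactly. Use this for
    exact replication of the published matrix results; ratios re-derived
    from densities are available via ``build_life_table(PRINTED_DENSITIES)``.
    """
    g = np.array([np.nan, *PRINTED_SURVIVALS])
    l = np.ones(6)
    l[1:] = np.cumprod(PRINTED_SURVIVALS)
    return LifeTable(
        stages=STAGES,
        n_x=np.array(PRINTED_DENSITIES),
        g_x=g,
        l_x=l,
        fecundity=PRINTED_FECUNDITY,
    )


@dataclass(frozen=True)
class StageWindow:
    """Calendar window assigning survey dates to a life-table stage."""

    series: str  # census count class: egg | larva | pupa
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start must not be after end")

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


#: Default stage calendar for the 1998-1999 generation: eggs in early
#: August, L1 soon after hatch in late August, L2 in mid-autumn, L3 at the
#: first post-winter survey, L4 in late spring and pupae in July.
DEFAULT_STAGE_WINDOWS: Mapping[str, StageWindow] = {
    "E": StageWindow("egg", dt.date(1998, 8, 1), dt.date(1998, 8, 10)),
    "L1": StageWindow("larva", dt.date(1998, 8, 15), dt.date(1998, 8, 31)),
    "L2": StageWindow("larva", dt.date(1998, 10, 1), dt.date(1998, 11, 30)),
    "L3": StageWindow("larva", dt.date(1999, 3, 1), dt.date(1999, 3, 31)),
    "L4": StageWindow("larva", dt.date(1999, 5, 1), dt.date(1999, 5, 31)),
    "P": StageWindow("pupa", dt.date(1999, 6, 20), dt.date(1999, 7, 31)),
}


def stage_schedule_from_series(
    series: Iterable[StageDensitySeries],
    stage_windows: Mapping[str, StageWindow] = DEFAULT_STAGE_WINDOWS,
) -> np.ndarray:
    """Ordered stage densities n_x from per-date density series.

    For each life-table stage the mean density of the matching census class
    (egg/larva/pupa) is averaged over the survey dates falling inside the
    stage's calendar window. Every stage window must capture at least one
    survey date.
    """
    series = list(series)
    out = []
    for stage in STAGES:
        window = stage_windows[stage]
        vals = [
            s.mean_density
            for s in series
            if s.stage == window.series and window.contains(s.survey_date)
        ]
        if not vals:
            raise ValueError(
                f"no {window.series} survey dates fall in the window for "
                f"stage {stage!r} ({window.start} to {window.end})"
            )
        out.append(float(np.mean(vals)))
    return np.array(out)
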