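"""Culture-based ecophysiological profiling of soil bacterial communities.

Colonies on dilution plates are scored by the day on which they first become
visible (days 1, 2 and 6 of incubation).  Fast-appearing colonies (within
48 h) are attributed to r-strategists — opportunists that grow quickly in
uncrowded, resource-rich conditions — and the remainder to K-strategists.
The eco-physiological (EP) index is the Shannon entropy of the distribution
of colonies over appearance-day classes: it is 0 when every colony appears in
a single class and maximal (ln 3 with three classes) when the classes are
equally occupied, so it summarizes how evenly the community spreads over
growth-rate guilds.

The module also provides the classical balanced fixed-effects ANOVA used to
test land-use and season effects (with their interaction) on these indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .synthetic import DAY_CLASSES, StudyDesign

__all__ = [
    "ColonyCounts",
    "EPResult",
    "AnovaResult",
    "cfu_per_gram",
    "strategist_fractions",
    "ep_index",
    "logit",
    "anova_factorial",
    "anova_oneway",
]


@dataclass(frozen=True)
class ColonyCounts:
    """Colonies per appearance-day class from one dilution plate.

    dilution_exponent d means the plate received the 10^-d suspension;
    plated_volume_ml of a suspension of soil_mass_g in suspension_volume_ml.
    Defaults reflect the common protocol: 100 ul plated from 1 g of soil in
    10 ml of buffer.
    """

    counts_by_day: Mapping[int, int]
    dilution_exponent: int = 0
    plated_volume_ml: float = 0.1
    soil_mass_g: float = 1.0
    suspension_volume_ml: float = 10.0

    def __post_init__(self) -> None:
        for day, n in self.counts_by_day.items():
            if n < 0:
                raise ValueError(f"negative colony count for day {day}")
        if self.plated_volume_ml <= 0:
            raise ValueError("plated volume must be positive")
        if self.soil_mass_g <= 0 or self.suspension_volume_ml <= 0:
            raise ValueError("soil mass and suspension volume must be positive")

    @classmethod
    def from_array(cls, counts: Sequence[int], **kwargs) -> "ColonyCounts":
        if len(counts) != len(DAY_CLASSES):
            raise ValueError(f"expected {len(DAY_CLASSES)} day classes")
        return cls(dict(zip(DAY_CLASSES, (int(c) for c in counts))), **kwargs)

    @property
    def total(self) -> int:
        return sum(self.counts_by_day.values())


@dataclass(frozen=True)
class EPResult:
    ep: float
    proportions: tuple[float, ...]
    r_percent: float
    k_percent: float


@dataclass(frozen=True)
class AnovaTerm:
    sum_of_squares: float
    df: int
    mean_square: float
    f_statistic: float
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects decomposition; keys are term names incl. 'residual'."""

    terms: dict[str, AnovaTerm]
    total_ss: float
    n: int


def cfu_per_gram(c: ColonyCounts) -> float:
    """Total colony-forming units per gram of dry soil.

    colonies x 10^dilution x (suspension volume / plated volume) / soil mass.
    Counts outside the 30-300 plate validity window trigger a warning only,
    so extreme synthetic plates stay usable.
    """
    if c.dilution_exponent < 0:
        raise ValueError("dilution_exponent must be >= 0")
    total = c.total
    if total > 0 and not 30 <= total <= 300:
        warnings.warn(
            f"plate count {total} outside the 30-300 validity window",
            stacklevel=2,
        )
    return (
        total
        * 10.0**c.dilution_exponent
        * (c.suspension_volume_ml / c.plated_volume_ml)
        / c.soil_mass_g
    )


def strategist_fractions(c: ColonyCounts) -> tuple[float, float]:
    """(r_percent, k_percent): colonies within 48 h are r-strategists."""
    total = c.total
    if total == 0:
        raise ValueError("strategist fractions undefined for zero total count")
    fast = sum(n for day, n in c.counts_by_day.items() if day <= 2)
    r = 100.0 * fast / total
    return r, 100.0 - r


def ep_index(c: ColonyCounts, base: float = math.e) -> EPResult:
    """Eco-physiological index: entropy of appearance-day proportions.

    EP = -sum_i P_i log(P_i), with P_i the share of colonies first counted on
    day i and 0 log 0 = 0 by continuity.  Natural log by default; pass
    ``base=10`` for decimal entropy (report the base alongside the value).
    """
    total = c.total
    if total == 0:
        raise ValueError("EP index undefined for zero total count")
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    props = tuple(n / total for _, n in sorted(c.counts_by_day.items()))
    ep = -sum(p * math.log(p, base) for p in props if p > 0)
    r, k = strategist_fractions(c)
    return EPResult(ep=max(ep, 0.0), proportions=props, r_percent=r, k_percent=k)


def logit(p: float, shrink_n: int | None = None) -> float:
    """ln(p / (1 - p)) for a proportion p in (0, 1).

    Exact 0 or 1 is a domain error by default.  When ``shrink_n`` (the sample
    size behind the proportion) is given, the empirical shrink
    p <- (p (n - 1) + 0.5) / n is applied first so boundary values become
    finite; this correction is opt-in, never silent.
    """
    if shrink_n is not None:
        if shrink_n < 1:
            raise ValueError("shrink_n must be >= 1")
        p = (p * (shrink_n - 1) + 0.5) / shrink_n
    if not 0.0 < p < 1.0:
        raise ValueError("logit requires p strictly inside (0, 1)")
    return math.log(p / (1.0 - p))


def _as_cell_array(
    values: Mapping[str, float], design: StudyDesign
) -> tuple[np.ndarray, list[str], list[str]]:
    """Arrange per-sample values into an (A levels, B levels, reps) array."""
    a_levels = sorted({s.land_use for s in design.samples})
    b_levels = sorted({s.season for s in design.samples})
    r = design.n_replicates
    arr = np.full((len(a_levels), len(b_levels), r), np.nan)
    counter: dict[tuple[str, str], int] = {}
    for s in design.samples:
        if s.sample_id not in values:
            raise ValueError(f"missing value for sample {s.sample_id}")
        i = a_levels.index(s.land_use)
        j = b_levels.index(s.season)
        k = counter.get((s.land_use, s.season), 0)
        counter[(s.land_use, s.season)] = k + 1
        arr[i, j, k] = float(values[s.sample_id])
    if np.isnan(arr).any():
        raise ValueError("unbalanced design: balanced formulas only")
    return arr, a_levels, b_levels


def anova_factorial(
    values: Mapping[str, float],
    design: StudyDesign,
    factor_a: str = "land_use",
    factor_b: str = "season",
) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Classical decomposition SS_total = SS_A + SS_B + SS_AxB + SS_residual,
    exact on balanced data.  Requires >= 2 replicates per cell for the
    interaction term.  If all observations are equal, F statistics are
    reported as NaN with p = NaN (zero-variance data carry no evidence).
    """
    arr, a_levels, b_levels = _as_cell_array(values, design)
    a, b, r = arr.shape
    if r < 2:
        raise ValueError("interaction term needs >= 2 replicates per cell")
    n = arr.size
    grand = arr.mean()
    mean_a = arr.mean(axis=(1, 2))
    mean_b = arr.mean(axis=(0, 2))
    mean_cell = arr.mean(axis=2)

    ss_a = b * r * float(np.sum((mean_a - grand) ** 2))
    ss_b = a * r * float(np.sum((mean_b - grand) ** 2))
    ss_cell = r * float(np.sum((mean_cell - grand) ** 2))
    ss_ab = ss_cell - ss_a - ss_b
    ss_res = float(np.sum((arr - mean_cell[:, :, None]) ** 2))
    ss_tot = float(np.sum((arr - grand) ** 2))

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_res = a * b * (r - 1)

    ms_res = ss_res / df_res
    terms: dict[str, AnovaTerm] = {}
    for name, ss, df in (
        (factor_a, ss_a, df_a),
        (factor_b, ss_b, df_b),
        (f"{factor_a}:{factor_b}", max(ss_ab, 0.0), df_ab),
    ):
        ms = ss / df
        if ms_res > 0:
            f = ms / ms_res
            p = float(stats.f.sf(f, df, df_res))
        else:
            f, p = float("nan"), float("nan")
        terms[name] = AnovaTerm(ss, df, ms, f, p)
    terms["residual"] = AnovaTerm(ss_res, df_res, ms_res, float("nan"), float("nan"))
    return AnovaResult(terms=terms, total_ss=ss_tot, n=n)


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Balanced (or unbalanced) one-way fixed-effects ANOVA.

    Provided for the log-CFU comparisons, which the study design reduces to a
    single grouping factor.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    data = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in data):
        raise ValueError("empty group")
    allv = np.concatenate(data)
    grand = allv.mean()
    ss_b = float(sum(g.size * (g.mean() - grand) ** 2 for g in data))
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in data))
    df_b = len(data) - 1
    df_w = allv.size - len(data)
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w > 0:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    else:
        f, p = float("nan"), float("nan")
    terms = {
        "group": AnovaTerm(ss_b, df_b, ms_b, f, p),
        "residual": AnovaTerm(ss_w, df_w, ms_w, float("nan"), float("nan")),
    }
    return AnovaResult(terms=terms, total_ss=ss_b + ss_w, n=int(allv.size))
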