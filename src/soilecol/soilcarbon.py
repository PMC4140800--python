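"""Soil organic carbon fractions, humification and microbial activity indices.

Carbon fractionation splits total organic carbon (C_org, % of dry soil) into
an alkali-extractable pool (C_ext), its humified part (C_HA+FA, humic plus
fulvic acids) and the non-humified remainder C_NH = C_ext - C_HA+FA.  Three
standard humification indicators follow:

    HI  = C_NH / C_HA+FA        humification index (labile over humified)
    DH% = 100 C_HA+FA / C_ext   degree of humification
    HR% = 100 C_HA+FA / C_org   humification rate

Soil organic matter is SOM = 1.724 x C_org (the van Bemmelen factor).

Microbial activity is characterized from a 28-day respiration incubation.
Cumulative CO2-C follows first-order kinetics C_m(t) = C0 (1 - e^{-kt}) with
C0 the potentially mineralizable carbon; the fit is by nonlinear least
squares.  Derived quotients: basal respiration C_bas (mean daily rate over
the final measured interval), cumulative respiration C_cum (value at day 28),
the metabolic quotient qCO2 = C_bas / C_mic, the mineralization quotient
qM = C_cum / C_org and the biomass share Cmic:Corg, where C_mic is microbial
biomass carbon (mg C per kg soil).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "VAN_BEMMELEN",
    "KineticsFit",
    "MicrobialIndices",
    "som_from_corg",
    "humification_indices",
    "fit_mineralization",
    "cumulative_basal",
    "microbial_indices",
    "percent_to_mg_per_kg",
]

#: conventional conversion from organic C to organic matter
VAN_BEMMELEN = 1.724

#: standard CO2 trapping schedule (days of incubation)
STANDARD_DAYS = (1, 2, 4, 7, 10, 14, 21, 28)


@dataclass(frozen=True)
class KineticsFit:
    c0: float  # potentially mineralizable C, mg C kg^-1 soil
    k: float  # rate constant, day^-1
    rss: float
    converged: bool
    iterations: int


@dataclass(frozen=True)
class MicrobialIndices:
    c_cum: float  # mg C kg^-1 per 28 d
    c_bas: float  # mg C kg^-1 day^-1
    qco2: float  # day^-1 (C_bas per unit C_mic)
    qm: float  # dimensionless (C_cum / C_org, both mg kg^-1)
    cmic_corg_percent: float


def percent_to_mg_per_kg(percent: float) -> float:
    """Convert a carbon fraction in % of dry soil to mg C per kg soil."""
    return percent * 1e4


def som_from_corg(c_org: float) -> float:
    """Soil organic matter from organic carbon: SOM = 1.724 C_org."""
    if c_org < 0:
        raise ValueError("C_org must be nonnegative")
    return VAN_BEMMELEN * c_org


def humification_indices(
    c_org: float, c_ext: float, c_hafa: float
) -> tuple[float, float, float, float]:
    """(C_NH, HI, DH%, HR%) from the three measured carbon fractions.

    Requires 0 <= C_HAFA <= C_ext <= C_org with positive C_org and C_ext.
    HI is reported as NaN when C_HAFA = 0 (no humified fraction to normalize
    by) — flagged, not silently zeroed.
    """
    if c_org <= 0 or c_ext <= 0:
        raise ValueError("C_org and C_ext must be positive")
    if not 0 <= c_hafa <= c_ext <= c_org:
        raise ValueError("fractions must satisfy 0 <= C_HAFA <= C_ext <= C_org")
    c_nh = c_ext - c_hafa
    hi = c_nh / c_hafa if c_hafa > 0 else float("nan")
    dh = 100.0 * c_hafa / c_ext
    hr = 100.0 * c_hafa / c_org
    return c_nh, hi, dh, hr


def _model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    c0, k = params
    return c0 * (1.0 - np.exp(-k * t))


def fit_mineralization(series: np.ndarray, max_iter: int = 500) -> KineticsFit:
    """Nonlinear least-squares fit of C_m(t) = C0 (1 - e^{-kt}).

    ``series`` is (n, 2): columns (day, cumulative CO2-C).  Start values:
    C0 <- 1.1 x max(C_m); k from a log-linear regression of
    log(1 - C_m / C0_init) on t.  The trust-region solver stops when the
    relative parameter change falls below 1e-8 or after ``max_iter`` residual
    evaluations; non-convergence is flagged in the result, never silent.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 3:
        raise ValueError("series must be (n >= 3, 2): day, cumulative CO2-C")
    t, cm = s[:, 0], s[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(cm < 0) or cm.max() <= 0:
        raise ValueError("cumulative CO2-C must be nonnegative with a positive max")

    c0_init = 1.1 * cm.max()
    frac = np.clip(1.0 - cm / c0_init, 1e-12, None)
    # log(1 - Cm/C0) = -k t : slope through the origin
    k_init = float(-np.sum(t * np.log(frac)) / np.sum(t * t))
    k_init = max(k_init, 1e-6)

    res = least_squares(
        lambda p: _model(p, t) - cm,
        x0=[c0_init, k_init],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-8,
        max_nfev=max_iter,
    )
    c0, k = res.x
    return KineticsFit(
        c0=float(c0),
        k=float(k),
        rss=float(2.0 * res.cost),
        converged=bool(res.success),
        iterations=int(res.nfev),
    )


def cumulative_basal(series: np.ndarray, final_day: float = 28.0) -> tuple[float, float]:
    """(C_cum, C_bas) from a cumulative respiration series.

    C_cum is the cumulative CO2-C at the final incubation day; C_bas is the
    mean daily rate over the last measured interval (e.g. days 21-28), since
    CO2 is trapped at discrete days and a literal single-day value at day 28
    is not observable from the standard schedule.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 2:
        raise ValueError("series must be (n >= 2, 2): day, cumulative CO2-C")
    t, cm = s[:, 0], s[:, 1]
    idx = np.where(t == final_day)[0]
    if idx.size == 0:
        raise ValueError(f"series does not cover day {final_day:g}")
    i = int(idx[0])
    if i == 0:
        raise ValueError("no measurement precedes the final day")
    c_cum = float(cm[i])
    c_bas = float((cm[i] - cm[i - 1]) / (t[i] - t[i - 1]))
    return c_cum, c_bas


def microbial_indices(
    c_bas: float,
    c_cum: float,
    c_mic: float,
    c_org_percent: float,
) -> MicrobialIndices:
    """Metabolic quotients from respiration, biomass and organic carbon.

    qCO2 = C_bas / C_mic (per day); qM = C_cum / C_org with C_org converted
    from % to mg kg^-1; Cmic:Corg as a percentage of organic carbon held in
    microbial biomass.
    """
    if c_mic <= 0:
        raise ValueError("C_mic must be positive")
    if c_org_percent <= 0:
        raise ValueError("C_org must be positive")
    if c_bas < 0 or c_cum < 0:
        raise ValueError("respiration values must be nonnegative")
    c_org_mg = percent_to_mg_per_kg(c_org_percent)
    return MicrobialIndices(
        c_cum=c_cum,
        c_bas=c_bas,
        qco2=c_bas / c_mic,
        qm=c_cum / c_org_mg,
        cmic_corg_percent=100.0 * c_mic / c_org_mg,
    )
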