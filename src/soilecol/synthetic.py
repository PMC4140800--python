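"""Synthetic study-shaped data for a land-use x season soil survey.

The generators emulate the structure of a balanced field campaign over five
Mediterranean land-use types (cork-oak forest CO, hayland-pasture rotation PA,
managed meadow MM, grass-covered vineyard CV, tilled vineyard TV), each sampled
in spring and autumn with the same number of field replicates.  Every
downstream stage of the package (colony-count ecophysiology, gel fingerprint
analysis, respiration kinetics, soil chemistry indicators) can therefore be
exercised end to end without field data, with the group effects fully known.

A single global seed is expanded into independent per-stream seeds by fixed
offsets, so each simulation stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LAND_USES",
    "SEASONS",
    "DAY_CLASSES",
    "Sample",
    "StudyDesign",
    "GroupParams",
    "GroupEffects",
    "default_group_effects",
    "simulate_design",
    "simulate_colony_counts",
    "simulate_lane_trace",
    "simulate_band_community",
    "simulate_respiration",
    "simulate_soil_chemistry",
]

LAND_USES = ("CO", "PA", "MM", "CV", "TV")
SEASONS = ("spring", "autumn")
#: colony counting days (days of incubation at which new colonies are scored)
DAY_CLASSES = (1, 2, 6)

# fixed per-stream seed offsets (global seed + offset -> stream RNG)
_STREAM_OFFSET = {
    "colony": 1,
    "bands": 2,
    "respiration": 3,
    "chemistry": 4,
    "trace": 5,
}


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(int(seed) + _STREAM_OFFSET[stream])


@dataclass(frozen=True)
class Sample:
    """One composite field sample."""

    sample_id: str
    land_use: str
    season: str
    replicate: int


@dataclass(frozen=True)
class StudyDesign:
    """Balanced land-use x season x replicate design."""

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample identifiers must be unique")
        counts = {}
        for s in self.samples:
            counts[(s.land_use, s.season)] = counts.get((s.land_use, s.season), 0) + 1
        if len(set(counts.values())) > 1:
            raise ValueError("design is unbalanced: unequal replicates per cell")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_replicates(self) -> int:
        first = self.samples[0]
        return sum(
            1
            for s in self.samples
            if (s.land_use, s.season) == (first.land_use, first.season)
        )

    def groups(self) -> list[tuple[str, str]]:
        """All (land_use, season) cells in design order."""
        seen: list[tuple[str, str]] = []
        for s in self.samples:
            key = (s.land_use, s.season)
            if key not in seen:
                seen.append(key)
        return seen


@dataclass(frozen=True)
class GroupParams:
    """Generating parameters for one (land_use, season) group.

    class_proportions : expected share of colonies appearing on each counting
        day (day 1, 2, 6); must sum to 1.
    occurrence_prob / mean_abundance : per-species probability of presence and
        expected lane intensity in the shared band pool.
    c0, k : first-order mineralization parameters (mg C kg^-1 soil, day^-1).
    chemistry_means : (C_org %, C_ext %, C_HAFA %, C_mic mg kg^-1).
    """

    class_proportions: tuple[float, float, float]
    occurrence_prob: np.ndarray
    mean_abundance: np.ndarray
    c0: float
    k: float
    chemistry_means: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be nonnegative and sum to 1")
        if self.c0 <= 0 or self.k <= 0:
            raise ValueError("kinetic parameters C0 and k must be positive")
        c_org, c_ext, c_hafa, c_mic = self.chemistry_means
        if not (0 <= c_hafa <= c_ext <= c_org) or c_org <= 0 or c_mic <= 0:
            raise ValueError(
                "chemistry means must satisfy 0 <= C_HAFA <= C_ext <= C_org "
                "with positive C_org and C_mic"
            )


@dataclass(frozen=True)
class GroupEffects:
    """Group-level generating parameters plus the shared band pool.

    band_positions holds the relative-migration (Rf) position of every species
    in the pool; all lanes draw bands from this common pool so cross-lane band
    matching is well defined.
    """

    params: dict[tuple[str, str], GroupParams]
    band_positions: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __getitem__(self, key: tuple[str, str]) -> GroupParams:
        return self.params[key]

    @property
    def pool_size(self) -> int:
        return int(self.band_positions.size)


# ---------------------------------------------------------------------------
# default study conditions


def _default_class_proportions() -> dict[tuple[str, str], tuple[float, float, float]]:
    # r-strategists (days 1+2) dominate everywhere; the managed meadow has the
    # most uneven distribution (lowest EP); the tilled vineyard shifts most
    # between seasons.
    return {
        ("CO", "spring"): (0.30, 0.45, 0.25),
        ("CO", "autumn"): (0.28, 0.44, 0.28),
        ("PA", "spring"): (0.32, 0.46, 0.22),
        ("PA", "autumn"): (0.30, 0.42, 0.28),
        ("MM", "spring"): (0.15, 0.35, 0.50),
        ("MM", "autumn"): (0.12, 0.33, 0.55),
        ("CV", "spring"): (0.35, 0.40, 0.25),
        ("CV", "autumn"): (0.25, 0.45, 0.30),
        ("TV", "spring"): (0.40, 0.40, 0.20),
        ("TV", "autumn"): (0.22, 0.38, 0.40),
    }


_DEFAULT_KINETICS = {
    # C0 declines from spring to autumn in every soil; the forest soil holds
    # the largest labile pool.
    ("CO", "spring"): (850.0, 0.050),
    ("CO", "autumn"): (700.0, 0.045),
    ("PA", "spring"): (750.0, 0.050),
    ("PA", "autumn"): (650.0, 0.048),
    ("MM", "spring"): (600.0, 0.040),
    ("MM", "autumn"): (500.0, 0.040),
    ("CV", "spring"): (550.0, 0.045),
    ("CV", "autumn"): (450.0, 0.042),
    ("TV", "spring"): (500.0, 0.040),
    ("TV", "autumn"): (400.0, 0.038),
}

_DEFAULT_CHEMISTRY = {
    # (C_org %, C_ext %, C_HAFA %, C_mic mg/kg); organic carbon richest under
    # the cork-oak forest in spring, slightly higher under pasture in autumn.
    ("CO", "spring"): (2.8, 1.40, 0.90, 450.0),
    ("CO", "autumn"): (2.4, 1.20, 0.80, 380.0),
    ("PA", "spring"): (2.0, 1.00, 0.65, 400.0),
    ("PA", "autumn"): (2.1, 1.10, 0.72, 360.0),
    ("MM", "spring"): (1.6, 0.80, 0.50, 300.0),
    ("MM", "autumn"): (1.4, 0.70, 0.45, 260.0),
    ("CV", "spring"): (1.3, 0.65, 0.42, 260.0),
    ("CV", "autumn"): (1.2, 0.60, 0.40, 230.0),
    ("TV", "spring"): (1.1, 0.55, 0.35, 220.0),
    ("TV", "autumn"): (1.0, 0.50, 0.32, 200.0),
}


def default_group_effects(
    pool_size: int = 40,
    season_effect: float = 0.8,
    land_use_effect: float = 0.6,
    seed: int = 0,
) -> GroupEffects:
    """Build the default generating parameters for the 10 study groups.

    A shared species pool of ``pool_size`` bands is split into a ubiquitous
    core, two season-indicator blocks (present mostly in one season) and five
    land-use-indicator blocks.  ``season_effect`` and ``land_use_effect`` in
    [0, 1] scale the occupancy contrast of the indicator blocks: 0 removes all
    group structure, 1 makes indicator species (almost) exclusive to their
    group.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if not (0 <= season_effect <= 1 and 0 <= land_use_effect <= 1):
        raise ValueError("effect sizes must lie in [0, 1]")
    rng = np.random.default_rng(int(seed) + 97)
    positions = np.sort(rng.uniform(0.05, 0.95, size=pool_size))
    # block assignment: ~40% core, ~30% season indicators, rest land use
    n_core = max(1, int(round(pool_size * 0.4)))
    n_season = max(2, int(round(pool_size * 0.3)))
    idx = np.arange(pool_size)
    core = idx[:n_core]
    season_block = idx[n_core : n_core + n_season]
    spring_block = season_block[: len(season_block) // 2]
    autumn_block = season_block[len(season_block) // 2 :]
    lu_block = idx[n_core + n_season :]
    lu_assign = {lu: lu_block[i::5] for i, lu in enumerate(LAND_USES)}

    base_abund = rng.lognormal(mean=np.log(1000.0), sigma=0.5, size=pool_size)

    props = _default_class_proportions()
    params: dict[tuple[str, str], GroupParams] = {}
    for lu in LAND_USES:
        for season in SEASONS:
            p = np.full(pool_size, 0.5)
            p[core] = 0.9
            own_season = spring_block if season == "spring" else autumn_block
            other_season = autumn_block if season == "spring" else spring_block
            p[own_season] = 0.5 + 0.45 * season_effect
            p[other_season] = 0.5 - 0.45 * season_effect
            for lu2 in LAND_USES:
                block = lu_assign[lu2]
                if lu2 == lu:
                    p[block] = 0.5 + 0.45 * land_use_effect
                else:
                    p[block] = 0.5 - 0.45 * land_use_effect
            params[(lu, season)] = GroupParams(
                class_proportions=props[(lu, season)],
                occurrence_prob=p,
                mean_abundance=base_abund.copy(),
                c0=_DEFAULT_KINETICS[(lu, season)][0],
                k=_DEFAULT_KINETICS[(lu, season)][1],
                chemistry_means=_DEFAULT_CHEMISTRY[(lu, season)],
            )
    return GroupEffects(params=params, band_positions=positions)


# ---------------------------------------------------------------------------
# simulators


def simulate_design(n_replicates: int, seed: int = 0) -> StudyDesign:
    """Balanced design: 5 land uses x 2 seasons x ``n_replicates`` samples."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    samples = []
    for lu in LAND_USES:
        for season in SEASONS:
            for rep in range(1, n_replicates + 1):
                samples.append(
                    Sample(f"{lu}-{season}-{rep}", lu, season, rep)
                )
    return StudyDesign(samples=tuple(samples))


def simulate_colony_counts(
    design: StudyDesign,
    effects: GroupEffects,
    total_mean: float = 150.0,
    dispersion: float = 0.2,
    dilution_exponent: int = 4,
    seed: int = 0,
) -> dict[str, "np.ndarray"]:
    """Colony counts per appearance-day class for every sample.

    The total plate count is lognormal around ``total_mean`` (multiplicative
    noise keeps counts positive), then split multinomially over the group's
    day-class proportions.  Returns ``{sample_id: array([day1, day2, day6])}``.
    """
    if total_mean <= 0:
        raise ValueError("total_mean must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    rng = _stream_rng(seed, "colony")
    out: dict[str, np.ndarray] = {}
    for s in design.samples:
        p = np.asarray(effects[(s.land_use, s.season)].class_proportions)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        total = max(1, int(round(rng.lognormal(np.log(total_mean), dispersion))))
        out[s.sample_id] = rng.multinomial(total, p)
    return out


def simulate_lane_trace(
    bands: Sequence[tuple[float, float]],
    peak_width: float = 0.01,
    baseline_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    n_points: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Densitometric lane trace: Gaussian peaks + smooth baseline + noise.

    ``bands`` is a list of (position in [0, 1] of lane length, peak height).
    ``peak_width`` is the Gaussian sigma in lane-fraction units.  The smooth
    baseline is a half-cosine arch scaled by ``baseline_amplitude`` (gel
    backgrounds are brightest mid-lane).  The trace is clipped at zero.
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    if peak_width <= 0:
        raise ValueError("peak_width must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    grid = np.linspace(0.0, 1.0, n_points)
    trace = np.zeros(n_points)
    for pos, height in bands:
        if not 0.0 <= pos <= 1.0:
            raise ValueError(f"band position {pos} outside [0, 1]")
        if height <= 0:
            raise ValueError("band heights must be positive")
        trace += height * np.exp(-0.5 * ((grid - pos) / peak_width) ** 2)
    if baseline_amplitude:
        trace += baseline_amplitude * np.sin(np.pi * grid)
    if noise_sd > 0:
        rng = _stream_rng(seed, "trace")
        trace += rng.normal(0.0, noise_sd, size=n_points)
    return np.clip(trace, 0.0, None)


def simulate_band_community(
    design: StudyDesign,
    effects: GroupEffects,
    abundance_sigma: float = 0.4,
    seed: int = 0,
) -> dict[str, "np.ndarray"]:
    """Per-sample band abundances over the shared species pool.

    Each species is present with its group's occurrence probability; present
    species get a lognormal intensity around the group mean abundance.
    Returns ``{sample_id: abundance vector over the pool}`` — zero where the
    band is absent.  Band Rf positions live in ``effects.band_positions``.
    """
    if effects.pool_size < 1:
        raise ValueError("effects must carry a nonempty band pool")
    rng = _stream_rng(seed, "bands")
    out: dict[str, np.ndarray] = {}
    for s in design.samples:
        g = effects[(s.land_use, s.season)]
        present = rng.random(effects.pool_size) < g.occurrence_prob
        abund = g.mean_abundance * rng.lognormal(0.0, abundance_sigma, effects.pool_size)
        out[s.sample_id] = np.where(present, abund, 0.0)
    return out


def first_order_accumulation(c0: float, k: float, t: np.ndarray) -> np.ndarray:
    """Cumulative mineralized C under first-order kinetics: C0 (1 - e^-kt)."""
    return c0 * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def simulate_respiration(
    c0: float,
    k: float,
    days: Sequence[float] = (1, 2, 4, 7, 10, 14, 21, 28),
    noise_sd: float = 0.0,
    monotonize: bool = False,
    seed: int = 0,
) -> "np.ndarray":
    """Cumulative CO2-C series on the given incubation days.

    Noiseless values follow the first-order model exactly; Gaussian noise is
    added independently per day, clipped to be nonnegative, and made
    non-decreasing only when ``monotonize`` is requested.
    Returns an array of shape (n_days, 2): columns (day, cumulative CO2-C).
    """
    if c0 <= 0 or k <= 0:
        raise ValueError("C0 and k must be positive")
    t = np.asarray(days, dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("days must be nonempty and strictly increasing")
    values = first_order_accumulation(c0, k, t)
    if noise_sd > 0:
        rng = _stream_rng(seed, "respiration")
        values = values + rng.normal(0.0, noise_sd, size=t.size)
        values = np.clip(values, 0.0, None)
        if monotonize:
            values = np.maximum.accumulate(values)
    return np.column_stack([t, values])


def simulate_soil_chemistry(
    design: StudyDesign,
    effects: GroupEffects,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Per-sample soil chemistry records obeying the fractionation identities.

    C_org is lognormal around the group mean with coefficient of variation
    ``noise_cv``; the extractable and humified fractions are generated as
    noisy *ratios* of the level above, so C_HAFA <= C_ext <= C_org holds by
    construction and C_NH = C_ext - C_HAFA exactly.
    """
    if not 0 <= noise_cv < 0.5:
        raise ValueError("noise_cv must lie in [0, 0.5)")
    rng = _stream_rng(seed, "chemistry")
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    out: dict[str, dict[str, float]] = {}
    for s in design.samples:
        c_org_m, c_ext_m, c_hafa_m, c_mic_m = effects[
            (s.land_use, s.season)
        ].chemistry_means
        mult = rng.lognormal(-0.5 * sigma**2, sigma, size=4) if sigma > 0 else np.ones(4)
        c_org = c_org_m * mult[0]
        ext_frac = min(c_ext_m / c_org_m * mult[1], 1.0)
        hum_frac = min(c_hafa_m / c_ext_m * mult[2], 1.0)
        c_ext = c_org * ext_frac
        c_hafa = c_ext * hum_frac
        c_mic = c_mic_m * mult[3]
        out[s.sample_id] = {
            "C_org": float(c_org),
            "C_ext": float(c_ext),
            "C_HAFA": float(c_hafa),
            "C_NH": float(c_ext - c_hafa),
            "C_mic": float(c_mic),
        }
    return out
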