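"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` wires the stages together: simulate (or load) study inputs,
compute per-sample ecophysiological indices with the land-use x season ANOVA,
call and match fingerprint bands with per-lane diversity indices and pairwise
similarity matrices, cluster samples (UPGMA + cophenetic correlation, Newick
export), run the group heat-map ordering and PCA, derive soil carbon and
microbial activity indicators, and emit a per-group summary.  Every run
writes a machine-readable copy of the fully resolved configuration next to
its outputs so results are reproducible from the config and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import ecophysiology as eco
from . import fingerprint as fp
from . import io as sio
from . import soilcarbon as sc
from . import synthetic as syn

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("soilecol")


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    Defaults reproduce the balanced 5 land-use x 2 season x 5 replicate
    simulated study.  ``log_base`` applies to both the EP index and Shannon
    H'; ``intensity_basis`` selects peak height or peak area as band
    abundance.
    """

    seed: int = 0
    n_replicates: int = 5
    outdir: str = "soilecol_out"
    log_base: float = math.e
    intensity_basis: str = "height"
    band_tolerance: float = 0.01
    pca_standardize: bool = True
    season_effect: float = 0.8
    land_use_effect: float = 0.6
    pool_size: int = 40
    colony_total_mean: float = 150.0
    colony_dispersion: float = 0.2
    dilution_exponent: int = 4
    respiration_noise_sd: float = 10.0
    chemistry_noise_cv: float = 0.1
    normalize_before_average: bool = False
    # optional pre-existing inputs (TSV paths); when unset, data are simulated
    colony_counts_path: str | None = None
    chemistry_path: str | None = None
    respiration_path: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    indices: pd.DataFrame  # per-sample table of all derived quantities
    group_summary: pd.DataFrame
    anova_ep: eco.AnovaResult
    dendrogram: cl.Dendrogram
    cophenetic_r: float
    heatmap_dendrogram: cl.Dendrogram
    pca: cl.PCAResult
    outputs: dict[str, Path] = field(default_factory=dict)


def _design_frame(design: syn.StudyDesign) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design.samples],
            "land_use": [s.land_use for s in design.samples],
            "season": [s.season for s in design.samples],
            "replicate": [s.replicate for s in design.samples],
        }
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    logger.info("pipeline start: seed=%d outdir=%s", config.seed, config.outdir)

    design = syn.simulate_design(config.n_replicates, seed=config.seed)
    effects = syn.default_group_effects(
        pool_size=config.pool_size,
        season_effect=config.season_effect,
        land_use_effect=config.land_use_effect,
        seed=config.seed,
    )
    df = _design_frame(design)

    # ------------------------------------------------------------------ ecophysiology
    if config.colony_counts_path:
        counts_df = sio.read_table(config.colony_counts_path, schema="colony_counts")
        counts = {
            r.sample_id: np.array([r.day1, r.day2, r.day6])
            for r in counts_df.itertuples()
        }
        dil = {r.sample_id: int(r.dilution_exponent) for r in counts_df.itertuples()}
    else:
        counts = syn.simulate_colony_counts(
            design,
            effects,
            total_mean=config.colony_total_mean,
            dispersion=config.colony_dispersion,
            dilution_exponent=config.dilution_exponent,
            seed=config.seed,
        )
        dil = {sid: config.dilution_exponent for sid in counts}

    ep_vals, r_vals, cfu_vals = {}, {}, {}
    for sid, arr in counts.items():
        cc = eco.ColonyCounts.from_array(arr, dilution_exponent=dil[sid])
        res = eco.ep_index(cc, base=config.log_base)
        ep_vals[sid] = res.ep
        r_vals[sid] = res.r_percent
        cfu_vals[sid] = eco.cfu_per_gram(cc)
    df["cfu_per_g"] = df.sample_id.map(cfu_vals)
    df["log10_cfu"] = np.log10(df["cfu_per_g"].where(df["cfu_per_g"] > 0))
    df["r_percent"] = df.sample_id.map(r_vals)
    df["ep"] = df.sample_id.map(ep_vals)
    anova_ep = eco.anova_factorial(ep_vals, design)

    # ------------------------------------------------------------------ fingerprint
    abund = syn.simulate_band_community(design, effects, seed=config.seed)
    profiles = []
    for s in design.samples:
        a = abund[s.sample_id]
        present = a > 0
        bands = tuple(
            fp.Band(position=float(p), height=float(v), area=float(v))
            for p, v in zip(effects.band_positions[present], a[present])
        )
        profiles.append(fp.BandProfile(bands=bands, lane_id=s.sample_id))
    matrix = fp.match_bands(
        profiles,
        position_tolerance=config.band_tolerance,
        intensity_basis=config.intensity_basis,
    )
    rich, hvals, dvals, jvals = {}, {}, {}, {}
    for i, lane in enumerate(matrix.lanes):
        r = fp.richness(matrix.presence[i])
        rich[lane] = r
        rel = matrix.relative_intensity[i]
        if r > 0:
            h = fp.shannon(rel, base=config.log_base)
            hvals[lane] = h
            dvals[lane] = fp.simpson(rel)
            jvals[lane] = fp.evenness(h, r)
        else:
            hvals[lane] = dvals[lane] = jvals[lane] = float("nan")
    df["richness"] = df.sample_id.map(rich)
    df["shannon"] = df.sample_id.map(hvals)
    df["simpson"] = df.sample_id.map(dvals)
    df["evenness"] = df.sample_id.map(jvals)

    # ------------------------------------------------------------------ clustering
    dist = cl.distance_matrix(
        matrix.presence.astype(float),
        labels=matrix.lanes,
        metric="dice_dissimilarity",
    )
    tree = cl.upgma(dist)
    coph = cl.cophenetic_correlation(tree, dist)

    # ------------------------------------------------------------------ soil carbon
    if config.chemistry_path:
        chem_df = sio.read_table(config.chemistry_path, schema="chemistry")
        chem = {
            r.sample_id: {
                "C_org": r.C_org,
                "C_ext": r.C_ext,
                "C_HAFA": r.C_HAFA,
                "C_NH": r.C_ext - r.C_HAFA,
                "C_mic": r.C_mic,
            }
            for r in chem_df.itertuples()
        }
    else:
        chem = syn.simulate_soil_chemistry(
            design, effects, noise_cv=config.chemistry_noise_cv, seed=config.seed
        )
    if config.respiration_path:
        resp_df = sio.read_table(config.respiration_path, schema="respiration")
        resp = {
            sid: g[["day", "cumulative_CO2_C"]].to_numpy()
            for sid, g in resp_df.groupby("sample_id", sort=False)
        }
    else:
        resp = {}
        for i, s in enumerate(design.samples):
            g = effects[(s.land_use, s.season)]
            resp[s.sample_id] = syn.simulate_respiration(
                g.c0,
                g.k,
                noise_sd=config.respiration_noise_sd,
                monotonize=True,
                seed=config.seed + 1000 + i,
            )

    rows = []
    for s in design.samples:
        c = chem[s.sample_id]
        c_nh, hi, dh, hr = sc.humification_indices(c["C_org"], c["C_ext"], c["C_HAFA"])
        fit = sc.fit_mineralization(resp[s.sample_id])
        c_cum, c_bas = sc.cumulative_basal(resp[s.sample_id])
        mi = sc.microbial_indices(c_bas, c_cum, c["C_mic"], c["C_org"])
        rows.append(
            {
                "sample_id": s.sample_id,
                "C_org": c["C_org"],
                "SOM": sc.som_from_corg(c["C_org"]),
                "C_ext": c["C_ext"],
                "C_HAFA": c["C_HAFA"],
                "C_NH": c_nh,
                "HI": hi,
                "DH_percent": dh,
                "HR_percent": hr,
                "C_mic": c["C_mic"],
                "C0": fit.c0,
                "k": fit.k,
                "C_cum": mi.c_cum,
                "C_bas": mi.c_bas,
                "qCO2": mi.qco2,
                "qM": mi.qm,
                "Cmic_Corg_percent": mi.cmic_corg_percent,
            }
        )
    df = df.merge(pd.DataFrame(rows), on="sample_id")

    # ------------------------------------------------------------- heat map + PCA
    param_cols = [
        "ep",
        "r_percent",
        "log10_cfu",
        "richness",
        "shannon",
        "simpson",
        "C_org",
        "C_ext",
        "C_HAFA",
        "C_NH",
        "HI",
        "DH_percent",
        "HR_percent",
        "C_mic",
        "C0",
        "C_cum",
        "C_bas",
        "qCO2",
        "qM",
    ]
    values = {
        r.sample_id: [getattr(r, c) for c in param_cols] for r in df.itertuples()
    }
    if config.normalize_before_average:
        mat = np.array([values[s.sample_id] for s in design.samples])
        mat = cl.minmax_normalize(mat, axis=0)
        values = {
            s.sample_id: mat[i] for i, s in enumerate(design.samples)
        }
        group_table, groups = cl.group_average(values, design)
        norm = group_table.T  # parameters x groups
    else:
        group_table, groups = cl.group_average(values, design)
        norm = cl.minmax_normalize(group_table.T, axis=1)
    group_labels = [f"{lu}-{season}" for lu, season in groups]
    heat_dist = cl.distance_matrix(norm.T, labels=group_labels, metric="bray_curtis")
    heat_tree = cl.upgma(heat_dist)
    pca_res = cl.pca(group_table, standardize=config.pca_standardize)

    # ------------------------------------------------------------------ summary
    summary = (
        df.drop(columns=["sample_id", "replicate"])
        .groupby(["land_use", "season"], sort=False)
        .mean()
        .reset_index()
    )

    # ------------------------------------------------------------------ outputs
    outputs: dict[str, Path] = {}

    def save(df_, name):
        p = out / name
        sio.write_table(df_, p)
        outputs[name] = p

    save(df, "indices.tsv")
    save(summary, "group_summary.tsv")
    anova_df = pd.DataFrame(
        [
            {
                "term": name,
                "sum_of_squares": t.sum_of_squares,
                "df": t.df,
                "mean_square": t.mean_square,
                "F": t.f_statistic,
                "p_value": t.p_value,
            }
            for name, t in anova_ep.terms.items()
        ]
    )
    save(anova_df, "anova_ep.tsv")
    sio.write_matrix(dist.values, dist.labels, out / "dice_dissimilarity.tsv")
    outputs["dice_dissimilarity.tsv"] = out / "dice_dissimilarity.tsv"
    sio.write_newick(cl.to_newick(tree), out / "samples_upgma.nwk")
    outputs["samples_upgma.nwk"] = out / "samples_upgma.nwk"
    sio.write_newick(cl.to_newick(heat_tree), out / "groups_upgma.nwk")
    outputs["groups_upgma.nwk"] = out / "groups_upgma.nwk"
    heat_df = pd.DataFrame(norm, index=param_cols, columns=group_labels)
    heat_df.insert(0, "parameter", heat_df.index)
    save(heat_df.reset_index(drop=True), "heatmap_normalized.tsv")
    pca_df = pd.DataFrame(
        pca_res.scores[:, : min(5, pca_res.scores.shape[1])],
        columns=[f"PC{i+1}" for i in range(min(5, pca_res.scores.shape[1]))],
    )
    pca_df.insert(0, "group", group_labels)
    save(pca_df, "pca_scores.tsv")
    var_df = pd.DataFrame(
        {
            "component": [f"PC{i+1}" for i in range(pca_res.variance_percent.size)],
            "variance_percent": pca_res.variance_percent,
        }
    )
    save(var_df, "pca_variance.tsv")

    logger.info(
        "pipeline done: %d samples, cophenetic r=%.3f, PC1=%.2f%%",
        len(design),
        coph,
        pca_res.variance_percent[0],
    )
    return PipelineResult(
        config=config,
        indices=df,
        group_summary=summary,
        anova_ep=anova_ep,
        dendrogram=tree,
        cophenetic_r=coph,
        heatmap_dendrogram=heat_tree,
        pca=pca_res,
        outputs=outputs,
    )
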