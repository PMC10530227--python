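"""End-to-end habitat analysis: metrics -> features -> PCA -> clusters -> HDR.

The four analysis steps mirror the study design: (I) correlation-matrix
PCA of the presence cells, (II) VEI Gaussian-mixture clustering of the
presence scores with BIC selection over K, (III) projection of the
absence cells into the presence PC space and soft assignment to the
presence clusters, and (IV) highest-density-region closeness scores for
every cell.  Cluster summaries, presence-vs-absence and between-cluster
tests, and the absence-buffer sensitivity analysis are produced from the
scored table.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from . import features as feat
from . import hdr, metrics, mixture, pca
from .synthetic import IceScapeConfig, generate_bathymetry, generate_icescape

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "summarize_clusters",
    "compare_groups",
    "buffer_sensitivity",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of a full synthetic-data analysis run."""

    icescape: IceScapeConfig = field(default_factory=IceScapeConfig)
    agg_factor: int = 1  # synthetic stacks are generated on the 5-km grid
    q: int = 4
    k_min: int = 2
    k_max: int = 7
    n_starts: int = 10
    tau_strict: float = 0.80
    tau_relaxed: float = 0.59
    closeness_samples: int = 200_000
    buffers_km: tuple[float, ...] = (10.0, 20.0, 30.0)
    alpha: float = 0.05
    seed: int = 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: object
    metrics: metrics.FastIceMetrics
    table: pd.DataFrame  # features + labels + scores + assignments
    pcspace: pca.PCSpace
    model: mixture.VEIMixtureModel
    bic_table: pd.DataFrame
    presence_scores: np.ndarray
    absence_scores: np.ndarray | None
    presence_assign: mixture.CellScores
    absence_assign: mixture.CellScores | None
    presence_truth_ari: float | None
    summary: pd.DataFrame | None
    between_tests: pd.DataFrame | None
    within_tests: pd.DataFrame | None
    buffer_results: dict | None
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as err:  # noqa: BLE001 - re-raise with stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

        return wrapper

    return deco


def summarize_clusters(
    scored: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Median, SD and n per cluster x variable x presence-status.

    ``scored`` must carry 'cluster' (the label retained at the working
    certainty threshold) and 'is_presence'.  Single-member groups get a
    missing SD; clusters empty at the threshold appear with n = 0.
    """
    variables = variables or feat.FEATURE_COLUMNS
    clusters = sorted(int(c) for c in scored["cluster"].unique() if c >= 0)
    rows = []
    for k in clusters:
        for status, flag in (("presence", True), ("absence", False)):
            sub = scored[(scored["cluster"] == k) & (scored["is_presence"] == flag)]
            for v in variables:
                vals = sub[v].to_numpy()
                rows.append(
                    {
                        "cluster": k,
                        "status": status,
                        "variable": v,
                        "n": len(vals),
                        "median": np.median(vals) if len(vals) else np.nan,
                        "sd": np.std(vals, ddof=1) if len(vals) > 1 else np.nan,
                    }
                )
    if not rows:
        warnings.warn("no rows retained at the certainty threshold", stacklevel=2)
    return pd.DataFrame(rows)


def compare_groups(
    scored: pd.DataFrame,
    design: str = "between_clusters",
    alpha: float = 0.05,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Nonparametric group comparisons with Holm adjustment.

    between_clusters: per variable, a Kruskal-Wallis test across
    clusters followed by pairwise two-sided rank-sum (Mann-Whitney)
    tests, Holm-adjusted within the variable.  presence_absence: per
    cluster and variable, a two-sided rank-sum test of presence vs
    absence rows, Holm-adjusted across variables within the cluster.
    Groups with fewer than 2 members are skipped with a note.
    """
    variables = variables or feat.FEATURE_COLUMNS
    clusters = sorted(int(c) for c in scored["cluster"].unique() if c >= 0)
    rows: list[dict] = []

    if design == "between_clusters":
        for v in variables:
            groups = [
                scored.loc[scored["cluster"] == k, v].to_numpy() for k in clusters
            ]
            sizes = [len(g) for g in groups]
            usable = [g for g in groups if len(g) >= 2]
            if len(usable) < 2:
                rows.append({"variable": v, "test": "kruskal", "group_a": "all",
                             "group_b": "", "stat": np.nan, "p_raw": np.nan,
                             "note": "fewer than 2 usable groups"})
                continue
            if np.ptp(np.concatenate(usable)) == 0:  # all values identical
                stat, p = 0.0, 1.0
            else:
                kw = stats.kruskal(*usable)
                stat, p = kw.statistic, kw.pvalue
            rows.append({"variable": v, "test": "kruskal", "group_a": "all",
                         "group_b": "", "stat": stat, "p_raw": p, "note": ""})
            pair_rows = []
            for i, ka in enumerate(clusters):
                for kb in clusters[i + 1:]:
                    ga, gb = groups[clusters.index(ka)], groups[clusters.index(kb)]
                    if len(ga) < 2 or len(gb) < 2:
                        continue
                    if np.ptp(np.concatenate([ga, gb])) == 0:
                        stat, p = 0.0, 1.0
                    else:
                        mw = stats.mannwhitneyu(ga, gb, alternative="two-sided")
                        stat, p = mw.statistic, mw.pvalue
                    pair_rows.append({"variable": v, "test": "ranksum",
                                      "group_a": str(ka), "group_b": str(kb),
                                      "stat": stat, "p_raw": p, "note": ""})
            if pair_rows:
                adj = multipletests([r["p_raw"] for r in pair_rows], method="holm")[1]
                for r, pa in zip(pair_rows, adj):
                    r["p_adj"] = pa
                rows.extend(pair_rows)
    elif design == "presence_absence":
        for k in clusters:
            cl_rows = []
            for v in variables:
                pres = scored.loc[(scored["cluster"] == k) & scored["is_presence"], v].to_numpy()
                absn = scored.loc[(scored["cluster"] == k) & ~scored["is_presence"], v].to_numpy()
                if len(pres) < 2 or len(absn) < 2:
                    rows.append({"cluster": k, "variable": v, "test": "ranksum",
                                 "stat": np.nan, "p_raw": np.nan,
                                 "note": "group with n < 2 skipped"})
                    continue
                if np.ptp(np.concatenate([pres, absn])) == 0:
                    stat, p = 0.0, 1.0
                else:
                    mw = stats.mannwhitneyu(pres, absn, alternative="two-sided")
                    stat, p = mw.statistic, mw.pvalue
                cl_rows.append({"cluster": k, "variable": v, "test": "ranksum",
                                "stat": stat, "p_raw": p, "note": ""})
            if cl_rows:
                adj = multipletests([r["p_raw"] for r in cl_rows], method="holm")[1]
                for r, pa in zip(cl_rows, adj):
                    r["p_adj"] = pa
                rows.extend(cl_rows)
    else:
        raise ValueError(f"unknown design {design!r}")

    out = pd.DataFrame(rows)
    if "p_adj" not in out.columns:
        out["p_adj"] = np.nan
    out["p_adj"] = out["p_adj"].fillna(out["p_raw"])
    out["significant"] = out["p_adj"] < alpha
    return out


def buffer_sensitivity(
    scored: pd.DataFrame,
    emperor_xy: np.ndarray,
    buffers_km: tuple[float, ...] = (10.0, 20.0, 30.0),
    alpha: float = 0.05,
    variables: list[str] | None = None,
) -> dict:
    """Presence-vs-absence tests after removing near-colony absences.

    Reruns the within-cluster comparisons on tables with absences inside
    each buffer removed and reports which significance decisions flip
    relative to the unbuffered analysis.
    """
    base = compare_groups(scored, "presence_absence", alpha, variables)
    key = ["cluster", "variable"]
    results: dict = {"base": base, "buffers": {}, "flips": {}}
    for b in buffers_km:
        filtered = feat.absence_buffer_filter(scored, emperor_xy, b)
        res = compare_groups(filtered, "presence_absence", alpha, variables)
        merged = base.merge(res, on=key, suffixes=("_base", "_buf"))
        flips = merged[
            merged["significant_base"].ne(merged["significant_buf"])
            & merged["note_base"].eq("")
            & merged["note_buf"].eq("")
        ][key + ["significant_base", "significant_buf"]]
        results["buffers"][b] = res
        results["flips"][b] = flips.reset_index(drop=True)
    return results


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False, float_format="%.10g").encode()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis on a synthetic icescape.

    Generates the inputs, derives the seven fast-ice metrics and six
    geographic/biological covariates, fits the presence PCA and the VEI
    mixture (BIC over K = k_min..k_max), assigns presence and projected
    absence cells, computes HDR closeness for all scored cells, and
    summarises/tests the clusters.  With no absence rows, steps III-IV
    are skipped with a warning.  A manifest of seeds, sizes and output
    hashes makes reruns checkable for bit-identity.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]

    gen = _stage("synthetic")(lambda: generate_icescape(
        config.icescape.replace(seed=int(config.icescape.seed + config.seed))
    ))
    stack, truth = gen()
    depth = _stage("bathymetry")(lambda: generate_bathymetry(config.icescape))()

    mets = _stage("metrics")(lambda: metrics.compute_fastice_metrics(stack, config.agg_factor))()
    table = _stage("features")(
        lambda: feat.build_feature_table(mets, depth, truth.colony_points)
    )()

    presence = table[table["is_presence"]]
    absence = table[~table["is_presence"]]
    space = _stage("pca")(lambda: pca.fit_pca(presence, feat.FEATURE_COLUMNS, config.q))()
    pres_scores = space.scores

    model, bic_table = _stage("clustering")(lambda: mixture.select_model(
        pres_scores,
        range(config.k_min, config.k_max + 1),
        n_starts=config.n_starts,
        seed=seeds[0],
    ))()

    pres_assign = mixture.assign(model, pres_scores, config.tau_strict)

    abs_scores = None
    abs_assign = None
    if len(absence):
        abs_scores = _stage("projection")(lambda: pca.project(space, absence))()
        abs_assign = mixture.assign(model, abs_scores, config.tau_strict)
    else:
        warnings.warn("no absence rows: skipping projection and absence scoring", stacklevel=2)

    all_scores = pres_scores if abs_scores is None else np.vstack([pres_scores, abs_scores])
    close = _stage("closeness")(lambda: hdr.closeness(
        model, all_scores, n_samples=config.closeness_samples, seed=seeds[1]
    ))()

    # scored table in presence-first order
    ordered = pd.concat([presence, absence]).reset_index(drop=True)
    post = pres_assign.posterior if abs_assign is None else np.vstack(
        [pres_assign.posterior, abs_assign.posterior]
    )
    scored = ordered.copy()
    scored["cluster_map"] = np.argmax(post, axis=1)
    scored["a"] = post.max(axis=1)
    scored["u"] = 1.0 - scored["a"]
    scored["cluster"] = np.where(scored["a"] >= config.tau_strict, scored["cluster_map"], -1)
    scored["cluster_relaxed"] = np.where(
        scored["a"] >= config.tau_relaxed, scored["cluster_map"], -1
    )
    scored["p_hdr"] = close.p
    scored["c_hdr"] = close.c
    for qi in range(config.q):
        scored[f"PC{qi + 1}"] = all_scores[:, qi]

    # truth recovery on presence cells (synthetic ground truth available)
    pres_cells = presence[["row", "col"]].to_numpy()
    truth_labels = truth.class_map[pres_cells[:, 0], pres_cells[:, 1]]
    ari = float(adjusted_rand_score(truth_labels, pres_assign.z))

    retained = scored[scored["cluster"] >= 0]
    summary = summarize_clusters(retained)
    between = compare_groups(retained, "between_clusters", config.alpha)
    within = compare_groups(retained, "presence_absence", config.alpha) if len(absence) else None
    emperor_xy = truth.colony_points.query("species == 'emperor'")[["x_km", "y_km"]].to_numpy()
    buffers = (
        buffer_sensitivity(retained, emperor_xy, config.buffers_km, config.alpha)
        if len(absence)
        else None
    )

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_cells": int(len(table)),
        "n_presence": int(len(presence)),
        "n_absence": int(len(absence)),
        "selected_K": int(model.K),
        "loglik": float(model.loglik),
        "bic": float(model.bic),
        "icl": float(model.icl),
        "presence_truth_ari": ari,
        "thresholds": {"strict": config.tau_strict, "relaxed": config.tau_relaxed},
        "hashes": {
            "features": _hash_frame(table),
            "scored": _hash_frame(scored),
            "bic_table": _hash_frame(bic_table.drop(columns=["error"])),
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "features.csv", index=False)
        scored.to_csv(outdir / "scored_cells.csv", index=False)
        bic_table.to_csv(outdir / "bic_table.csv", index=False)
        summary.to_csv(outdir / "cluster_summary.csv", index=False)
        between.to_csv(outdir / "between_cluster_tests.csv", index=False)
        if within is not None:
            within.to_csv(outdir / "presence_absence_tests.csv", index=False)
        space.loadings_frame().to_csv(outdir / "pca_loadings.csv")
        with open(outdir / "model.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=config,
        truth=truth,
        metrics=mets,
        table=scored,
        pcspace=space,
        model=model,
        bic_table=bic_table,
        presence_scores=pres_scores,
        absence_scores=abs_scores,
        presence_assign=pres_assign,
        absence_assign=abs_assign,
        presence_truth_ari=ari,
        summary=summary,
        between_tests=between,
        within_tests=within,
        buffer_results=buffers,
        manifest=manifest,
    )
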