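"""End-to-end cohort analysis drivers.

``run_whole_bm`` reproduces the whole bone-marrow analysis track (consensus
detection, joint normalization, proliferative indexes, MM-vs-HC differential
expression, median and reference stratification, per-circRNA survival
screening, 3-group clustering) and ``run_purified`` the CD138-purified
plasma-cell track (purity filtering, all three indexes, index-vs-circRNA
correlations, per-index Cox fits, abundance screening, 3-group clustering
with pairwise hazard ratios). Both are deterministic given their inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage

from . import circconsensus, grouptests, normquant, prolifscore, survanalysis
from .containers import ExpressionMatrix
from .simcohort import read_cohort

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run (flat YAML on disk)."""

    mode: str
    input_dir: str
    output_dir: str
    min_reads: int = 2
    minprop: float = 0.2
    top_k: int = 100
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    purity_threshold: float = 0.85
    seed: int = 0
    signatures_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity_threshold <= 1.0:
            raise ValueError("purity_threshold must lie in [0, 1]")
        if self.mode not in ("whole_bm", "purified_pc"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: Path | str, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class AnalysisReport:
    """JSON-serializable record of every analysis stage."""

    mode: str
    stages: dict = field(default_factory=dict)

    def to_json(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            json.dump({"mode": self.mode, "stages": self.stages}, fh,
                      indent=1, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row (x - mean)/sd with sample sd (n-1); constant rows are an error."""
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs at least two samples")
    sd = matrix.std(axis=1, ddof=1)
    bad = sd[sd == 0]
    if len(bad):
        raise ValueError(f"constant row(s): {list(bad.index)[:5]}")
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


def cluster_groups(z_matrix: pd.DataFrame, k: int = 3) -> pd.Series:
    """Agglomerative clustering of sample columns (Euclidean, complete linkage).

    Columns are processed in lexicographic sample order so ties break
    deterministically; labels are renumbered 1..k by first occurrence.
    """
    if k > z_matrix.shape[1]:
        raise ValueError("k exceeds the number of samples")
    cols = sorted(z_matrix.columns)
    data = z_matrix[cols].to_numpy(dtype=float).T
    tree = linkage(data, method="complete", metric="euclidean")
    raw = fcluster(tree, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for value in raw:
        if value not in relabel:
            relabel[value] = len(relabel) + 1
        labels.append(relabel[value])
    out = pd.Series(labels, index=cols, name="cluster")
    return out[z_matrix.columns]


def filter_purity(metadata: pd.DataFrame, purity_threshold: float) -> pd.DataFrame:
    """Retain samples with estimated purity >= threshold (boundary inclusive)."""
    if "purity" not in metadata.columns:
        raise ValueError("purity column required in purified mode")
    purity = pd.to_numeric(metadata["purity"], errors="coerce")
    if purity.isna().all():
        raise ValueError("purity column required in purified mode")
    keep = metadata[purity >= purity_threshold]
    if keep.empty:
        raise ValueError("no samples pass the purity threshold")
    log.info("purity filter: removed %d of %d samples", len(metadata) - len(keep), len(metadata))
    return keep


def _load_inputs(config: AnalysisConfig):
    linear, calls, db, metadata, truth = read_cohort(config.input_dir)
    signatures = prolifscore.load_signatures(config.signatures_path)
    return linear, calls, db, metadata, truth, signatures


def _normalize(linear: ExpressionMatrix, cs: circconsensus.ConsensusSet, samples: list[str]):
    lin_counts = linear.values[samples]
    circ_counts = cs.circ_counts[samples]
    sf = normquant.combined_size_factors(circ_counts, lin_counts)
    tpm = normquant.tpm(
        ExpressionMatrix(values=lin_counts, feature_meta=linear.feature_meta)
    )
    log2tpm = normquant.log2_tpm(tpm)
    total_circ = normquant.total_circ_expression(circ_counts, sf)
    return circ_counts, sf, tpm, log2tpm, total_circ


def _survival_for(metadata: pd.DataFrame, samples: list[str]) -> survanalysis.SurvivalData:
    frame = metadata.loc[samples]
    return survanalysis.SurvivalData.from_frame(frame)


def _strata_logrank(d, labels: pd.Series):
    if labels.nunique() < 2:
        return None
    res = survanalysis.logrank_test(d, labels)
    km = {
        level: survanalysis.km_estimate(
            survanalysis.SurvivalData(d.time[(labels == level).to_numpy()],
                                      d.event[(labels == level).to_numpy()])
        ).median()
        for level in sorted(labels.unique())
    }
    return {"statistic": res.statistic, "p": res.p_value, "km_median": km,
            "n": labels.value_counts().to_dict()}


def _write_tables(outdir: Path, tables: dict[str, pd.DataFrame]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t")


def run_whole_bm(config: AnalysisConfig) -> AnalysisReport:
    """Whole bone-marrow cohort analysis (MM patients vs healthy controls)."""
    if config.mode != "whole_bm":
        raise ValueError("config.mode must be whole_bm")
    linear, calls, db, metadata, _truth, signatures = _load_inputs(config)
    mm = sorted(metadata.index[metadata["diagnosis"] == "MM"])
    hc = sorted(metadata.index[metadata["diagnosis"] == "HC"])
    if not hc:
        raise ValueError("whole_bm analysis requires healthy controls")
    samples = mm + hc
    report = AnalysisReport(mode="whole_bm")
    outdir = Path(config.output_dir)

    cs = circconsensus.consensus_filter(calls, db, min_reads=config.min_reads)
    n_caller_a = len({str(c.circ_id) for c in calls if c.caller == circconsensus.CALLER_A})
    report.stages["consensus"] = {
        "n_caller_a": n_caller_a,
        "n_consensus": len(cs.ids),
        "circ_exceeds_linear_fraction": circconsensus.circ_exceeds_linear_fraction(cs),
        "isoform_count_mode": int(circconsensus.isoforms_per_gene(cs).mode().iloc[0]),
    }

    circ_counts, sf, tpm, log2tpm, total_circ = _normalize(linear, cs, samples)
    report.stages["normalization"] = {
        "n_samples": len(samples),
        "size_factor_range": [float(sf.min()), float(sf.max())],
    }

    scores = {}
    for name in ("bergsagel", "shaughnessy"):
        scores[name] = prolifscore.prolif_index(log2tpm, signatures[name], cohort_mode="whole_bm")
    turnover = prolifscore.turnover_ratio(tpm)
    mw_circ = grouptests.mann_whitney(total_circ[mm], total_circ[hc])
    report.stages["group_comparisons"] = {
        "total_circ_mm_vs_hc": {"statistic": mw_circ.statistic, "p": mw_circ.p_value,
                                "mm_mean": float(total_circ[mm].mean()),
                                "hc_mean": float(total_circ[hc].mean())},
        "indexes_mm_vs_hc": {
            name: dataclasses.asdict(grouptests.mann_whitney(scores[name][mm], scores[name][hc]))
            for name in scores
        },
    }

    de = grouptests.diff_expr(circ_counts, sf, mm, hc,
                              lfc_threshold=config.lfc_threshold, alpha=config.alpha)
    report.stages["diff_expr"] = {
        "n_tested": int(len(de)),
        "n_up_mm": int((de["significant"] & (de["log2FC"] > 0)).sum()),
        "n_down_mm": int((de["significant"] & (de["log2FC"] < 0)).sum()),
    }

    d_mm = _survival_for(metadata, mm)
    strata = {}
    for name, score in scores.items():
        med = prolifscore.stratify_median(score[mm])
        strata[f"{name}_median"] = _strata_logrank(d_mm, med)
        ref = prolifscore.stratify_reference(score[mm], score[hc])
        strata[f"{name}_reference"] = _strata_logrank(d_mm, ref)
    turn_med = prolifscore.stratify_median(turnover[mm])
    strata["turnover_median"] = _strata_logrank(d_mm, turn_med)
    report.stages["stratified_survival"] = strata

    screens = {}
    screen_tables = {}
    for mode_name, kwargs in (
        ("abundance", {"rank_by": "abundance"}),
        ("de_table", {"rank_by": "de_table", "de_table": de}),
    ):
        sr = survanalysis.survival_screen(circ_counts[mm], sf[mm], d_mm,
                                          top_k=config.top_k, minprop=config.minprop, **kwargs)
        screens[mode_name] = {"n_screened": int(len(sr.table)),
                              "n_significant": sr.n_significant,
                              "n_favourable_high": sr.n_favourable_high}
        screen_tables[f"screen_{mode_name}"] = sr.table
    report.stages["survival_screen"] = screens

    top_de = de.sort_values(["q", "p"], kind="stable").index[:50]
    circ_norm = circ_counts.loc[top_de] / sf
    sig_genes = [g for g in signatures["shaughnessy"].genes if g in log2tpm.index]
    z_features = pd.concat([circ_norm, log2tpm.loc[sig_genes]])
    z_features = z_features[z_features.std(axis=1, ddof=1) > 0]
    clusters = cluster_groups(zscore_rows(z_features), k=3)
    mm_clusters = clusters[mm]
    cluster_surv = None
    if mm_clusters.nunique() >= 2:
        cluster_surv = _strata_logrank(d_mm, mm_clusters.astype(str))
    report.stages["cluster_groups"] = {
        "sizes": clusters.value_counts().to_dict(),
        "mm_survival": cluster_surv,
    }

    _write_tables(outdir, {
        "consensus_circ_counts": cs.circ_counts,
        "size_factors": sf.to_frame(),
        "tpm": tpm,
        "index_scores": pd.DataFrame(scores).assign(turnover=turnover),
        "de_table": de,
        **screen_tables,
        "cluster_labels": clusters.to_frame(),
    })
    report.to_json(outdir / "report.json")
    return report


def run_purified(config: AnalysisConfig) -> AnalysisReport:
    """CD138-purified plasma-cell cohort analysis."""
    if config.mode != "purified_pc":
        raise ValueError("config.mode must be purified_pc")
    linear, calls, db, metadata, _truth, signatures = _load_inputs(config)
    metadata = filter_purity(metadata, config.purity_threshold)
    samples = sorted(metadata.index)
    report = AnalysisReport(mode="purified_pc")
    outdir = Path(config.output_dir)
    report.stages["purity_filter"] = {"n_retained": len(samples)}

    calls = [c for c in calls if c.sample_id in set(samples)]
    cs = circconsensus.consensus_filter(calls, db, min_reads=config.min_reads)
    report.stages["consensus"] = {
        "n_consensus": len(cs.ids),
        "circ_exceeds_linear_fraction": circconsensus.circ_exceeds_linear_fraction(cs),
    }

    circ_counts, sf, tpm, log2tpm, total_circ = _normalize(linear, cs, samples)

    scores = {
        name: prolifscore.prolif_index(log2tpm, signatures[name], cohort_mode="purified_pc")
        for name in ("bergsagel", "shaughnessy", "hose")
    }
    turnover = prolifscore.turnover_ratio(tpm)

    correlations = {}
    for name, score in {**scores, "turnover": turnover}.items():
        rho, p = grouptests.spearman(score[samples], total_circ[samples])
        correlations[name] = {"rho": rho, "p": p}
    report.stages["index_circ_correlation"] = correlations

    d = _survival_for(metadata, samples)
    strata = {}
    cox = {}
    for name, score in {**scores, "turnover": turnover}.items():
        labels = prolifscore.stratify_median(score[samples])
        strata[f"{name}_median"] = _strata_logrank(d, labels)
        try:
            fit = survanalysis.cox_univariate(d, (labels == "high").astype(float).to_numpy())
            cox[name] = {"beta": fit.beta, "hr": fit.hr, "se": fit.se, "p": fit.wald_p}
        except (ValueError, survanalysis.ConvergenceError) as exc:
            cox[name] = {"error": str(exc)}
    report.stages["stratified_survival"] = strata
    report.stages["cox_high_vs_low"] = cox

    sr = survanalysis.survival_screen(circ_counts, sf, d, top_k=config.top_k,
                                      rank_by="abundance", minprop=config.minprop)
    report.stages["survival_screen"] = {
        "n_screened": int(len(sr.table)),
        "n_significant": sr.n_significant,
        "n_favourable_high": sr.n_favourable_high,
    }

    fav = sr.table[(sr.table["p"].notna()) & (sr.table["direction"] == "favourable_high")]
    top20 = list(fav.sort_values("p", kind="stable").index[:20])
    sig_genes = [g for g in signatures["bergsagel"].genes if g in log2tpm.index]
    z_features = pd.concat([circ_counts.loc[top20] / sf, log2tpm.loc[sig_genes]])
    z_features = z_features[z_features.std(axis=1, ddof=1) > 0]
    clusters = cluster_groups(zscore_rows(z_features), k=3)

    cluster_stage: dict = {"sizes": clusters.value_counts().to_dict()}
    if clusters.nunique() >= 2:
        cluster_stage["survival"] = _strata_logrank(d, clusters.astype(str))
        # phenotype labels by mean index score and mean circRNA burden
        mean_index = pd.DataFrame(scores).mean(axis=1)
        phenotype = {}
        for level in sorted(clusters.unique()):
            members = clusters.index[clusters == level]
            phenotype[int(level)] = {
                "mean_index": float(mean_index[members].mean()),
                "mean_total_circ": float(total_circ[members].mean()),
                "n": int(len(members)),
            }
        cluster_stage["phenotype"] = phenotype
        pairwise = {}
        levels = sorted(clusters.unique())
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                mask = clusters.isin([a, b])
                sub = metadata.loc[clusters.index[mask]]
                d_sub = survanalysis.SurvivalData.from_frame(sub)
                try:
                    fit = survanalysis.cox_univariate(
                        d_sub, (clusters[mask] == a).astype(float).to_numpy())
                    pairwise[f"{a}_vs_{b}"] = {"hr": fit.hr, "p": fit.wald_p}
                except (ValueError, survanalysis.ConvergenceError) as exc:
                    pairwise[f"{a}_vs_{b}"] = {"error": str(exc)}
        cluster_stage["pairwise_cox"] = pairwise
    report.stages["cluster_groups"] = cluster_stage

    _write_tables(outdir, {
        "consensus_circ_counts": cs.circ_counts,
        "size_factors": sf.to_frame(),
        "tpm": tpm,
        "index_scores": pd.DataFrame(scores).assign(turnover=turnover),
        "screen_abundance": sr.table,
        "cluster_labels": clusters.to_frame(),
    })
    report.to_json(outdir / "report.json")
    return report
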