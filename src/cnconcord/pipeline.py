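"""End-to-end pipeline: calls -> Z-scores -> tendencies -> statistics ->
concordant genes -> survival, with a checksummed run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cn, concordance, simulate, stats, survival, tendency, zscores
from .config import PipelineConfig

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_calls(config: PipelineConfig) -> pd.DataFrame:
    if config.cn_mode == "gistic":
        return cn.calls_from_gistic(simulate.read_matrix(config.calls))
    absolute = simulate.read_matrix(config.absolute_cn)
    ploidy = pd.read_csv(config.ploidy, sep="\t",
                         index_col="sample")["ploidy"]
    return cn.calls_from_picnic(absolute, ploidy).astype(float)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all result tables plus a manifest.

    Reruns with identical inputs and seed reproduce identical file
    checksums.  Any stage failure propagates with the stage name
    prepended.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", float_format=FLOAT_FMT, **kwargs)
        written.append(path)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # -- copy-number harmonization --------------------------------------
    calls = stage("cn_calls", load_calls, config)
    expression = simulate.read_matrix(config.expression)

    # -- diploid-referenced Z-scores ------------------------------------
    zmat = stage("expression_z", zscores.compute_z, expression, calls,
                 min_diploid=config.min_diploid,
                 log2_offset=config.log2_offset)
    calls = calls.loc[zmat.z.index, zmat.z.columns]
    emit(zmat.z, "zscores.tsv", index_label="gene", na_rep="NA")
    emit(zmat.stats[["diploid_n", "valid", "reason"]], "gene_validity.tsv",
         index_label="gene")
    degs = zscores.call_degs(zmat, threshold=config.deg_threshold)

    # -- tendency classification ----------------------------------------
    table = stage("tendency_concordance", tendency.classify_tendency,
                  calls, degs, zmat.valid_genes)
    emit(table.to_long(), "tendency_long.tsv", index=False)
    emit(table.gene_counts, "gene_counts.tsv", index_label="gene")
    grouping = None
    if config.grouping is not None:
        grouping = pd.read_csv(config.grouping, sep="\t",
                               index_col="sample")["cohort"]
    fractions = tendency.cohort_tendency_fractions(
        table, calls, grouping, zmat.valid_genes)
    emit(fractions, "cohort_summary.tsv")

    # -- association statistics -----------------------------------------
    assoc = stage("correlation_stats", stats.gene_associations, calls,
                  zmat.z, zmat.valid_genes)
    emit(assoc, "gene_association.tsv", index_label="gene", na_rep="NA")
    fit = stats.cohort_fit(zmat.z, calls, zmat.valid_genes)
    emit(pd.DataFrame([{"slope": fit.slope, "intercept": fit.intercept,
                        "r": fit.r, "p": fit.p,
                        "n_levels": fit.n_levels}]),
         "cohort_fit.tsv", index=False)

    # -- AUG / DDG identification ---------------------------------------
    if config.threshold_mode == "fixed":
        thresholds = concordance.ConcordanceThresholds(
            config.fixed_rho_min_aug, config.fixed_count_min_aug,
            config.fixed_rho_min_ddg, config.fixed_count_min_ddg,
            config.ratio_min)
    else:
        onco = concordance.load_reference_list(
            config.oncogene_list if config.oncogene_list else "oncogenes")
        tsg = concordance.load_reference_list(
            config.tsg_list if config.tsg_list else "tsgs")
        thresholds = stage("concordant_genes", concordance.calibrate_thresholds,
                           table.gene_counts, assoc, onco, tsg,
                           config.ratio_min)
    gc = stage("concordant_genes", concordance.identify_aug_ddg,
               table.gene_counts, assoc, thresholds)
    emit(gc, "concordant_genes.tsv", index_label="gene", na_rep="NA")

    chrom = pd.DataFrame(columns=["n_genes", "fraction"])
    if config.annotation is not None:
        annotation = pd.read_csv(config.annotation, sep="\t",
                                 index_col="gene",
                                 dtype={"chromosome": str})["chromosome"]
        chrom = concordance.chromosome_distribution(gc, annotation)
    emit(chrom, "chromosome_distribution.tsv", index_label="chromosome")

    # -- survival stratification ----------------------------------------
    surv = pd.DataFrame(
        columns=["gene", "tendency", "n_carrier", "n_other", "chisq", "p",
                 "skipped", "p_adj"])
    if config.clinical is not None:
        clinical = pd.read_csv(config.clinical, sep="\t")
        pairs = ([(g, "AU") for g in concordance.rank_top_concordant(
                     gc, config.max_survival_genes, "AUG")]
                 if (gc["status"] == "AUG").any() else [])
        pairs += ([(g, "DD") for g in concordance.rank_top_concordant(
                      gc, config.max_survival_genes, "DDG")]
                  if (gc["status"] == "DDG").any() else [])
        if pairs:
            surv = stage("survival_analysis", survival.survival_scan,
                         table.labels, clinical, pairs)
    emit(surv, "survival_results.tsv", index=False)

    # -- manifest --------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "thresholds": dataclasses.asdict(thresholds),
        "n_genes": int(len(calls.index)),
        "n_samples": int(len(calls.columns)),
        "n_valid_genes": int(len(zmat.valid_genes)),
        "total_variant_cn": table.total_variant_cn,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@dataclasses.dataclass
class CohortAnalysis:
    """In-memory results of all analysis stages for one cohort."""

    calls: pd.DataFrame
    zmat: zscores.ZScoreMatrix
    degs: pd.DataFrame
    table: tendency.TendencyTable
    fractions: pd.DataFrame
    assoc: pd.DataFrame
    fit: stats.LinearFit
    thresholds: concordance.ConcordanceThresholds
    gene_concordance: pd.DataFrame


def analyze_cohort(cohort: simulate.SyntheticCohort,
                   min_diploid: int = 3, deg_threshold: float = 2.0,
                   thresholds: concordance.ConcordanceThresholds | None = None,
                   ) -> CohortAnalysis:
    """Run every analysis stage on an in-memory synthetic cohort.

    Unless explicit ``thresholds`` are given, the AUG/DDG thresholds are
    calibrated from the cohort's planted calibration-reference gene tiers
    (``ref_oncogene`` / ``ref_tsg`` truth labels).
    """
    calls = cohort.calls.astype(float)
    zmat = zscores.compute_z(cohort.expression, calls,
                             min_diploid=min_diploid)
    degs = zscores.call_degs(zmat, threshold=deg_threshold)
    table = tendency.classify_tendency(calls, degs, zmat.valid_genes)
    fractions = tendency.cohort_tendency_fractions(
        table, calls, valid_genes=zmat.valid_genes)
    assoc = stats.gene_associations(calls, zmat.z, zmat.valid_genes)
    fit = stats.cohort_fit(zmat.z, calls, zmat.valid_genes)
    if thresholds is None:
        truth = cohort.truth
        onco = truth.index[truth["planted"] == "ref_oncogene"].tolist()
        tsg = truth.index[truth["planted"] == "ref_tsg"].tolist()
        thresholds = concordance.calibrate_thresholds(
            table.gene_counts, assoc, onco, tsg)
    gc = concordance.identify_aug_ddg(table.gene_counts, assoc, thresholds)
    return CohortAnalysis(calls=calls, zmat=zmat, degs=degs, table=table,
                          fractions=fractions, assoc=assoc, fit=fit,
                          thresholds=thresholds, gene_concordance=gc)


def recovery_metrics(analysis: CohortAnalysis,
                     truth: pd.DataFrame) -> dict:
    """Planted-truth recovery of the AUG/DDG classifier.

    Calibration-reference genes are excluded from both sensitivity and
    false-discovery computations (they set the thresholds, so scoring
    them would test the calibration set).
    """
    gc = analysis.gene_concordance
    eval_genes = truth.index[~truth["planted"].isin(
        ["ref_oncogene", "ref_tsg"])]
    g = gc.loc[eval_genes]
    t = truth.loc[eval_genes]
    out = {}
    for cls in ("AUG", "DDG"):
        true = set(t.index[t["planted"] == cls])
        called = set(g.index[g["status"] == cls])
        out[f"{cls.lower()}_sensitivity"] = (
            len(true & called) / len(true) if true else float("nan"))
        out[f"{cls.lower()}_fdp"] = (
            len(called - true) / len(called) if called else 0.0)
    confusions = int(
        (gc.loc[truth["planted"] == "AUG", "status"] == "DDG").sum()
        + (gc.loc[truth["planted"] == "DDG", "status"] == "AUG").sum())
    out["aug_ddg_confusions"] = confusions
    return out


REPORT_REQUIRES = ("manifest.json", "gene_association.tsv", "cohort_fit.tsv",
                   "cohort_summary.tsv", "concordant_genes.tsv",
                   "zscores.tsv")


def summary_report(run_dir: str | Path) -> dict:
    """Numeric summary of a completed run.

    Reports the fraction of genes with positive rho, the fit-r
    distribution, per-cohort tendency fractions, AUG/DDG counts, the
    Welch comparison of amplified- vs deleted-event Z-scores, and the
    cohort-level median-Z fit.  Missing artifacts raise with a list of
    what is absent.
    """
    run_dir = Path(run_dir)
    missing = [n for n in REPORT_REQUIRES if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run at {run_dir}: missing {missing}")
    with open(run_dir / "manifest.json") as fh:
        manifest = json.load(fh)

    assoc = pd.read_csv(run_dir / "gene_association.tsv", sep="\t",
                        index_col="gene", na_values="NA")
    fit = pd.read_csv(run_dir / "cohort_fit.tsv", sep="\t").iloc[0]
    fractions = pd.read_csv(run_dir / "cohort_summary.tsv", sep="\t",
                            index_col="cohort")
    gc = pd.read_csv(run_dir / "concordant_genes.tsv", sep="\t",
                     index_col="gene", na_values="NA")

    fit_r = assoc["fit_r"].dropna()
    report = {
        "seed": manifest["seed"],
        "n_valid_genes": manifest["n_valid_genes"],
        "positive_rho_fraction": stats.positive_rho_fraction(assoc),
        "fit_r_mean": float(fit_r.mean()) if len(fit_r) else float("nan"),
        "fit_r_frac_above_0.8": (float((fit_r > 0.8).mean())
                                 if len(fit_r) else float("nan")),
        "cohort_fit_r": float(fit["r"]),
        "cohort_fit_slope": float(fit["slope"]),
        "cohort_fit_p": float(fit["p"]),
        "n_aug": int((gc["status"] == "AUG").sum()),
        "n_ddg": int((gc["status"] == "DDG").sum()),
        "tendency_fractions": {
            str(idx): {k: (None if pd.isna(row[k]) else float(row[k]))
                       for k in ("frac_AU", "frac_AD", "frac_DU", "frac_DD")}
            for idx, row in fractions.iterrows()},
    }

    # Welch comparison of Z at amplified vs deleted events
    z = pd.read_csv(run_dir / "zscores.tsv", sep="\t", index_col="gene",
                    na_values="NA")
    config = manifest["config"]
    cfg_like = dataclasses.replace(
        PipelineConfig(expression=Path(config["expression"]),
                       output_dir=run_dir,
                       cn_mode=config["cn_mode"],
                       calls=Path(config["calls"]) if config["calls"] else None,
                       absolute_cn=(Path(config["absolute_cn"])
                                    if config["absolute_cn"] else None),
                       ploidy=(Path(config["ploidy"])
                               if config["ploidy"] else None)))
    calls = load_calls(cfg_like).loc[z.index, z.columns]
    amp_mask, del_mask = cn.variant_masks(calls)
    zv = z.to_numpy(dtype=float)
    z_amp = zv[amp_mask & np.isfinite(zv)]
    z_del = zv[del_mask & np.isfinite(zv)]
    if z_amp.size >= 2 and z_del.size >= 2:
        cmpr = stats.welch_t(z_amp, z_del)
        report["welch_amp_vs_del"] = {
            "t": cmpr.t, "df": cmpr.df, "p": cmpr.p,
            "mean_amplified": cmpr.mean_a, "mean_deleted": cmpr.mean_b}
    else:
        report["welch_amp_vs_del"] = None

    with open(run_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
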