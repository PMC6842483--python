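"""Synthetic paired copy-number / expression / clinical cohorts.

The generator plants the statistical structure the concordance analysis
assumes and nothing more: discrete calls are i.i.d. per (gene, sample)
with amplification more frequent than deletion, dosage-sensitive genes
follow ``expression = baseline + slope * call + noise`` floored at zero,
a configurable fraction of variant events is sign-flipped (discordant),
absolute copy numbers and ploidies are generated by inverting the
ploidy-conditional calling rules so the same cohort exercises both
calling dialects, and survival is exponential with an elevated hazard
for carriers of a planted gene's concordant amplification.

Gene tiers and their truth labels:

======================  =========================================
``AUG`` / ``DDG``       planted strongly concordant genes
``ref_oncogene``        calibration stand-ins for a known-oncogene
                        list (moderate rates, attenuated slopes)
``ref_tsg``             calibration stand-ins for tumor suppressors
``neither``             background genes
======================  =========================================
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .cn import PLOIDY_CUTOFF

COHORT_FILES = ("calls.tsv", "absolute_cn.tsv", "expression.tsv",
                "ploidy.tsv", "clinical.tsv", "annotation.tsv", "truth.tsv")


@dataclass
class SyntheticCohort:
    """In-memory cohort with ground truth."""

    calls: pd.DataFrame          # gene x sample, int in {-2..2}
    absolute_cn: pd.DataFrame    # gene x sample, non-negative int
    ploidy: pd.Series            # per sample, > 0
    expression: pd.DataFrame     # gene x sample, >= 0
    truth: pd.DataFrame          # gene -> dosage, planted
    clinical: pd.DataFrame       # sample, os_time, os_event
    annotation: pd.Series        # gene -> chromosome
    survival_gene: str | None    # planted gene driving the hazard
    survival_carriers: pd.Series  # per sample, bool: concordant amp of it

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def samples(self) -> pd.Index:
        return self.calls.columns


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort; identical config gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_samples
    genes = pd.Index([f"G{i + 1:05d}" for i in range(G)], name="gene")
    samples = pd.Index([f"S{j + 1:04d}" for j in range(S)], name="sample")

    # ---- gene tiers ----------------------------------------------------
    n_sensitive = round(config.dosage_fraction * G)
    perm = rng.permutation(G)
    sensitive_idx = perm[:n_sensitive]
    cut = np.cumsum([config.n_planted_aug, config.n_planted_ddg,
                     config.n_ref_oncogenes, config.n_ref_tsgs])
    aug_idx = sensitive_idx[:cut[0]]
    ddg_idx = sensitive_idx[cut[0]:cut[1]]
    ref_onco_idx = sensitive_idx[cut[1]:cut[2]]
    ref_tsg_idx = sensitive_idx[cut[2]:cut[3]]

    dosage = np.full(G, "insensitive", dtype=object)
    dosage[sensitive_idx] = "sensitive"
    planted = np.full(G, "neither", dtype=object)
    planted[aug_idx] = "AUG"
    planted[ddg_idx] = "DDG"
    planted[ref_onco_idx] = "ref_oncogene"
    planted[ref_tsg_idx] = "ref_tsg"

    # ---- per-gene event rates -----------------------------------------
    amp_p = np.full(G, config.amp_rate)
    del_p = np.full(G, config.del_rate)
    amp_p[aug_idx] = config.aug_amp_rate
    del_p[ddg_idx] = config.ddg_del_rate
    amp_p[ref_onco_idx] = config.ref_amp_rate
    del_p[ref_tsg_idx] = config.ref_del_rate

    # ---- discrete calls, i.i.d. per (gene, sample) ---------------------
    u = rng.random((G, S))
    t_amp = amp_p[:, None]
    t_del = t_amp + del_p[:, None]
    t_gain = t_del + config.gain_rate
    t_hemi = t_gain + config.hemiloss_rate
    calls = np.zeros((G, S), dtype=np.int8)
    calls[u < t_amp] = 2
    calls[(u >= t_amp) & (u < t_del)] = -2
    calls[(u >= t_del) & (u < t_gain)] = 1
    calls[(u >= t_gain) & (u < t_hemi)] = -1

    # ---- expression ----------------------------------------------------
    slopes = np.abs(rng.normal(config.slope_mean, config.slope_sd, G))
    slopes[dosage == "insensitive"] = 0.0
    slopes[ref_onco_idx] *= config.ref_slope_factor
    slopes[ref_tsg_idx] *= config.ref_slope_factor
    baseline = rng.uniform(config.baseline_low, config.baseline_high, G)

    # sign-flip a fraction of variant (+-2) events of sensitive genes
    flip_u = rng.random((G, S))
    variant = np.abs(calls) == 2
    flipped = variant & (flip_u < config.discord_rate)
    effect_sign = np.where(flipped, -1.0, 1.0)

    noise = (rng.normal(0.0, config.noise_sd, (G, S))
             if config.noise_sd > 0 else np.zeros((G, S)))
    expression = (baseline[:, None]
                  + slopes[:, None] * calls * effect_sign + noise)
    np.maximum(expression, 0.0, out=expression)

    # ---- absolute CN + ploidy inverting the ploidy-conditional rules ---
    ploidy = np.where(rng.random(S) < 0.4,
                      rng.uniform(PLOIDY_CUTOFF + 0.1, 4.2, S),
                      rng.uniform(1.8, PLOIDY_CUTOFF, S))
    absolute_cn = _invert_picnic(calls, ploidy, rng)

    # ---- clinical ------------------------------------------------------
    if len(aug_idx):
        survival_gene_i = int(aug_idx[0])
        survival_gene = str(genes[survival_gene_i])
        carriers = (calls[survival_gene_i] == 2) & ~flipped[survival_gene_i]
    else:
        survival_gene = None
        carriers = np.zeros(S, dtype=bool)
    hazard = config.baseline_hazard * np.where(
        carriers, config.survival_hazard_ratio, 1.0)
    event_t = rng.exponential(1.0 / hazard)
    censor_t = rng.exponential(1.0 / config.censoring_hazard, S)
    os_time = np.minimum(event_t, censor_t)
    os_event = (event_t <= censor_t).astype(int)

    chromosomes = rng.choice([str(c) for c in range(1, 23)], size=G)

    return SyntheticCohort(
        calls=pd.DataFrame(calls, index=genes, columns=samples),
        absolute_cn=pd.DataFrame(absolute_cn, index=genes, columns=samples),
        ploidy=pd.Series(ploidy, index=samples, name="ploidy"),
        expression=pd.DataFrame(expression, index=genes, columns=samples),
        truth=pd.DataFrame(
            {"dosage": dosage, "planted": planted,
             "survival_driver": [g == survival_gene for g in genes]},
            index=genes),
        clinical=pd.DataFrame({"sample": samples, "os_time": os_time,
                               "os_event": os_event}),
        annotation=pd.Series(chromosomes, index=genes, name="chromosome"),
        survival_gene=survival_gene,
        survival_carriers=pd.Series(carriers, index=samples,
                                    name="carrier"),
    )


def _invert_picnic(calls: np.ndarray, ploidy: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample absolute copy numbers consistent with each discrete call.

    Amplified (+2): cn in [5, 8] for near-diploid samples, [9, 12]
    otherwise.  Deleted (-2): cn = 0 near-diploid; any integer strictly
    below ploidy - 2.7 otherwise.  Neutral / gain / hemiloss land in the
    complementary neutral band around round(ploidy).
    """
    G, S = calls.shape
    near = ploidy <= PLOIDY_CUTOFF          # per sample
    rp = np.round(ploidy).astype(int)
    near_m = np.broadcast_to(near, (G, S))
    rp_m = np.broadcast_to(rp, (G, S))

    cn = np.array(rp_m, dtype=int)           # neutral default: round(ploidy)

    gain = calls == 1
    cn[gain] = np.where(near_m, np.minimum(rp_m + 1, 4), rp_m + 1)[gain]
    hemi = calls == -1
    hemi_floor = np.ceil(ploidy - PLOIDY_CUTOFF).astype(int)
    hemi_vals = np.where(near_m, np.maximum(rp_m - 1, 1),
                         np.maximum(rp_m - 1,
                                    np.broadcast_to(hemi_floor, (G, S))))
    cn[hemi] = hemi_vals[hemi]

    amp = calls == 2
    amp_vals = np.where(near_m, 5, 9) + rng.integers(0, 4, (G, S))
    cn[amp] = amp_vals[amp]

    dele = calls == -2
    # strictly below ploidy - 2.7 for polyploid samples; 0 near-diploid
    hi = np.maximum(np.ceil(ploidy - PLOIDY_CUTOFF).astype(int), 1)
    del_vals = np.where(near_m, 0,
                        rng.integers(0, np.broadcast_to(hi, (G, S))))
    cn[dele] = del_vals[dele]
    return cn.astype(np.int32)


# ---------------------------------------------------------------------------
# disk round trip


def write_cohort(cohort: SyntheticCohort, directory: str | Path,
                 overwrite: bool = False) -> list[Path]:
    """Write the cohort as the seven canonical TSV files.

    Refuses to clobber existing files unless ``overwrite=True``.
    Matrices are written genes-as-rows with a leading ``gene`` column;
    floats round-trip to full precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [directory / name for name in COHORT_FILES]
    if not overwrite:
        existing = [p for p in paths if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {existing[0]} (pass overwrite=True)")

    def write_matrix(df: pd.DataFrame, path: Path) -> None:
        df.to_csv(path, sep="\t", index_label="gene",
                  float_format="%.17g")

    write_matrix(cohort.calls, directory / "calls.tsv")
    write_matrix(cohort.absolute_cn, directory / "absolute_cn.tsv")
    write_matrix(cohort.expression, directory / "expression.tsv")
    cohort.ploidy.rename("ploidy").to_csv(
        directory / "ploidy.tsv", sep="\t", index_label="sample",
        float_format="%.17g")
    cohort.clinical.to_csv(directory / "clinical.tsv", sep="\t",
                           index=False, float_format="%.17g")
    cohort.annotation.rename("chromosome").to_csv(
        directory / "annotation.tsv", sep="\t", index_label="gene")
    cohort.truth.to_csv(directory / "truth.tsv", sep="\t",
                        index_label="gene")
    return paths


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV matrix (leading ``gene`` column)."""
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.index = df.index.astype(str)
    return df


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    calls = read_matrix(directory / "calls.tsv").astype(np.int8)
    absolute_cn = read_matrix(directory / "absolute_cn.tsv").astype(np.int32)
    expression = read_matrix(directory / "expression.tsv")
    ploidy = pd.read_csv(directory / "ploidy.tsv", sep="\t",
                         index_col="sample")["ploidy"]
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t")
    annotation = pd.read_csv(directory / "annotation.tsv", sep="\t",
                             index_col="gene",
                             dtype={"chromosome": str})["chromosome"]
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", index_col="gene")
    drivers = truth.index[truth["survival_driver"]]
    survival_gene = str(drivers[0]) if len(drivers) else None
    carriers = pd.Series(False, index=calls.columns, name="carrier")
    return SyntheticCohort(
        calls=calls, absolute_cn=absolute_cn, ploidy=ploidy,
        expression=expression, truth=truth, clinical=clinical,
        annotation=annotation, survival_gene=survival_gene,
        survival_carriers=carriers)
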