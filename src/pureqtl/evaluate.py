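"""Scoring scans against simulated truth; purity-noise sweeps; purity-subset checks.

Ground truth for all performance measures is the set of genes simulated with a
nonzero *cancer-cell* eQTL effect: the question being scored is whether a
model attributes eQTLs to cancer cells correctly, not whether it finds any
association in the bulk mixture.  Shared-eQTL groups (identical or similar
effects in both compartments) therefore count as positives; normal-only and
no-eQTL genes count as negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import fit_conventional, run_scan
from .simulate import SimConfig, add_purity_noise, permute_purity, simulate_cohort

__all__ = [
    "PerformanceSummary",
    "classify_performance",
    "noise_sweep",
    "high_purity_comparison",
    "benchmark_replicate",
]


@dataclass
class PerformanceSummary:
    """Confusion-matrix summary of a scan against simulated cancer-eQTL truth."""

    model: str
    fdr_threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    misattributed_by_group: dict = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def true_fdr(self) -> float:
        """Realized FDR among calls; 0 when nothing was called."""
        called = self.tp + self.fp
        return self.fp / called if called else 0.0

    @property
    def fp_normal_driven(self) -> int:
        """False discoveries at genes simulated with a normal-cell eQTL."""
        return sum(
            n for g, n in self.misattributed_by_group.items() if g in (3, "3", "normal_extra")
        )

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "fdr_threshold": self.fdr_threshold,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "true_fdr": self.true_fdr,
            "fp_normal_driven": self.fp_normal_driven,
        }


def classify_performance(
    results: pd.DataFrame, truth: pd.DataFrame, fdr_threshold: float = 0.05
) -> PerformanceSummary:
    """Score a scan result table at q < fdr_threshold against simulated truth.

    Positives are genes with ``beta_cancer != 0``; negatives are genes whose
    simulated cancer effect is exactly zero (normal-only and no-eQTL genes).
    False positives are broken down by truth group to show where
    misattributed eQTLs come from.
    """
    merged = results.merge(truth, on="gene_id", how="left", validate="many_to_one")
    if merged["beta_cancer"].isna().any():
        missing = merged.loc[merged["beta_cancer"].isna(), "gene_id"].tolist()
        raise ValueError(f"genes missing from the truth table: {missing[:5]}")
    called = (merged["q"] < fdr_threshold).fillna(False).to_numpy()
    positive = (merged["beta_cancer"] != 0).to_numpy()

    tp = int((called & positive).sum())
    fp = int((called & ~positive).sum())
    tn = int((~called & ~positive).sum())
    fn = int((~called & positive).sum())
    fp_groups = (
        merged.loc[called & ~positive, "group"].value_counts().to_dict()
    )
    model = str(results["model"].iloc[0]) if len(results) else "unknown"
    return PerformanceSummary(model, fdr_threshold, tp, fp, tn, fn, fp_groups)


def noise_sweep(
    config: SimConfig,
    sd_grid=None,
    seed: int = 0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Interaction-model performance as purity measurement noise grows.

    One cohort is simulated once from ``config`` and reused across the whole
    grid so that only the measured purity changes.  For each noise SD, noise
    is added to the true purity (and quantile-normalized back onto its
    values), the interaction model is re-scanned with the noisy purity, and
    performance at q < fdr_threshold is recorded together with the Pearson
    correlation between the noise-added and original purity vectors.
    """
    if sd_grid is None:
        sd_grid = np.arange(0.01, 1.5 + 1e-9, 0.025)
    cohort = simulate_cohort(config)
    rng_seeds = np.random.SeedSequence(seed).spawn(len(sd_grid))
    rows = []
    for sd, ss in zip(sd_grid, rng_seeds):
        measured = add_purity_noise(cohort.purity, float(sd), np.random.default_rng(ss))
        res = run_scan(
            cohort.bulk, cohort.genotypes, cohort.pairs, purity=measured, model="interaction"
        )
        perf = classify_performance(res, cohort.truth, fdr_threshold)
        r = stats.pearsonr(cohort.purity.to_numpy(), measured.to_numpy())[0]
        rows.append(
            {
                "noise_sd": float(sd),
                "pearson_r": float(r),
                "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
                "true_fdr": perf.true_fdr,
            }
        )
    return pd.DataFrame(rows)


def high_purity_comparison(
    expr: pd.DataFrame,
    geno: pd.DataFrame,
    pairs: pd.DataFrame,
    purity: pd.Series,
    covars: pd.DataFrame | None = None,
    top_fraction: float = 0.10,
) -> dict:
    """Compare a high-purity-subset scan with the interaction model.

    Runs a conventional scan restricted to the ``top_fraction`` of samples
    with the highest purity (selection by purity rank; ties broken by sample
    order, so the subset is deterministic), and correlates its effect sizes
    with (a) interaction-model and (b) full-cohort conventional effect sizes.
    On mixed cohorts the subset effects should resemble the interaction
    model's extrapolated cancer-cell effects more than the bulk estimates.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n_top = max(int(round(top_fraction * len(purity))), 1)
    order = np.lexsort((np.arange(len(purity)), -purity.to_numpy()))
    subset = purity.index[order[:n_top]]
    n_covars = 0 if covars is None else covars.shape[1]
    if n_top <= n_covars + 2:
        raise ValueError(f"high-purity subset of {n_top} samples is too small to fit")

    sub_covars = covars.loc[subset] if covars is not None else None
    subset_scan = run_scan(
        expr.loc[subset], geno.loc[subset], pairs, covars=sub_covars, model="conventional"
    )
    full_conv = run_scan(expr, geno, pairs, covars=covars, model="conventional")
    full_int = run_scan(expr, geno, pairs, purity=purity, covars=covars, model="interaction")

    b_sub = subset_scan["beta1"].to_numpy()
    r_int = stats.pearsonr(b_sub, full_int["beta1"].to_numpy())[0]
    r_conv = stats.pearsonr(b_sub, full_conv["beta1"].to_numpy())[0]
    return {
        "n_subset": n_top,
        "min_subset_purity": float(purity.loc[subset].min()),
        "r_subset_vs_interaction": float(r_int),
        "r_subset_vs_conventional": float(r_conv),
        "subset_scan": subset_scan,
        "conventional_scan": full_conv,
        "interaction_scan": full_int,
    }


def benchmark_replicate(
    seed: int,
    n_samples: int = 1000,
    genes_per_group: int = 100,
    extra_normal_only: int = 500,
    purity_noise_sd: float = 0.1,
    fdr_threshold: float = 0.05,
) -> dict:
    """One replicate of the full simulation benchmark study.

    Runs the default cohort (six architecture groups) through the
    conventional and interaction models, and the augmented cohort (with
    ``extra_normal_only`` additional normal-only eQTL genes) through the
    conventional model, the purity-as-covariate control, the interaction
    model, and the interaction model with a fully permuted purity vector.
    Measured purity for the interaction scans carries quantile-normalized
    Gaussian noise (SD ``purity_noise_sd``).

    Returns a flat dict of performance metrics keyed by
    ``<cohort>_<model>_<metric>``; rates are proportions in [0, 1].
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(4).astype(np.int64) % (2**31)

    out: dict[str, float] = {}

    # default cohort: 6 groups x genes_per_group
    default = simulate_cohort(
        SimConfig(n_samples=n_samples, genes_per_group=genes_per_group, seed=int(seeds[0]))
    )
    conv = run_scan(default.bulk, default.genotypes, default.pairs, model="conventional")
    perf = classify_performance(conv, default.truth, fdr_threshold)
    out.update(
        default_conventional_sensitivity=perf.sensitivity,
        default_conventional_specificity=perf.specificity,
        default_conventional_true_fdr=perf.true_fdr,
        default_conventional_fp=perf.fp,
        default_conventional_fp_normal=perf.fp_normal_driven,
    )

    measured = add_purity_noise(default.purity, purity_noise_sd, int(seeds[1]))
    inter = run_scan(
        default.bulk, default.genotypes, default.pairs, purity=measured, model="interaction"
    )
    perf = classify_performance(inter, default.truth, fdr_threshold)
    out.update(
        default_interaction_sensitivity=perf.sensitivity,
        default_interaction_specificity=perf.specificity,
        default_interaction_true_fdr=perf.true_fdr,
        default_interaction_fp_normal=perf.fp_normal_driven,
    )

    # augmented cohort: + extra normal-only eQTL genes
    augmented = simulate_cohort(
        SimConfig(
            n_samples=n_samples,
            genes_per_group=genes_per_group,
            extra_normal_only=extra_normal_only,
            seed=int(seeds[2]),
        )
    )
    conv_aug = run_scan(augmented.bulk, augmented.genotypes, augmented.pairs, model="conventional")
    perf = classify_performance(conv_aug, augmented.truth, fdr_threshold)
    out.update(
        augmented_conventional_true_fdr=perf.true_fdr,
        augmented_conventional_fp=perf.fp,
        augmented_conventional_fp_normal=perf.fp_normal_driven,
    )

    cov_only = run_scan(
        augmented.bulk, augmented.genotypes, augmented.pairs,
        purity=augmented.purity, model="conventional", purity_as_covariate=True,
    )
    perf = classify_performance(cov_only, augmented.truth, fdr_threshold)
    out["augmented_purity_covariate_true_fdr"] = perf.true_fdr

    measured_aug = add_purity_noise(augmented.purity, purity_noise_sd, int(seeds[1]))
    inter_aug = run_scan(
        augmented.bulk, augmented.genotypes, augmented.pairs,
        purity=measured_aug, model="interaction",
    )
    perf = classify_performance(inter_aug, augmented.truth, fdr_threshold)
    out.update(
        augmented_interaction_true_fdr=perf.true_fdr,
        augmented_interaction_fp_normal=perf.fp_normal_driven,
    )

    # fully randomized purity: the measured cell fractions carry no
    # information, the worst case of the purity-noise continuum
    permuted = permute_purity(augmented.purity, int(seeds[3]))
    perm_scan = run_scan(
        augmented.bulk, augmented.genotypes, augmented.pairs,
        purity=permuted, model="interaction",
    )
    perf = classify_performance(perm_scan, augmented.truth, fdr_threshold)
    out["augmented_permuted_true_fdr"] = perf.true_fdr

    return out
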