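"""Expression normalization, QC filters, cis pairing and covariate construction.

Mirrors the standard GTEx-style preprocessing stack for cis-eQTL mapping:
cross-sample quantile normalization followed by a per-gene rank-based
inverse-normal transform, a minimum expressed-fraction gene filter, a minor
allele frequency filter, pairing of variants with genes inside a fixed cis
window, genotype principal components for population structure, and
expression principal components (after residualizing known covariates) as
hidden-confounder factors.  A Lasso-based purity transfer lets a cohort
without purity estimates borrow them from a reference cohort.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV

__all__ = [
    "quantile_normalize_and_int",
    "filter_genes_expressed",
    "filter_variants_maf",
    "map_cis_pairs",
    "compute_genotype_pcs",
    "compute_expression_factors",
    "purity_transfer",
]


def _inverse_normal_rows(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform per column, Blom offset (r-0.5)/n."""
    n = values.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 0, values)  # average ties
    return stats.norm.ppf((ranks - 0.5) / n)


def quantile_normalize_and_int(expr: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize across samples, then inverse-normal transform per gene.

    Step 1 forces every sample's expression distribution onto the mean of the
    per-sample sorted profiles (classic quantile normalization across the
    sample axis).  Step 2 maps each gene to a standard normal via average
    ranks with the Blom offset (r - 0.5)/n, so each gene ends up mean ~0,
    sd ~1 with within-gene ranks preserved.  Genes that are constant across
    samples carry no rank information and are dropped with a warning.

    ``expr`` is samples x genes.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    constant = expr.nunique(axis=0) <= 1
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant gene(s): "
            f"{list(expr.columns[constant][:5])}",
            stacklevel=2,
        )
        expr = expr.loc[:, ~constant]
    values = expr.to_numpy(dtype=float)
    # quantile normalization across samples: sort within each sample (row of
    # the gene axis -> here samples are rows, genes columns, distributions
    # are per sample i.e. per row)
    order = np.argsort(values, axis=1)
    ranks = np.argsort(order, axis=1)
    mean_profile = np.sort(values, axis=1).mean(axis=0)
    qn = mean_profile[ranks]
    out = _inverse_normal_rows(qn)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def filter_genes_expressed(
    expr: pd.DataFrame, min_fraction: float = 0.75, threshold: float = 0.0
) -> pd.DataFrame:
    """Keep genes expressed (raw value > threshold) in >= min_fraction of samples."""
    frac = (expr.to_numpy(dtype=float) > threshold).mean(axis=0)
    kept = expr.loc[:, frac >= min_fraction]
    if kept.shape[1] == 0:
        raise ValueError("no genes pass the expressed-fraction filter")
    return kept


def filter_variants_maf(geno: pd.DataFrame, maf_min: float = 0.05) -> pd.DataFrame:
    """Keep variants with minor allele frequency >= maf_min.

    MAF per variant is min(f, 1-f) with f = sum(dosage) / (2n), ignoring
    missing genotypes.
    """
    values = geno.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = np.nanmean(values, axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    return geno.loc[:, maf >= maf_min]


def _gene_anchor(genes: pd.DataFrame) -> np.ndarray:
    """Transcription start site: 'start' on + strand, 'end' on - strand."""
    if "tss" in genes.columns:
        return genes["tss"].to_numpy(dtype=np.int64)
    start = genes["start"].to_numpy(dtype=np.int64)
    if "strand" in genes.columns and "end" in genes.columns:
        minus = genes["strand"].astype(str).to_numpy() == "-"
        end = genes["end"].to_numpy(dtype=np.int64)
        return np.where(minus, end, start)
    return start


def map_cis_pairs(
    variants: pd.DataFrame, genes: pd.DataFrame, window: int = 500_000
) -> pd.DataFrame:
    """Pair every variant with every gene whose TSS lies within the cis window.

    ``variants`` needs columns (variant_id, chrom, pos); ``genes`` needs
    (gene_id, chrom) plus either a ``tss`` column or ``start``
    (/``end``/``strand``) from which the transcription start site is taken.
    Coordinates are 1-based; the window boundary is inclusive.  Returns a
    DataFrame (variant_id, gene_id, distance) with signed distance
    ``pos - tss``.  Chromosomes present on only one side yield no pairs and
    are reported with a warning.
    """
    v_chroms = set(variants["chrom"].astype(str))
    g_chroms = set(genes["chrom"].astype(str))
    orphan = v_chroms.symmetric_difference(g_chroms)
    if orphan:
        warnings.warn(f"chromosomes without counterpart skipped: {sorted(orphan)}", stacklevel=2)

    anchors = genes.assign(_anchor=_gene_anchor(genes))
    rows = []
    for chrom, v_sub in variants.groupby(variants["chrom"].astype(str)):
        g_sub = anchors[anchors["chrom"].astype(str) == chrom]
        if g_sub.empty:
            continue
        tss = g_sub["_anchor"].to_numpy()
        order = np.argsort(tss, kind="stable")
        tss_sorted = tss[order]
        gid_sorted = g_sub["gene_id"].to_numpy()[order]
        for variant_id, pos in v_sub[["variant_id", "pos"]].itertuples(index=False):
            lo = np.searchsorted(tss_sorted, pos - window, side="left")
            hi = np.searchsorted(tss_sorted, pos + window, side="right")
            for j in range(lo, hi):
                rows.append((variant_id, gid_sorted[j], int(pos - tss_sorted[j])))
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "distance"])


def _pca_scores(values: np.ndarray, k: int, index, prefix: str) -> pd.DataFrame:
    n = values.shape[0]
    if k > min(values.shape) - 1 or k > np.linalg.matrix_rank(values - values.mean(0)):
        raise ValueError(f"k={k} exceeds the rank of the matrix")
    centered = values - values.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(scores, index=index, columns=[f"{prefix}{i + 1}" for i in range(k)])


def compute_genotype_pcs(geno: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Population-structure covariates: first k PCs of the standardized dosages.

    Variants are centered and scaled to unit variance before decomposition;
    monomorphic variants are excluded.  Returns samples x k scores.
    """
    values = geno.to_numpy(dtype=float)
    sd = values.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("all variants are monomorphic; genotype PCs undefined")
    z = (values[:, poly] - values[:, poly].mean(axis=0)) / sd[poly]
    return _pca_scores(z, k, geno.index, "geno_PC")


def compute_expression_factors(
    expr: pd.DataFrame, known_covariates: pd.DataFrame | None = None, k: int = 0
) -> pd.DataFrame:
    """Hidden expression-heterogeneity factors (PEER-factor stand-ins).

    Known covariates (population structure, purity, ...) are regressed out of
    every gene first; the first k principal components of the residual matrix
    are returned as samples x k covariate columns.  k = 0 yields an empty
    block.
    """
    if k == 0:
        return pd.DataFrame(index=expr.index)
    values = expr.to_numpy(dtype=float)
    if known_covariates is not None and known_covariates.shape[1] > 0:
        C = np.column_stack(
            [np.ones(len(expr)), known_covariates.to_numpy(dtype=float)]
        )
        beta, *_ = np.linalg.lstsq(C, values, rcond=None)
        values = values - C @ beta
    return _pca_scores(values, k, expr.index, "expr_PC")


def purity_transfer(
    expr_target: pd.DataFrame,
    expr_reference: pd.DataFrame,
    purity_reference: pd.Series,
    cv: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Transfer tumor-purity estimates to a cohort lacking them.

    A Lasso regression of reference purity on reference expression (L1 path
    chosen by cross-validation) is applied to the target cohort's expression
    over the shared gene set; predictions are then quantile-mapped onto the
    reference purity distribution, so the transferred estimates have exactly
    the reference's marginal distribution (its sorted values when the cohorts
    are the same size, interpolated empirical quantiles otherwise).
    """
    shared = expr_target.columns.intersection(expr_reference.columns)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need at least 10")
    X_ref = expr_reference[shared].to_numpy(dtype=float)
    X_tgt = expr_target[shared].to_numpy(dtype=float)
    model = LassoCV(cv=cv, random_state=seed, max_iter=5000)
    model.fit(X_ref, purity_reference.to_numpy(dtype=float))
    pred = model.predict(X_tgt)

    ref_sorted = np.sort(purity_reference.to_numpy(dtype=float))
    n = len(pred)
    ranks = stats.rankdata(pred, method="ordinal")
    quantiles = (ranks - 0.5) / n
    mapped = np.quantile(ref_sorted, quantiles, method="nearest" if n == len(ref_sorted) else "linear")
    if n == len(ref_sorted):
        # exact sorted-value replacement
        out = np.empty(n)
        out[np.argsort(pred, kind="stable")] = ref_sorted
        mapped = out
    return pd.Series(mapped, index=expr_target.index, name="purity")
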