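"""Simulation of bulk tumor expression as a purity-weighted mixture of cell types.

The generator builds two latent expression compartments -- pure cancer cells
and tumor-associated normal cells -- with a known per-gene eQTL architecture,
then mixes them per sample with the cancer-cell fraction (tumor purity) as the
weight.  Six architecture groups cover the scenarios that can arise in vivo:

1. independent eQTL effects in cancer and normal cells,
2. a cancer-cell-only eQTL,
3. a normal-cell-only eQTL,
4. no eQTL in either compartment,
5. the identical eQTL in both compartments,
6. similar (identical-plus-noise) eQTLs in both compartments.

Optionally an extra block of normal-only eQTL genes can be appended to stress
false-discovery control when most regulatory signal lives in the normal
compartment.  Purity measurement error is emulated by adding Gaussian noise
and quantile-normalizing back onto the original purity values, so the marginal
distribution of "measured" purity is preserved exactly while its ranking
degrades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "GROUP_LABELS",
    "effect_grid",
    "simulate_genotypes",
    "simulate_truth",
    "simulate_expression_pair",
    "simulate_purity",
    "mix_bulk",
    "add_purity_noise",
    "permute_purity",
    "simulate_cohort",
]

#: group labels in cohort order; "normal_extra" marks the optional appended
#: block of normal-only eQTL genes.
GROUP_LABELS = [1, 2, 3, 4, 5, 6]
NORMAL_EXTRA = "normal_extra"

# Beta parameters reproducing a right-skewed purity distribution with
# mean ~0.72 and sd ~0.14, the shape typical of consensus purity estimates
# in breast tumors.
_PURITY_MEAN = 0.72
_PURITY_SD = 0.14


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated cohort.

    Attributes
    ----------
    n_samples:
        Cohort size. Genotype counts are exact Hardy-Weinberg fractions at
        allele frequency 0.5, so values divisible by 4 give the canonical
        n/4 : n/2 : n/4 split.
    genes_per_group:
        Genes per architecture group (six groups).
    extra_normal_only:
        Additional genes carrying a normal-compartment eQTL only.
    effect_min, effect_max, effect_step:
        Uniform grid from which nonzero eQTL effect sizes are drawn
        (expression units per minor-allele copy); 0 is excluded so that
        eQTL-bearing groups are unambiguously positive ground truth.
    baseline_mean, baseline_sd:
        Per-sample baseline expression draw, Normal(mean, sd), independent
        per compartment.
    group6_noise_sd:
        SD of the Gaussian noise that turns group-6 normal-compartment
        expression into a "similar" rather than identical eQTL.
    purity_alpha, purity_beta:
        Beta distribution of the cancer-cell fraction when no empirical
        purity vector is supplied.
    purity_values:
        Optional empirical purity vector to resample from instead of the
        Beta distribution.
    purity_noise_sd:
        Default SD of purity measurement noise (quantile-normalized back to
        the original distribution).
    seed:
        Seed fixing all randomness of the cohort.
    """

    n_samples: int = 1000
    genes_per_group: int = 100
    extra_normal_only: int = 0
    effect_min: float = -0.5
    effect_max: float = 0.5
    effect_step: float = 0.01
    baseline_mean: float = 1.0
    baseline_sd: float = 1.0
    group6_noise_sd: float = 0.25
    purity_alpha: float = field(default_factory=lambda: _beta_params(_PURITY_MEAN, _PURITY_SD)[0])
    purity_beta: float = field(default_factory=lambda: _beta_params(_PURITY_MEAN, _PURITY_SD)[1])
    purity_values: tuple[float, ...] | None = None
    purity_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.genes_per_group <= 0:
            raise ValueError("genes_per_group must be positive")
        if self.extra_normal_only < 0:
            raise ValueError("extra_normal_only must be >= 0")
        if not (self.effect_min < 0 < self.effect_max):
            raise ValueError("effect grid must straddle 0")
        if not np.isclose(self.effect_min, -self.effect_max):
            raise ValueError("effect grid must be symmetric about 0")
        if self.purity_noise_sd < 0:
            raise ValueError("purity_noise_sd must be >= 0")

    @property
    def n_genes(self) -> int:
        return 6 * self.genes_per_group + self.extra_normal_only

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def effect_grid(config: SimConfig) -> np.ndarray:
    """Nonzero eQTL effect sizes on the configured uniform grid."""
    n_steps = int(round((config.effect_max - config.effect_min) / config.effect_step))
    grid = config.effect_min + config.effect_step * np.arange(n_steps + 1)
    return grid[~np.isclose(grid, 0.0)]


def simulate_genotypes(
    n_samples: int, n_variants: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Simulate biallelic dosages at exact allele frequency 0.5.

    Each variant has exactly n/4 samples with dosage 0, n/2 with dosage 1 and
    n/4 with dosage 2 (the Hardy-Weinberg proportions at equal allele
    frequency), randomly permuted across samples.  The minor allele is an
    arbitrary designation at frequency 0.5.

    Returns a samples x variants dosage DataFrame.
    """
    rng = np.random.default_rng(seed)
    n_hom = n_samples // 4
    n_het = n_samples - 2 * n_hom
    if n_samples % 4:
        warnings.warn(
            f"n_samples={n_samples} not divisible by 4; using dosage counts "
            f"{n_hom}/{n_het}/{n_hom} (remainder assigned to heterozygotes)",
            stacklevel=2,
        )
    template = np.concatenate(
        [np.zeros(n_hom, dtype=np.int8), np.ones(n_het, dtype=np.int8), np.full(n_hom, 2, dtype=np.int8)]
    )
    dosages = np.column_stack([rng.permutation(template) for _ in range(n_variants)])
    return pd.DataFrame(
        dosages,
        index=[f"sample_{i:04d}" for i in range(n_samples)],
        columns=[f"variant_{j:04d}" for j in range(n_variants)],
    )


def simulate_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the ground-truth eQTL architecture table.

    Returns a DataFrame with gene_id, group, beta_cancer, beta_normal.
    Group semantics: 1 independent effects, 2 cancer-only, 3 normal-only,
    4 none, 5 shared, 6 shared-with-noise; "normal_extra" rows behave as
    group 3.
    """
    grid = effect_grid(config)
    g = config.genes_per_group
    groups: list[object] = [lab for lab in GROUP_LABELS for _ in range(g)]
    groups += [NORMAL_EXTRA] * config.extra_normal_only

    beta_cancer = np.zeros(len(groups))
    beta_normal = np.zeros(len(groups))
    for i, grp in enumerate(groups):
        if grp == 1:
            beta_cancer[i] = rng.choice(grid)
            beta_normal[i] = rng.choice(grid)
        elif grp == 2:
            beta_cancer[i] = rng.choice(grid)
        elif grp in (3, NORMAL_EXTRA):
            beta_normal[i] = rng.choice(grid)
        elif grp in (5, 6):
            beta_cancer[i] = beta_normal[i] = rng.choice(grid)
        # group 4: both stay 0
    return pd.DataFrame(
        {
            "gene_id": [f"gene_{i:04d}" for i in range(len(groups))],
            "group": groups,
            "beta_cancer": beta_cancer,
            "beta_normal": beta_normal,
        }
    )


def simulate_expression_pair(
    config: SimConfig,
    genotypes: pd.DataFrame,
    seed: int | np.random.Generator,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate paired cancer/normal expression with one variant per gene.

    Expression of gene g in sample s is ``baseline + beta * dosage`` with an
    independent Normal(baseline_mean, baseline_sd) baseline per compartment
    and beta taken from the truth table (beta_cancer / beta_normal).  Group-6
    genes instead copy the cancer-compartment values into the normal
    compartment and add Normal(0, group6_noise_sd) noise, yielding similar
    but not identical realized eQTLs.

    Returns (cancer, normal, truth) with expression as samples x genes.
    """
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = simulate_truth(config, rng)
    n_genes = len(truth)
    if genotypes.shape[1] != n_genes:
        raise ValueError(
            f"need one variant per gene: {genotypes.shape[1]} variants for {n_genes} genes"
        )
    n = genotypes.shape[0]
    dos = genotypes.to_numpy(dtype=float)

    base_c = rng.normal(config.baseline_mean, config.baseline_sd, size=(n, n_genes))
    base_n = rng.normal(config.baseline_mean, config.baseline_sd, size=(n, n_genes))
    cancer = base_c + dos * truth["beta_cancer"].to_numpy()
    normal = base_n + dos * truth["beta_normal"].to_numpy()

    is_g6 = (truth["group"] == 6).to_numpy()
    if is_g6.any():
        noise = rng.normal(0.0, config.group6_noise_sd, size=(n, int(is_g6.sum())))
        normal[:, is_g6] = cancer[:, is_g6] + noise

    genes = truth["gene_id"].tolist()
    cancer_df = pd.DataFrame(cancer, index=genotypes.index, columns=genes)
    normal_df = pd.DataFrame(normal, index=genotypes.index, columns=genes)
    return cancer_df, normal_df, truth


def simulate_purity(
    n_samples: int,
    source: tuple[float, float] | Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
    *,
    eps: float = 1e-6,
) -> pd.Series:
    """Draw per-sample cancer-cell fractions strictly inside (0, 1).

    ``source`` is either a ``(alpha, beta)`` pair for a Beta distribution, an
    empirical purity vector to resample (without replacement when it is at
    least n_samples long), or None for the default right-skewed Beta
    (mean ~0.72, sd ~0.14).  Values outside (0, 1) are clamped with a warning.
    """
    rng = np.random.default_rng(seed)
    if source is None:
        source = _beta_params(_PURITY_MEAN, _PURITY_SD)
    if isinstance(source, tuple) and len(source) == 2 and np.isscalar(source[0]):
        values = rng.beta(source[0], source[1], size=n_samples)
    else:
        pool = np.asarray(source, dtype=float)
        if pool.size >= n_samples:
            values = rng.choice(pool, size=n_samples, replace=False)
        else:
            values = rng.choice(pool, size=n_samples, replace=True)
    if (values <= 0).any() or (values >= 1).any():
        warnings.warn("purity values outside (0,1) clamped", stacklevel=2)
        values = np.clip(values, eps, 1.0 - eps)
    return pd.Series(values, index=[f"sample_{i:04d}" for i in range(n_samples)], name="purity")


def mix_bulk(cancer: pd.DataFrame, normal: pd.DataFrame, purity: pd.Series) -> pd.DataFrame:
    """Mix compartments into bulk expression by the per-sample cancer fraction.

    ``bulk[s, g] = purity[s] * cancer[s, g] + (1 - purity[s]) * normal[s, g]``
    """
    if cancer.shape[0] != normal.shape[0] or cancer.shape[0] != len(purity):
        raise ValueError(
            f"sample axis mismatch: cancer={cancer.shape[0]}, normal={normal.shape[0]}, "
            f"purity={len(purity)}"
        )
    if cancer.shape[1] != normal.shape[1]:
        raise ValueError(
            f"gene axis mismatch: cancer={cancer.shape[1]}, normal={normal.shape[1]}"
        )
    w = purity.to_numpy()[:, None]
    return pd.DataFrame(
        w * cancer.to_numpy() + (1.0 - w) * normal.to_numpy(),
        index=cancer.index,
        columns=cancer.columns,
    )


def add_purity_noise(
    purity: pd.Series, noise_sd: float, seed: int | np.random.Generator = 0
) -> pd.Series:
    """Emulate purity measurement error while preserving the distribution.

    Gaussian noise with SD ``noise_sd`` is added, and the noisy values are
    quantile-normalized back onto the original values: the output is a
    rearrangement of the exact input values whose ranking follows
    ``input + noise``.  ``noise_sd = 0`` returns the input unchanged.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    values = purity.to_numpy(dtype=float)
    noisy = values + rng.normal(0.0, noise_sd, size=values.shape)
    order = np.argsort(noisy, kind="stable")
    out = np.empty_like(values)
    out[order] = np.sort(values)
    return pd.Series(out, index=purity.index, name=purity.name)


def permute_purity(purity: pd.Series, seed: int | np.random.Generator = 0) -> pd.Series:
    """Randomly reassign purity values across samples (multiset preserved)."""
    rng = np.random.default_rng(seed)
    return pd.Series(rng.permutation(purity.to_numpy()), index=purity.index, name=purity.name)


@dataclass
class SimulatedCohort:
    """A fully realized simulated cohort: genotypes, compartments, bulk, truth."""

    config: SimConfig
    genotypes: pd.DataFrame
    cancer: pd.DataFrame
    normal: pd.DataFrame
    bulk: pd.DataFrame
    purity: pd.Series
    truth: pd.DataFrame

    @property
    def pairs(self) -> pd.DataFrame:
        """One-to-one variant-gene pairing used by the simulation."""
        return pd.DataFrame(
            {
                "variant_id": self.genotypes.columns,
                "gene_id": self.truth["gene_id"].to_numpy(),
                "distance": 0,
            }
        )


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a complete cohort (genotypes, expression, purity, bulk).

    All randomness derives from ``config.seed``; identical configs give
    bit-identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    geno_rng, expr_rng, purity_rng = (np.random.default_rng(s) for s in root.spawn(3))
    genotypes = simulate_genotypes(config.n_samples, config.n_genes, geno_rng)
    cancer, normal, truth = simulate_expression_pair(config, genotypes, expr_rng)
    source = config.purity_values if config.purity_values is not None else (
        config.purity_alpha,
        config.purity_beta,
    )
    purity = simulate_purity(config.n_samples, source, purity_rng)
    bulk = mix_bulk(cancer, normal, purity)
    return SimulatedCohort(config, genotypes, cancer, normal, bulk, purity, truth)
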