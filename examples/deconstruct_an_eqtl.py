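"""Deconstruct a misattributed eQTL across tumor-purity bins.

Picks the strongest normal-cell-only eQTL from a simulated cohort, splits the
cohort into five equal-sized purity bins, and refits the effect in each bin.
A normal-driven signal fades as cancer-cell content rises; the interaction
model's extrapolated cancer-cell effect sits at zero while the conventional
bulk estimate is misleadingly nonzero.
"""

from pureqtl import SimConfig, binned_effects, simulate_cohort

cohort = simulate_cohort(SimConfig(seed=13))
truth = cohort.truth
g3 = truth[truth["group"] == 3]
gene = g3.loc[g3["beta_normal"].abs().idxmax()]
variant = cohort.genotypes.columns[gene.name]

y = cohort.bulk[gene["gene_id"]].to_numpy()
x = cohort.genotypes[variant].to_numpy(dtype=float)
bins, conventional, interaction = binned_effects(y, x, cohort.purity, n_bins=5)

print(f"{gene['gene_id']}: simulated beta_cancer = 0, "
      f"beta_normal = {gene['beta_normal']:+.2f}\n")
print("effect size by purity bin (95% CI):")
for row in bins.itertuples():
    print(f"  purity {row.purity_low:.2f}-{row.purity_high:.2f}  "
          f"beta = {row.beta:+.3f}  [{row.ci_low:+.3f}, {row.ci_high:+.3f}]")

lo_c, hi_c = conventional.ci()
lo_i, hi_i = interaction.ci()
print(f"\nwhole-cohort conventional estimate: {conventional.beta1:+.3f} "
      f"[{lo_c:+.3f}, {hi_c:+.3f}]  p = {conventional.p:.2e}")
print(f"interaction model, effect at 100% cancer cells: {interaction.beta1:+.3f} "
      f"[{lo_i:+.3f}, {hi_i:+.3f}]  p = {interaction.p:.2e}")
print(
    "\nThe binned effects shrink toward zero in the purest bins, the pattern of"
    "\na normal-cell eQTL. The conventional model calls this gene significant;"
    "\nthe interaction model's extrapolated CI covers zero, so the eQTL is not"
    "\nattributed to cancer cells."
)
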