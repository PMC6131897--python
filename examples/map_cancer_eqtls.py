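"""Conventional vs purity-interaction eQTL mapping on a simulated bulk cohort.

Scans the same bulk tumor expression matrix twice: once with the conventional
model (expression ~ genotype), once with the interaction model (expression ~
genotype + normal fraction + genotype x normal fraction, whose genotype term
extrapolates the effect to 100% cancer cells), then scores both against the
simulated cancer-eQTL ground truth at BH FDR < 0.05.
"""

from pureqtl import (
    SimConfig,
    add_purity_noise,
    classify_performance,
    run_scan,
    simulate_cohort,
)

cohort = simulate_cohort(SimConfig(seed=1))
# measured purity carries quantile-normalized Normal(0, 0.1) noise
measured_purity = add_purity_noise(cohort.purity, 0.1, seed=2)

for model, kwargs in [
    ("conventional", {}),
    ("interaction", {"purity": measured_purity}),
]:
    results = run_scan(
        cohort.bulk, cohort.genotypes, cohort.pairs, model=model, **kwargs
    )
    perf = classify_performance(results, cohort.truth, fdr_threshold=0.05)
    print(f"{model} model ({int((results['q'] < 0.05).sum())} calls at q<0.05):")
    print(f"  sensitivity {perf.sensitivity:6.1%}   specificity {perf.specificity:6.1%}"
          f"   true FDR {perf.true_fdr:6.1%}")
    print(f"  false discoveries driven by normal-cell eQTLs: "
          f"{perf.fp_normal_driven} of {perf.fp}")

print(
    "\nThe conventional model reads bulk expression as cancer expression, so"
    "\nnormal-cell eQTLs leak in: its realized FDR exceeds the nominal 5% and"
    "\nmost false calls are normal-driven. The interaction model trades some"
    "\nsensitivity for a realized FDR below the nominal level."
)
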