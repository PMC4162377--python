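"""Locate non-invariant item parameters and rank group factor means.

Simulates three groups with one injected threshold shift (+1.0 on item
Y3 in group G2), aligns the configural fit, bootstraps standard errors
for the aligned quantities, and prints the invariance flags, the
non-invariance rates with the 25% rule-of-thumb verdict, and the
factor-mean ranking with pairwise significance.
"""

from irtalign import (
    AlignmentOptions,
    align,
    aligned_standard_errors,
    detect_invariant_sets,
    factor_mean_ranking,
    fit_configural,
    generate_responses,
    make_population,
    noninvariance_summary,
)

pop = make_population(G=3, P=5, seed=21)  # means 0/1/2, unit variances
pop.thresholds[2, 1] += 1.0  # DIF: item Y3's threshold in group G2

data = generate_responses(pop, 2000, seed=3)
fit = fit_configural(data)
result = align(fit, AlignmentOptions(n_starts=5, seed=0))
ses = aligned_standard_errors(result, fit, n_boot=100, seed=5)

flags = detect_invariant_sets(result, ses, alpha_level=0.01)
print("flagged item parameters (group shown = significantly non-invariant):")
for (item, family), entry in sorted(flags.entries.items()):
    if entry.flagged:
        print(f"  {item} {family}: {entry.flagged}")

rates = noninvariance_summary(flags)
print(
    f"\nnon-invariance: thresholds {rates.threshold_pct:.1f}%, "
    f"loadings {rates.loading_pct:.1f}%, average {rates.average_pct:.1f}% "
    f"-> {rates.verdict}"
)

ranking = factor_mean_ranking(result, ses, alpha_level=0.05)
print("\nfactor-mean ranking (higher groups list those significantly below):")
print(ranking.to_dataframe().to_string(index=False))

print()
print("Only the injected cell (Y3 threshold, G2) should be flagged; the")
print("rates stay far below 25%, so the mean comparison is trustworthy,")
print("and the ranking reproduces the generating order G3 > G2 > G1 with")
print("the reference group G1 fixed at mean 0.")
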