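"""Classical invariance testing: configural vs metric vs scalar.

Simulates three groups whose factor means genuinely differ while the
item parameters are fully invariant, fits the three model levels and
prints the likelihood-ratio table.  With invariant items the metric and
scalar restrictions should not be strongly rejected.
"""

from irtalign import (
    fit_configural,
    fit_invariance_model,
    likelihood_ratio_test,
    make_population,
    generate_responses,
)

pop = make_population(G=3, P=8, seed=11)  # invariant items, means 0/1/2
data = generate_responses(pop, 800, seed=4)

configural = fit_configural(data)
metric = fit_invariance_model(data, "metric", configural=configural)
scalar = fit_invariance_model(data, "scalar", configural=configural)

print(f"{'model':<12}{'free parameters':>16}{'loglik':>14}")
for fit in (configural, metric, scalar):
    level = getattr(fit, "level")
    print(f"{level:<12}{fit.n_free:>16}{fit.loglik:>14.3f}")

print()
print(f"{'comparison':<28}{'chi-square':>11}{'df':>5}{'p':>9}")
for general, restricted in ((configural, metric), (configural, scalar), (metric, scalar)):
    lrt = likelihood_ratio_test(general, restricted)
    name = f"{restricted.level} against {general.level}"
    print(f"{name:<28}{lrt.chisq:>11.3f}{lrt.df:>5}{lrt.pvalue:>9.4f}")

print()
print("Degrees of freedom follow the constraint bookkeeping: (G-1)(P-1)")
print("for metric-vs-configural and 2(G-1)(P-1) for scalar-vs-configural.")
print("Because the generating items are invariant, the chi-squares stay")
print("near their degrees of freedom; the scalar fit also recovers the")
print("generating factor means:", [round(float(a), 2) for a in scalar.alphas])
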