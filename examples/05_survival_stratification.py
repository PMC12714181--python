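"""Expression-stratified survival: median split, Kaplan-Meier, log-rank.

Draws exponential survival times whose hazard doubles for tumor samples
with above-median hub-gene expression, estimates both survival curves and
tests the difference.
"""

from degnet import (
    SimulationConfig,
    generate_cohorts,
    generate_survival,
    km_estimate,
    logrank_test,
)

config = SimulationConfig(survival_hr=2.0, censor_rate=0.2, seed=1)
matrix, metadata, truth = generate_cohorts(config)

tumor_ids = metadata.loc[metadata.group == "tumor", "sample_id"]
expression = matrix.data.loc[truth.survival_gene, list(tumor_ids)]
records = generate_survival(config, truth, expression)

for stratum in ("high", "low"):
    sub = [r for r in records if r.stratum == stratum]
    curve = km_estimate(sub)
    median_t = next(
        (t for t, s in zip(curve.event_times, curve.survival) if s <= 0.5), float("nan")
    )
    print(f"{stratum}: n={len(sub)}, events={sum(r.event for r in sub)}, "
          f"median survival ~ {median_t:.1f}")

chi2, p = logrank_test(records)
print(f"log-rank chi-square = {chi2:.3f}, p = {p:.4f}")
# With a true hazard ratio of 2 between the expression strata, the high
# group reaches 50% survival sooner and the log-rank test is significant.
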