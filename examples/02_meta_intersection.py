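"""Cross-cohort meta-intersection: direction-consistent common DEG sets.

Runs per-cohort and pooled contrasts on the simulated three-cohort study
and prints the Venn-style breakdown of single-study vs pooled vs common
DEGs, mirroring how "consistently dysregulated" gene sets are built.
"""

from degnet import SimulationConfig, generate_cohorts, run_meta_contrast, split_by_cohort

config = SimulationConfig(seed=1)  # study-scale defaults: 43+43, 20+20, 21+21
matrix, metadata, truth = generate_cohorts(config)

report = run_meta_contrast(split_by_cohort(matrix, metadata), metadata)
for cohort, sets in report.per_study.items():
    print(f"{cohort}: {len(sets.up)} up / {len(sets.down)} down")
print(f"pooled:   {len(report.meta.up)} up / {len(report.meta.down)} down")
print(f"common:   {len(report.common_up)} up / {len(report.common_down)} down")
print("venn:", report.venn)

recovered = report.common_up | report.common_down
print(f"planted recovery: {len(recovered & truth.de_genes)}/{len(truth.de_genes)}")
# "common" genes pass the per-cohort call in every cohort AND the pooled
# contrast with the same sign - the strictest, direction-consistent rule.
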