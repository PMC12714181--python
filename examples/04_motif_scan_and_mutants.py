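"""Promoter motif scanning, fragment partitioning and binding-core mutants.

Plants the C/EBP consensus at TSS-relative offsets -1800, -1250 and -400 of
one promoter, scans the 2-kb window on both strands, splits it into the
three reporter fragments, and designs core substitutions that ablate every
site.
"""

from degnet import (
    SimulationConfig,
    default_cebpb_pfm,
    design_motif_mutants,
    generate_cohorts,
    generate_promoters,
    partition_promoter,
    pfm_to_pwm,
    rank_genes_by_motif,
    scan_promoter,
)

config = SimulationConfig(seed=1)
_, _, truth = generate_cohorts(config)
pfm = default_cebpb_pfm()
pwm = pfm_to_pwm(pfm)

(gene,) = truth.motif_offsets_by_gene
promoters = generate_promoters(config, truth, pfm, genes=[gene, "BG0001", "BG0002"])

sites = scan_promoter(promoters[gene], pwm, rel_threshold=0.85, gene=gene)
print(f"{gene}: {len(sites)} sites >= 0.85 of max score")
for s in sites:
    print(f"  [{s.tss_start}, {s.tss_end}) strand {s.strand} rel {s.rel_score:.3f}")

ranking = rank_genes_by_motif(promoters, pwm, rel_threshold=0.85)
print("\ngene ranking by best promoter score:")
print(ranking.to_string(index=False))

for frag in partition_promoter(promoters[gene]):
    n = len(scan_promoter(frag.sequence, pwm, rel_threshold=0.85))
    print(f"fragment {frag.label} [{frag.tss_start}, {frag.tss_end}): {n} site(s)")

mutant, subs = design_motif_mutants(promoters[gene], sites, pwm, rel_threshold=0.85)
residual = scan_promoter(mutant, pwm, rel_threshold=0.85, gene=gene)
print(f"\nmutant: {len(subs)} base substitutions, {len(residual)} residual sites")
# The perfect-score hits sit exactly at the planted offsets; substituting
# the highest-information core bases abolishes every match on rescan.
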