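"""Prioritize WGS variants inside the mapped interval down to candidates.

Five ordered filters: mapped interval; perfect recessive genotype pattern
(affected 1/1, carrier 0/1, wild type 0/0); no catalogued (dbSNP-like) ID;
not on the genotyping chip; protein-changing. The implanted causal missense
variant survives them all.
"""

import recessmap as rm

study = rm.simulate_study(rm.SimulationConfig(seed=1))
stats = rm.scan(study.genotypes, study.marker_map, study.phenotypes)
interval = rm.detect_intervals(stats, study.genotypes, study.phenotypes)[0]

report = rm.run_cascade(
    study.variants, interval, study.quartet_roles,
    known_ids=None,                       # any assigned ID counts as catalogued
    chip_positions=study.chip_positions,
    models=study.gene_models,
)
print(report.format_table())
for variant, consequence in report.candidates:
    print(f"candidate: {variant.chrom}:{variant.pos:,} "
          f"{variant.ref}>{variant.alt}  {consequence.gene}  "
          f"{consequence.hgvs_c}  {consequence.hgvs_p}  "
          f"({consequence.consequence_class})")

# Counts shrink at every step; the surviving candidate is the causal
# substitution, annotated with its coding change and amino-acid substitution.
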