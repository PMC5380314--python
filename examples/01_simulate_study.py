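"""Generate one synthetic mapping study and look at its structure.

A recessive mutation is introduced by a single founder sire who covers ~6% of
matings in every generation of a closed herd; eight generations later the
study cohort (12 affected calves, 123 unaffected adults) is genotyped on a
3,000-marker chip over a 100 Mb chromosome, and four animals (two affected,
one obligate carrier, one wild type) get a WGS-like variant table.
"""

import recessmap as rm

config = rm.SimulationConfig(seed=1)
study = rm.simulate_study(config)

ped = study.pedigree
print(f"pedigree: {len(ped)} individuals over {config.n_generations} generations")
print(f"cohort: {len(study.phenotypes.affected_ids)} affected, "
      f"{len(study.phenotypes.control_ids)} controls")
print(f"sequencing quartet: {study.phenotypes.quartet}")

common = rm.find_common_ancestors(ped, set(study.phenotypes.affected_ids))
print(f"ancestors shared by all affected: {sorted(common)}")

lo, hi = study.truth["shared_interval"]
print(f"true shared homozygous region: {lo:,}-{hi:,} "
      f"({(hi - lo + 1) / 1e6:.1f} Mb) around the causal site at "
      f"{study.truth['causal_pos']:,}")
print(f"variant table: {len(study.variants)} biallelic records "
      f"({sum(v.known_id is not None for v in study.variants)} with catalogued IDs)")

# The founder id appearing in the common-ancestor set, and a shared region of
# a few Mb, are the study's premise: all cases are identical by descent there.
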