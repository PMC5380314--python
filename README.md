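# recessmap

Mapping fully penetrant recessive disease in livestock from SNP-array and
whole-genome sequencing data — and validating every stage against a gene-drop
pedigree simulator.

`recessmap` is written for geneticists working on monogenic recessive defects
in managed populations (cattle breeds being the motivating case): a heavily
used carrier sire spreads a mutation through a closed herd, homozygous
affected offspring appear a few generations later, and the locus is found by
**homozygosity mapping** — all cases are homozygous identical-by-descent for
the founder haplotype around the causal site. The package implements the four
stages of that study design as a library, with a thin `recessmap` CLI on top:

1. **Homozygosity mapping** (`recessmap.hommap`). For each chip marker the
   affected cohort is summarised by genotype counts (n₁ homozygous allele 1,
   n₂ heterozygous, n₃ homozygous allele 2) and the control cohort by its
   allele-1 frequency f₁, reported with extreme values clamped (exactly 0 →
   0.1, exactly 1 → 0.9). The per-marker statistic is a likelihood ratio of
   the affected genotype distribution against Hardy–Weinberg at f₁:

   ```
   lrt = 2 [ sup_p ℓ(p) − ℓ(f₁) ],   ℓ(p) = n₁ ln p² + n₂ ln 2p(1−p) + n₃ ln (1−p)²
   ```

   with the supremum at the affected-sample MLE p̂ = (2n₁+n₂)/(2n). The mapped
   locus is detected as a maximal run of consecutive markers at which every
   typed affected animal is homozygous for the same allele, ranked by summed
   lrt.
2. **Variant prioritization** (`recessmap.varfilter`). WGS variant calls from
   a small panel (two affected, one obligate carrier, one wild type) pass five
   ordered filters: inside the mapped interval; perfect recessive segregation
   (affected 1/1, carrier 0/1, wild type 0/0); no catalogued (dbSNP-like) ID;
   not on the genotyping array; protein-changing. Survivors are annotated in
   coding coordinates (c.376C>T / p.R126C style) and ranked novel-first, then
   by a cross-species conservation score.
3. **Carrier-test design** (`recessmap.diagtest`). The disease haplotype is
   read directly off the mapped interval (every affected is homozygous for
   it) and new animals are classified from unphased chip genotypes as
   `affected_genotype` / `carrier` / `non_carrier` / `ambiguous` — the
   indirect test a diagnostic lab can run from array calls alone.
4. **Gene-drop simulation** (`recessmap.simulate`). A forward simulator
   reproduces the study's statistical structure — founder carrier sire,
   Mendelian transmission with Haldane recombination, an affected/control
   chip cohort, a quartet variant table with an implanted causal missense
   variant — so the whole pipeline is testable without any external data.

Standard formats throughout: PED/MAP chip genotypes, VCF 4.2, GFF3 + FASTA
gene models, TSV reports.

## Worked example

`examples/` holds one narrative script per capability. Running
`examples/02_homozygosity_scan.py` and `examples/03_variant_prioritization.py`
(one simulated study, seed 1: 12 affected calves, 123 controls, 3,000 markers
on a 100 Mb chromosome) prints:

```
scanned 3000 markers; peak lrt 61.0 at 7:93,365,517 (n1=0 n2=0 n3=12, f1=0.72)
8 shared homozygous interval(s); top-ranked: 7:91,441,595-94,213,875 (2.8 Mb, 79 markers, score 2252.6)
contains the true causal position: True
step    n_remaining
interval        69
genotype_pattern        4
not_in_known_ids        4
not_on_chip     4
nonsynonymous   1
candidate: 7:93,500,000 C>T  DGENE  c.376C>T  p.R126C  (missense)
```

Reading: the genome scan peaks at a marker where all 12 affected are
homozygous for an allele at frequency 0.72 in controls; the top-ranked shared
homozygous interval spans 2.8 Mb and contains the (simulator-known) causal
position. Of the 69 quartet variants inside that interval, the five filters
leave exactly one candidate — the implanted causal substitution, annotated as
an arginine→cysteine missense change at codon 126 (c.376C>T, p.R126C).
`examples/04_carrier_test.py` then derives a 79-marker haplotype signature
from the same interval and classifies 200 unseen animals, agreeing with the
true causal genotype for 198/200 (the discordants carry recombinant interval
haplotypes — the indirect test's structural blind spot).

The same pipeline runs from the shell:

```
recessmap simulate --seed 1 --out study/
recessmap scan      --ped study/cohort.ped --map study/cohort.map --pheno study/roles.tsv --out stats.tsv
recessmap intervals --stats stats.tsv --ped study/cohort.ped --map study/cohort.map --pheno study/roles.tsv --out intervals.tsv
recessmap prioritize --vcf study/quartet.vcf --interval 7:91441595-94213875 \
    --pheno roles.tsv --known-ids study/known_ids.txt --chip-map study/cohort.map \
    --gff study/genes.gff3 --fasta study/genome.fa --out report.tsv
recessmap design-test --ped study/cohort.ped --map study/cohort.map --pheno study/roles.tsv --out signature.tsv
recessmap classify  --ped study/cohort.ped --map study/cohort.map --signature signature.tsv --out calls.tsv
```

## Documentation

`docs/methods.md` describes the statistical model, the simulator's design and
its deliberate simplifications, numerical conventions, and known limitations.
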