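# Methods

## Study design being modelled

A fully penetrant autosomal recessive defect segregates in a closed livestock
population. One elite sire — the designated founder carrier — covers a large
share of matings over many years, so his haplotypes saturate the pedigree and
homozygous affected offspring surface several generations later. The mapping
design genotypes a modest affected cohort plus unaffected controls on a fixed
SNP array, localizes the locus by shared homozygosity, then sequences a small
panel (two affected, one obligate carrier, one unrelated wild type) and
filters the called variants down to candidates. A marker-haplotype test over
the mapped interval finally lets breeders screen carriers from array data
alone.

All four stages are implemented against that design; the gene-drop simulator
provides cohorts with known generative truth so every stage's claims are
testable end to end.

## Homozygosity-mapping statistic

At each marker, affected animals contribute genotype counts (n1, n2, n3) =
(homozygous allele 1, heterozygous, homozygous allele 2); controls contribute
the allele-1 frequency f1 = (2·hom1 + het) / (2·typed). Markers with fewer
than 90% of affected animals typed are dropped from the scan, as are markers
with zero typed controls.

The statistic is a one-parameter likelihood-ratio test on the trinomial
genotype likelihood under Hardy–Weinberg,

    l(p) = n1·ln p^2 + n2·ln 2p(1-p) + n3·ln (1-p)^2,
    lrt  = 2·[ l(p_hat) - l(f1) ],    p_hat = (2·n1 + n2) / (2·(n1+n2+n3)),

with 0·ln 0 = 0. The null pins the affected cohort to Hardy–Weinberg at the
control frequency; the alternative frees the allele frequency. Because
l(f1) diverges when f1 is exactly 0 or 1, extreme raw control frequencies
are reported clamped — exactly 0 becomes 0.1 and exactly 1 becomes 0.9;
intermediate values are never altered. The clamp is part of the reporting
convention, applied before the statistic is formed. The statistic is used
descriptively, to localize: no genome-wide significance calibration is
attached to it (single-marker LRTs under relatedness would not be
chi-squared anyway).

The test suite checks the closed form against an independent grid-search
maximization of l(p) (step 1e-4, locally refined) on a thousand random
configurations, plus the structural properties: nonnegativity, exact zero
when p_hat = f1, and monotone decrease in f1 when all affected are
homozygous for allele 1.

### Interval detection

A marker *qualifies* when every typed affected animal is homozygous and all
share the same allele. Homozygous intervals are maximal runs of at least
`min_markers` (default 5 — a guard against single-marker artifacts)
consecutive qualifying markers, ranked by summed lrt with ties broken by
marker count and then leftmost position. Interval boundaries are the
outermost qualifying markers, not midpoints to the flanking discordant
markers: the simplest defensible convention, with the consequence that a
causal site lying in the gap just beyond the boundary marker is formally
outside the reported interval. The simulator's truth interval, by contrast,
records the full identical-by-descent region (bounded exclusively by the
flanking discordant markers), which always contains the causal position.

Markers dropped from the scan (low call rate) do not interrupt a run;
consecutive means adjacent rows of the scan table. Carriers are permitted
among controls — the design assumes controls are known unaffected, not known
non-carriers — and the statistic does not rely on carrier-free controls.

## Variant prioritization cascade

Five ordered filters, with the survivor count recorded after each:

1. `interval` — (chrom, pos) inside the mapped interval, boundaries
   inclusive;
2. `genotype_pattern` — every affected homozygous-alternate, every wild type
   homozygous-reference, every carrier heterozygous. Roles drive the
   requirements, so designs without a sequenced carrier degrade gracefully.
   By default a missing genotype in a required animal removes the record
   (`allow_missing=True` ignores that animal instead);
3. `not_in_known_ids` — the record's ID is in the supplied catalogue
   (passing no catalogue means any assigned ID counts);
4. `not_on_chip` — (chrom, pos) matches an array position; alleles are not
   compared. Steps 3 and 4 remove old, breed-shared polymorphisms that
   cannot explain a recently emerged defect. Their cumulative counts depend
   on order (a variant can satisfy both), but the final set does not — both
   facts are asserted in the tests;
5. `nonsynonymous` — missense, nonsense or stop-lost under the gene models.

Candidates are ranked novel-ID first, then by a per-site conservation score
(fraction of non-gap sequences in a protein alignment matching the column's
majority residue, ties resolved toward the first sequence), descending.

### Consequence annotation

Only SNVs are classified. The genomic position is projected into coding
coordinates strand-aware (on the minus strand the coding base is the
complement and positions count from the transcript 5' end), the affected
codon is translated with the standard genetic code (codon index
ceil(cds_pos/3), offset (cds_pos-1) mod 3), and the change is classified
synonymous / missense / nonsense / stop-lost; positions inside a gene span
but outside its CDS are intronic, elsewhere intergenic. HGVS-style names are
minimal (`c.376C>T`, `p.R126C`). A REF allele disagreeing with the model
sequence raises an error rather than silently re-anchoring. Indels raise an
explicit unsupported-variant signal and can never be counted as
protein-changing; the only indel support is the in-frame replacement
arithmetic (reference codons, inserted bp, deleted bp → replacement codon
count). Splice-region and regulatory classes are not modelled — a deliberate
divergence from full effect predictors; the `non_coding` class exists in the
type but is never produced because non-coding transcripts are not modelled.

## Haplotype carrier test

The signature assigns each interval marker its shared allele as the risk
allele; affected training animals are re-verified against it. Classification
uses unphased genotypes only — no statistical phasing — because affected
animals are homozygous by design, making the risk haplotype directly
readable, and carrier calls reduce to compatibility logic: homozygous-risk
at every informative marker → `affected_genotype`; at least one
heterozygous marker and no homozygous-non-risk marker → `carrier`; any
homozygous-non-risk marker → `non_carrier` (one such marker excludes an
intact risk haplotype); fewer informative markers than `min_informative`
(default 80% of the signature, rounded up) → `ambiguous`.

The test is *indirect*: an animal carrying the marker haplotype without the
causal allele — a recombinant, or a coincidental identical-by-state match —
is misclassified by construction. The suite asserts this limitation
explicitly, and asserts soundness on noise-free animals whose interval
haplotypes are non-recombinant. Per-call genotyping error can only degrade
calls; the suite checks discordance is monotone over error rates 0, 0.001,
0.01 under common random numbers.

## Gene-drop simulator

### Demography and ascertainment

Discrete generations: 40 founder males and 360 founder females, then 8
generations of 600 offspring each, plus 10 immigrant founder females per
generation (a mildly open herd). For each offspring the sire is the founder
carrier with probability 0.06 — his semen remains in use across all
generations, matching a historical AI sire whose descendants sit 3–8
generations above the cases — otherwise a random male of the previous
generation; dams are random females. Penetrance is 1 with no phenocopies.
The affected cohort (12) and controls (123) are drawn from the last three
generations; the sequencing quartet is two of the affected, a heterozygous
parent of an affected (an obligate carrier) and a wild-type animal.

A mapping study of this kind exists only conditional on an outbreak. At 6%
founder usage, drift extinguishes the founder allele in a minority of
pedigree realisations before 12 homozygotes exist; the generator mirrors the
real-world ascertainment by rejecting such realisations and redrawing from a
deterministically derived sub-seed (`SeedSequence([seed, attempt])`), so one
seed still produces exactly one reproducible study. If no feasible pedigree
appears in 60 attempts the design itself is infeasible and an error names
the parameters to change.

### Chromosome, markers and transmission

One chromosome of 100 Mb carries 3,000 markers at uniform random positions —
a desk-scale stand-in for a genome-wide 50K array (same marker density,
~1/33 kb). Marker allele-1 frequencies are Beta(2, 2) (mid-frequency,
chip-like); founder haplotypes are drawn per marker with a first-order
Markov copy probability of 0.5 from the left neighbour (background LD,
enough to make long identical-by-state runs possible but not chromosome
wide). Transmission is Mendelian with Haldane recombination: crossover
counts Poisson with mean recomb_rate × length (1 cM/Mb × 100 Mb = 1 Morgan),
uniform positions, no interference, sex-averaged. The causal allele travels
with the founder's surrounding marker haplotype except across crossovers;
the per-meiosis mosaic is conditioned on the pedigree's recorded causal
transmission by the symmetric relabelling of the parent's two haplotypes,
which leaves the mosaic distribution unchanged.

### Variant table and gene models

3,000 background variants segregate on founder haplotypes (ALT frequencies
Beta(1, 3)). Each is independently tagged: catalogued-ID with probability
0.4 and chip-coinciding with probability 0.3 — chosen to emulate the
attrition proportions of the motivating study's filter table (about 39%
of pattern-matching variants removed as catalogued, about 30% of the
remainder as on-chip). Chip-coinciding variants are placed exactly at marker
positions so the positional chip filter behaves as in a real pipeline.
A fraction (2%, of which 70% nonsynonymous) is placed inside the CDS of
~60 synthetic gene models (1–3 exons, random strand, non-stop codons);
"uniform placement" is therefore a mixture — purely uniform placement on a
desk-scale chromosome would leave the final filter with nothing to do. The
disease gene is a plus-strand, 420-codon transcript positioned so the causal
site falls at coding position 376, first base of codon 126 (CGC); the
implanted causal record is novel, off-chip, missense (C>T, Arg→Cys), with
quartet genotypes 1/1, 1/1, 0/1, 0/0 by construction. Non-genic sequence is
a deterministic pseudo-random filler, so VCF REF alleles, GFF3 models and
the written FASTA always agree without holding 100 Mb in memory.

One global seed is split into named substreams (pedigree, markers, genes,
drop, cohort, error, founder variants), so the marker drop is identical
whether or not variant sites are carried, and repeated runs are
byte-identical.

### What the generator does not emulate

No coalescent founder diversity (founder haplotypes are exchangeable draws
from a parametric model); no selection against carriers; no genotyping-error
structure beyond a uniform per-call rate (default 0); no sex-specific or
interference-aware recombination; single chromosome; chip-coinciding
variants are not forced to share alleles with the marker at the same
position. Passing tests therefore demonstrate correctness of the analysis
under idealised Mendelian structure, not robustness to array artefacts,
population stratification or call-set noise in real data.

## Numerical and convention notes

- Coordinates at every interface are 1-based inclusive (VCF/GFF convention).
- Genotype coding is map-anchored: hom1 means two copies of the marker map's
  allele1, so "allele 1" is the same allele across animals.
- Multi-allelic VCF sites are split into biallelic records (a 1/2 call is
  heterozygous for each ALT); phase separators are ignored.
- Contig names must match exactly across VCF, GFF3, FASTA and MAP; there is
  no alias table, and mismatches raise a named error.
- The LRT is clipped at zero against floating-point negatives; counts of
  zero contribute exactly zero via `xlogy`.
- Overlapping gene models are resolved first-containing-transcript-wins;
  the simulator only emits non-overlapping models.
- The conservation-score column index is 0-based.

## Known limitations

- The interval boundary convention (outermost qualifying marker) can leave a
  causal site in the marker gap beyond the boundary; at the default marker
  density this is rare but real, and the recovery property in the test suite
  (top-ranked interval contains the causal position in at least 95 of 100
  replicates) reflects it: the few misses are replicates where an ancestral
  recombination fragments the shared region and a flanking run outscores the
  causal-straddling one.
- The trinomial LRT treats affected animals as independent draws, which
  inbred cases are not; the statistic is a localization score, not a
  calibrated test.
- The carrier test misclassifies recombinant and identical-by-state
  haplotypes by design; a production assay should type the causal variant
  directly once known.
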