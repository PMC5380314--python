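"""Candidate-variant prioritization for a fully penetrant recessive disease.

Whole-genome variant calls from a small sequenced panel (two affected, one
obligate carrier, one wild type in the motivating design) are reduced in five
ordered steps:

1. ``interval``          — keep variants inside the mapped homozygous interval;
2. ``genotype_pattern``  — keep variants whose genotypes segregate perfectly
   (affected homozygous-alternate, wild type homozygous-reference, carrier
   heterozygous);
3. ``not_in_known_ids``  — discard variants already catalogued (dbSNP-like ID);
4. ``not_on_chip``       — discard variants at genotyping-array positions
   (both 3 and 4 target old, breed-shared polymorphisms that cannot cause a
   recently emerged recessive disease);
5. ``nonsynonymous``     — keep protein-changing SNVs (missense, nonsense,
   stop-lost) under the synthesis of the gene models.

Consequence annotation projects a genomic SNV into coding coordinates
(strand-aware), translates the affected codon with the standard genetic code
and emits minimal HGVS-style names (c.376C>T / p.R126C). Indels are not
classified beyond an explicit unsupported-variant signal; splice and
regulatory classes are not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import ConfigurationError, UnsupportedVariantError
from .hommap import HomozygosityInterval
from .io import (HET, HOM_ALT, HOM_REF, MISSING, GeneModel, PhenotypeTable,
                 VariantRecord, revcomp)

logger = logging.getLogger(__name__)

CASCADE_STEPS = ("interval", "genotype_pattern", "not_in_known_ids",
                 "not_on_chip", "nonsynonymous")

NONSYNONYMOUS_CLASSES = frozenset({"missense", "nonsense", "stop_lost"})


@dataclass
class Consequence:
    """Predicted effect of an SNV on a transcript."""

    consequence_class: str  # intergenic | intronic | synonymous | missense |
    #                         nonsense | stop_lost | non_coding
    gene: str | None = None
    cds_pos: int | None = None       # 1-based coding-nucleotide index
    codon_index: int | None = None   # 1-based
    codon_offset: int | None = None  # 0, 1 or 2 within the codon
    ref_aa: str | None = None
    alt_aa: str | None = None
    hgvs_c: str | None = None        # e.g. c.376C>T
    hgvs_p: str | None = None        # e.g. p.R126C

    @property
    def is_nonsynonymous(self) -> bool:
        return self.consequence_class in NONSYNONYMOUS_CLASSES


def annotate_consequence(variant: VariantRecord, models: list[GeneModel]) -> Consequence:
    """Classify an SNV against a list of gene models.

    The first model whose CDS contains the position wins (models are expected
    to be non-overlapping); a position inside a gene span but outside its CDS
    is intronic; a position in no model is intergenic. Raises
    :class:`UnsupportedVariantError` for indels and a ``ValueError`` if the
    variant's REF disagrees with the model sequence.
    """
    if not variant.is_snv:
        raise UnsupportedVariantError(
            f"{variant.chrom}:{variant.pos}: indel consequences are not modelled "
            f"(ref={variant.ref}, alt={variant.alt})")
    intronic_gene = None
    for m in models:
        if not m.contains(variant.chrom, variant.pos):
            continue
        cds_pos = m.cds_position(variant.pos)
        if cds_pos is None:
            intronic_gene = intronic_gene or m.gene
            continue
        return _coding_consequence(variant, m, cds_pos)
    if intronic_gene is not None:
        return Consequence("intronic", gene=intronic_gene)
    return Consequence("intergenic")


def _coding_consequence(variant: VariantRecord, model: GeneModel, cds_pos: int
                        ) -> Consequence:
    codon_index = (cds_pos + 2) // 3          # = ceil(cds_pos / 3)
    codon_offset = (cds_pos - 1) % 3
    if model.strand == "+":
        ref_c, alt_c = variant.ref, variant.alt
    else:
        ref_c, alt_c = revcomp(variant.ref), revcomp(variant.alt)
    if model.cds_seq[cds_pos - 1] != ref_c:
        raise ValueError(
            f"{variant.chrom}:{variant.pos}: REF {variant.ref!r} does not match "
            f"model {model.transcript_id} coding base "
            f"{model.cds_seq[cds_pos - 1]!r} at c.{cds_pos}")
    start = (codon_index - 1) * 3
    ref_codon = model.cds_seq[start:start + 3]
    alt_codon = ref_codon[:codon_offset] + alt_c + ref_codon[codon_offset + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        cls = "synonymous"
    elif alt_aa == "*":
        cls = "nonsense"
    elif ref_aa == "*":
        cls = "stop_lost"
    else:
        cls = "missense"
    return Consequence(
        consequence_class=cls, gene=model.gene, cds_pos=cds_pos,
        codon_index=codon_index, codon_offset=codon_offset,
        ref_aa=ref_aa, alt_aa=alt_aa,
        hgvs_c=f"c.{cds_pos}{ref_c}>{alt_c}",
        hgvs_p=f"p.{ref_aa}{codon_index}{alt_aa}",
    )


def inframe_replacement_codons(ref_codons: int, inserted_bp: int, deleted_bp: int) -> int:
    """Codon count of the segment replacing ``ref_codons`` reference codons
    after an in-frame insertion/deletion combination.

    E.g. a 15 bp insertion combined with a 3 bp deletion inside a two-codon
    reference segment yields (2*3 - 3 + 15) / 3 = 6 replacement codons.
    Raises ``ValueError`` if the net length change is not a multiple of 3
    (a frameshift, outside this arithmetic).
    """
    replaced = ref_codons * 3 - deleted_bp + inserted_bp
    if replaced < 0 or (inserted_bp - deleted_bp) % 3 != 0:
        raise ValueError(
            f"not an in-frame replacement: {ref_codons} codons, +{inserted_bp} bp, "
            f"-{deleted_bp} bp")
    return replaced // 3


# ---------------------------------------------------------------------------
# Filter cascade


def filter_region(variants: list[VariantRecord], interval: HomozygosityInterval
                  ) -> list[VariantRecord]:
    """Keep variants with the interval's chromosome and start <= pos <= end
    (boundaries inclusive)."""
    return [v for v in variants if interval.contains(v.chrom, v.pos)]


def filter_genotype_pattern(variants: list[VariantRecord], roles: PhenotypeTable,
                            allow_missing: bool = False) -> list[VariantRecord]:
    """Keep variants whose genotypes match recessive segregation: every
    affected homozygous-alternate, every wild type homozygous-reference,
    every carrier heterozygous.

    With ``allow_missing=False`` (default) a missing genotype in any required
    animal removes the record; with True that animal is simply ignored.
    """
    required = {"affected": HOM_ALT, "wild_type": HOM_REF, "carrier": HET}
    panel = [(ind, required[st]) for ind, st in roles.status.items() if st in required]
    if not any(roles.status.get(ind) == "affected" for ind, _ in panel):
        raise ConfigurationError("no affected animal among the sequenced samples")

    kept = []
    for v in variants:
        ok = True
        for ind, want in panel:
            g = v.genotypes.get(ind, MISSING)
            if g == MISSING:
                if not allow_missing:
                    ok = False
                    break
                continue
            if g != want:
                ok = False
                break
        if ok:
            kept.append(v)
    return kept


def filter_known(variants: list[VariantRecord],
                 known_ids: set[str] | None,
                 chip_positions: set[tuple[str, int]] | None
                 ) -> tuple[list[VariantRecord], tuple[int, int]]:
    """Two recorded sub-steps mirroring the catalogued-variant exclusions.

    Sub-step 1 removes records whose ``known_id`` is in ``known_ids``; passing
    ``known_ids=None`` means "any assigned ID" (every non-null ID is treated as
    catalogued). Sub-step 2 removes records whose (chrom, pos) is in
    ``chip_positions`` (alleles are not compared). Returns the survivors and
    the cumulative counts after each sub-step.
    """
    if known_ids is None:
        after_ids = [v for v in variants if v.known_id is None]
    else:
        after_ids = [v for v in variants if v.known_id not in known_ids]
    chip_positions = chip_positions or set()
    after_chip = [v for v in after_ids
                  if (v.chrom, v.pos) not in chip_positions and not v.is_chip_site]
    return after_chip, (len(after_ids), len(after_chip))


@dataclass
class CascadeReport:
    """Ordered filter-step survivor counts plus the final ranked candidates."""

    steps: list[tuple[str, int]]
    candidates: list[tuple[VariantRecord, Consequence]] = field(default_factory=list)

    def __post_init__(self):
        names = [s for s, _ in self.steps]
        if names != list(CASCADE_STEPS):
            raise ValueError(f"cascade steps must be {CASCADE_STEPS}, got {names}")
        counts = [n for _, n in self.steps]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"cascade counts must be nonincreasing, got {counts}")

    def count(self, step_name: str) -> int:
        return dict(self.steps)[step_name]

    def format_table(self) -> str:
        """Two-column rendering: step name, number of surviving polymorphisms."""
        lines = ["step\tn_remaining"]
        lines += [f"{name}\t{n}" for name, n in self.steps]
        return "\n".join(lines)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.format_table() + "\n")
            fh.write("#\n#chrom\tpos\tref\talt\tid\tgene\tconsequence"
                     "\taa_substitution\thgvs_c\thgvs_p\tconservation\n")
            for v, c in self.candidates:
                cons = "" if getattr(v, "_conservation", None) is None \
                    else f"{v._conservation:.4f}"
                fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.known_id or '.'}"
                         f"\t{c.gene or '.'}\t{c.consequence_class}"
                         f"\t{(c.ref_aa or '')}/{(c.alt_aa or '')}"
                         f"\t{c.hgvs_c or '.'}\t{c.hgvs_p or '.'}\t{cons}\n")


def run_cascade(variants: list[VariantRecord], interval: HomozygosityInterval,
                roles: PhenotypeTable,
                known_ids: set[str] | None = None,
                chip_positions: set[tuple[str, int]] | None = None,
                models: list[GeneModel] | None = None,
                allow_missing: bool = False,
                conservation: dict[tuple[str, int], float] | None = None
                ) -> CascadeReport:
    """Apply the five filter steps in order and report survivor counts.

    The final step keeps only missense/nonsense/stop-lost SNVs; indels reach
    that step but are classified unsupported and removed there (never counted
    as protein-changing). Candidates are ranked novel-ID first, then by the
    supplied per-site conservation score (descending), then by position.
    """
    s1 = filter_region(variants, interval)
    s2 = filter_genotype_pattern(s1, roles, allow_missing=allow_missing)
    s3_4, (n3, n4) = filter_known(s2, known_ids, chip_positions)

    candidates: list[tuple[VariantRecord, Consequence]] = []
    for v in s3_4:
        try:
            cons = annotate_consequence(v, models or [])
        except UnsupportedVariantError:
            continue
        if cons.is_nonsynonymous:
            candidates.append((v, cons))

    conservation = conservation or {}
    for v, _ in candidates:
        v._conservation = conservation.get((v.chrom, v.pos))
    candidates.sort(key=lambda vc: (
        vc[0].known_id is not None,
        -(conservation.get((vc[0].chrom, vc[0].pos), 0.0)),
        vc[0].chrom, vc[0].pos))

    steps = [("interval", len(s1)), ("genotype_pattern", len(s2)),
             ("not_in_known_ids", n3), ("not_on_chip", n4),
             ("nonsynonymous", len(candidates))]
    return CascadeReport(steps=steps, candidates=candidates)


def conservation_score(alignment, column_index: int) -> float:
    """Fraction of non-gap sequences matching the column's majority residue.

    ``alignment`` is a list of equal-length aligned strings (or objects with a
    string ``seq``); ``column_index`` is 0-based. Ties for the majority residue
    are broken toward the first (reference) sequence's residue when it is among
    the tied residues. An all-gap column raises ``ValueError``.
    """
    seqs = [str(getattr(s, "seq", s)) for s in alignment]
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    if not 0 <= column_index < length:
        raise IndexError(f"column {column_index} outside alignment of length {length}")
    column = [s[column_index] for s in seqs]
    residues = [r for r in column if r not in "-."]
    if not residues:
        raise ValueError(f"column {column_index} is all-gap")
    counts: dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    top = max(counts.values())
    tied = {r for r, c in counts.items() if c == top}
    ref_residue = column[0]
    majority = ref_residue if ref_residue in tied else sorted(tied)[0]
    return counts[majority] / len(residues)
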