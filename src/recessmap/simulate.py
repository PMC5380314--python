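"""Gene-drop synthetic-data generator.

Emulates the statistical structure of a livestock recessive-disease mapping
study: a single founder sire introduces a fully penetrant recessive mutation
into a closed breeding population several generations before the present; his
heavy use in artificial insemination concentrates the allele; affected calves
in the last generations are homozygous identical-by-descent for the founder
haplotype around the causal site. The generator produces

* a pedigree with the designated carrier founder,
* phased chip-marker haplotypes dropped through the pedigree under Mendelian
  transmission with Haldane (Poisson, no-interference) recombination,
* an affected/control genotyping cohort (default 12 affected + 123 controls on
  a 3,000-marker, 100 Mb chromosome — a desk-scale stand-in for a 50K array),
* a WGS-like variant table for a four-animal panel (two affected, one obligate
  carrier, one wild type) with dbSNP-like IDs, chip-site overlaps and coding
  consequences drawn from synthetic gene models, and the causal variant
  implanted as a novel missense SNV,
* the generative truth (causal position, per-animal causal genotypes, the
  shared homozygous interval) for downstream validation.

One global seed is split into named substreams (pedigree, markers, genes/
variants, drop, cohort, error) so stages are individually reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SimulationError
from .io import (GeneModel, GenotypeMatrix, MarkerMap, PhenotypeTable,
                 VariantRecord, revcomp, write_gff3, write_ped_map, write_vcf,
                 write_phenotypes)

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                   if a + b + c not in _STOPS]

_CODON_AA = {}


def _codon_aa(codon: str) -> str:
    aa = _CODON_AA.get(codon)
    if aa is None:
        from Bio.Seq import Seq
        aa = str(Seq(codon).translate())
        _CODON_AA[codon] = aa
    return aa


@dataclass
class SimulationConfig:
    """Study-design parameters of the gene-drop generator.

    The cohort sizes (12 affected, 123 controls), the four-animal sequencing
    panel and the founder usage fraction mirror the motivating study design;
    the chromosome (100 Mb, 3,000 markers, 1 cM/Mb) is a desk-scale stand-in
    for a genome-wide 50K array. Demography (8 generations of 600, founder
    pools, immigrants) is a plausibility choice documented in the methods
    note. All outputs are fully determined by ``seed``.
    """

    seed: int = 0
    # demography
    n_generations: int = 8
    generation_size: int = 600
    n_founder_males: int = 40
    n_founder_females: int = 360
    founders_per_generation: int = 10      # immigrant founder females per generation
    founder_sire_usage_fraction: float = 0.06
    # chromosome / chip
    chrom: str = "7"
    chrom_length: int = 100_000_000        # bp
    n_chip_markers: int = 3000
    recomb_rate: float = 1.0               # cM per Mb, Haldane, sex-averaged
    allele_freq_beta: tuple[float, float] = (2.0, 2.0)   # chip allele-1 frequency
    founder_ld: float = 0.5                # first-order Markov adjacency copy prob.
    # causal variant
    causal_pos: int = 93_500_000           # near the telomeric end
    # WGS-like variant table
    n_background_variants: int = 3000
    variant_freq_beta: tuple[float, float] = (1.0, 3.0)  # background ALT frequency
    known_id_probability: float = 0.4
    chip_overlap_probability: float = 0.3
    fraction_coding: float = 0.02
    fraction_nonsynonymous: float = 0.7
    n_genes: int = 60
    # cohort
    n_affected: int = 12
    n_controls: int = 123
    genotyping_error: float = 0.0          # per-call probability on chip output

    def __post_init__(self):
        for name in ("founder_sire_usage_fraction", "founder_ld",
                     "known_id_probability", "chip_overlap_probability",
                     "fraction_coding", "fraction_nonsynonymous",
                     "genotyping_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        if not 1 <= self.causal_pos <= self.chrom_length:
            raise ValueError("causal_pos must lie within the chromosome")
        if self.n_generations < 2:
            raise ValueError("n_generations must be >= 2")

    def substreams(self, attempt: int = 0) -> dict[str, np.random.Generator]:
        """Named, independent RNG streams, fully determined by (seed, attempt).

        ``attempt`` indexes ascertainment retries (see
        :func:`simulate_study`); each attempt re-draws every stream.
        """
        names = ("pedigree", "markers", "genes", "drop", "cohort", "error",
                 "founder_variants")
        children = np.random.SeedSequence([self.seed, attempt]).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class PedigreeIndividual:
    """Node in the gene-drop pedigree.

    ``causal_genotype`` is the number of causal-allele copies (2 implies the
    affected phenotype — full penetrance, no phenocopies). The two transmission
    flags record which gamete carried the causal allele; haplotype 0 is the
    paternal gamete, haplotype 1 the maternal one (for generation-0 founders
    the two haplotypes are founder-drawn and the carrier founder holds his
    causal allele on haplotype 0).
    """

    id: str
    sire_id: str | None
    dam_id: str | None
    sex: str                 # "M" or "F"
    generation: int
    causal_genotype: int = 0
    causal_from_sire: bool = False
    causal_from_dam: bool = False

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None

    @property
    def affected(self) -> bool:
        return self.causal_genotype == 2


FOUNDER_ID = "FOUNDER"


def build_pedigree(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> list[PedigreeIndividual]:
    """Forward-build the pedigree and transmit the causal allele.

    Exactly one generation-0 male (``FOUNDER``) is the designated carrier; he
    sires approximately ``founder_sire_usage_fraction`` of each subsequent
    generation's offspring (AI semen persists across years), so all causal
    alleles in the population descend from him. Returned in generation order.
    """
    rng = rng if rng is not None else config.substreams()["pedigree"]
    pedigree: list[PedigreeIndividual] = []

    males = [FOUNDER_ID]
    pedigree.append(PedigreeIndividual(FOUNDER_ID, None, None, "M", 0,
                                       causal_genotype=1, causal_from_sire=True))
    for i in range(1, config.n_founder_males):
        pid = f"G0_M{i:03d}"
        pedigree.append(PedigreeIndividual(pid, None, None, "M", 0))
        males.append(pid)
    females = []
    for i in range(config.n_founder_females):
        pid = f"G0_F{i:03d}"
        pedigree.append(PedigreeIndividual(pid, None, None, "F", 0))
        females.append(pid)

    by_id = {p.id: p for p in pedigree}
    for g in range(1, config.n_generations + 1):
        if not males or not females:
            raise SimulationError(
                f"population died out at generation {g} (no "
                f"{'males' if not males else 'females'}); increase "
                "generation_size or founder pool sizes")
        n = config.generation_size
        use_founder = rng.random(n) < config.founder_sire_usage_fraction
        sire_idx = rng.integers(0, len(males), size=n)
        dam_idx = rng.integers(0, len(females), size=n)
        sexes = rng.random(n) < 0.5
        coin_s = rng.random(n) < 0.5
        coin_d = rng.random(n) < 0.5

        next_males, next_females = [], []
        for k in range(n):
            sire = FOUNDER_ID if use_founder[k] else males[sire_idx[k]]
            dam = females[dam_idx[k]]
            sp, dp = by_id[sire], by_id[dam]
            from_sire = sp.causal_genotype == 2 or (sp.causal_genotype == 1 and coin_s[k])
            from_dam = dp.causal_genotype == 2 or (dp.causal_genotype == 1 and coin_d[k])
            sex = "M" if sexes[k] else "F"
            pid = f"G{g}_{k:04d}"
            ind = PedigreeIndividual(pid, sire, dam, sex, g,
                                     causal_genotype=int(from_sire) + int(from_dam),
                                     causal_from_sire=bool(from_sire),
                                     causal_from_dam=bool(from_dam))
            pedigree.append(ind)
            by_id[pid] = ind
            (next_males if sex == "M" else next_females).append(pid)
        for i in range(config.founders_per_generation):
            pid = f"G{g}_IMM{i:02d}"
            ind = PedigreeIndividual(pid, None, None, "F", g)
            pedigree.append(ind)
            by_id[pid] = ind
            next_females.append(pid)
        males, females = next_males, next_females
    return pedigree


def find_common_ancestors(pedigree: list[PedigreeIndividual], ids) -> set[str]:
    """Individuals ancestral to *every* id in the query set.

    Strict ancestors: a query member is returned only if it is itself an
    ancestor of all the other query members.
    """
    by_id = {p.id: p for p in pedigree}
    ids = set(ids)
    unknown = ids - by_id.keys()
    if unknown:
        raise KeyError(f"unknown individual ids: {sorted(unknown)}")

    def ancestors(start: str) -> set[str]:
        seen: set[str] = set()
        stack = [start]
        while stack:
            p = by_id[stack.pop()]
            for parent in (p.sire_id, p.dam_id):
                if parent is not None and parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    anc = {i: ancestors(i) for i in ids}
    common = set.intersection(*anc.values()) if anc else set()
    for member in ids:
        others = ids - {member}
        if others and all(member in anc[o] for o in others):
            common.add(member)
    return common


# ---------------------------------------------------------------------------
# Chromosome synthesis: markers, genome, genes, variant sites


def make_marker_map(config: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[MarkerMap, np.ndarray]:
    """Random chip marker positions with per-marker allele-1 frequencies."""
    import pandas as pd

    pos = np.sort(rng.choice(config.chrom_length, size=config.n_chip_markers,
                             replace=False)) + 1
    pairs = [rng.permutation(4)[:2] for _ in range(config.n_chip_markers)]
    a1 = [_BASES[p[0]] for p in pairs]
    a2 = [_BASES[p[1]] for p in pairs]
    ids = [f"M{i:06d}" for i in range(config.n_chip_markers)]
    mm = MarkerMap(pd.DataFrame({
        "marker_id": ids, "chrom": config.chrom, "pos": pos,
        "allele1": a1, "allele2": a2}))
    freqs = rng.beta(*config.allele_freq_beta, size=config.n_chip_markers)
    return mm, freqs


class SyntheticGenome:
    """A chromosome whose sequence is explicit inside gene exons and a
    deterministic pseudo-random filler elsewhere (random access, no 100 Mb
    array held in memory)."""

    def __init__(self, chrom: str, length: int, salt: int):
        self.chrom = chrom
        self.length = length
        self.salt = int(salt)
        self._starts = np.empty(0, dtype=np.int64)
        self._ends = np.empty(0, dtype=np.int64)
        self._seqs: list[str] = []

    def add_segment(self, start: int, seq: str) -> None:
        """Pin explicit sequence at [start, start+len-1] (1-based)."""
        self._starts = np.append(self._starts, start)
        self._ends = np.append(self._ends, start + len(seq) - 1)
        self._seqs.append(seq)
        order = np.argsort(self._starts)
        self._starts = self._starts[order]
        self._ends = self._ends[order]
        self._seqs = [self._seqs[i] for i in order]

    def _filler(self, pos: int) -> str:
        h = (pos * 2654435761 + self.salt) & 0xFFFFFFFF
        return _BASES[(h >> 7) & 3]

    def base(self, pos: int) -> str:
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside chromosome of length {self.length}")
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        if i >= 0 and pos <= self._ends[i]:
            return self._seqs[i][pos - self._starts[i]]
        return self._filler(pos)

    def in_segment(self, pos: int) -> bool:
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        return i >= 0 and pos <= self._ends[i]

    def slice(self, start: int, end: int) -> str:
        h = (np.arange(start, end + 1, dtype=np.int64) * 2654435761 + self.salt) \
            & 0xFFFFFFFF
        idx = (h >> 7) & 3
        arr = np.frombuffer(_BASES.encode(), dtype="S1")[idx].copy()
        lo = np.searchsorted(self._ends, start, side="left")
        for i in range(lo, len(self._seqs)):
            s = int(self._starts[i])
            if s > end:
                break
            e = int(self._ends[i])
            a, b = max(s, start), min(e, end)
            arr[a - start:b - start + 1] = np.frombuffer(
                self._seqs[i][a - s:b - s + 1].encode(), dtype="S1")
        return arr.tobytes().decode()

    def write_fasta(self, path, line_width: int = 60, chunk: int = 1_000_020) -> None:
        chunk -= chunk % line_width  # keep every non-final line full width
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for start in range(1, self.length + 1, chunk):
                end = min(start + chunk - 1, self.length)
                seq = self.slice(start, end)
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i:i + line_width] + "\n")


#: coding position (1-based) of the implanted causal substitution in the
#: disease transcript; its codon is CGC (Arg) and the ALT creates TGC (Cys)
CAUSAL_CDS_POS = 376
_DISEASE_CDS_CODONS = 420  # incl. terminal stop


def make_gene_models(config: SimulationConfig, rng: np.random.Generator
                     ) -> tuple[list[GeneModel], SyntheticGenome]:
    """Synthesise non-overlapping protein-coding gene models.

    The disease gene is a plus-strand single-exon transcript placed so that
    ``causal_pos`` falls at coding position 376, first base of codon 126
    (codon CGC); remaining genes are random 1-3 exon models on either strand.
    """
    genome = SyntheticGenome(config.chrom, config.chrom_length,
                             salt=int(rng.integers(2**31)))
    models: list[GeneModel] = []
    spans: list[tuple[int, int]] = []

    # disease gene
    n_codons = _DISEASE_CDS_CODONS
    codons = [ _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS),
                                                        size=n_codons) ]
    codons[125] = "CGC"            # codon 126; c.376 is its first base
    codons[-1] = "TAA"
    cds = "".join(codons)
    start = config.causal_pos - (CAUSAL_CDS_POS - 1)
    if start < 1 or start + len(cds) - 1 > config.chrom_length:
        raise SimulationError("causal_pos too close to a chromosome end for the "
                              "disease transcript")
    disease = GeneModel("DGENE.t1", "DGENE", config.chrom, "+",
                        [(start, start + len(cds) - 1)], cds)
    models.append(disease)
    spans.append((disease.gene_start, disease.gene_end))
    genome.add_segment(start, cds)

    attempts = 0
    while len(models) < config.n_genes and attempts < config.n_genes * 50:
        attempts += 1
        n_cod = int(rng.integers(100, 400))
        n_ex = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, n_cod * 3), size=n_ex - 1,
                                  replace=False)) if n_ex > 1 else np.empty(0, int)
        lens = np.diff(np.concatenate(([0], cuts, [n_cod * 3])))
        introns = rng.integers(200, 2000, size=n_ex - 1)
        total = int(lens.sum() + introns.sum())
        gstart = int(rng.integers(1, config.chrom_length - total))
        gend = gstart + total - 1
        if any(not (gend < s - 1000 or gstart > e + 1000) for s, e in spans):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        codons = [_NONSTOP_CODONS[i] for i in rng.integers(
            0, len(_NONSTOP_CODONS), size=n_cod)]
        codons[-1] = "TAA"
        cds = "".join(codons)
        exons = []
        p = gstart
        for i, ln in enumerate(lens):
            exons.append((p, p + int(ln) - 1))
            p += int(ln) + (int(introns[i]) if i < n_ex - 1 else 0)
        # split the transcript-orientation CDS into genomic exon chunks
        tr_order = exons if strand == "+" else list(reversed(exons))
        cum = 0
        for s, e in tr_order:
            chunk = cds[cum:cum + (e - s + 1)]
            cum += e - s + 1
            genome.add_segment(s, chunk if strand == "+" else revcomp(chunk))
        models.append(GeneModel(f"GENE{len(models):03d}.t1", f"GENE{len(models):03d}",
                                config.chrom, strand, exons, cds))
        spans.append((gstart, gend))
    if len(models) < config.n_genes:
        logger.warning("placed only %d of %d requested genes", len(models),
                       config.n_genes)
    return models, genome


@dataclass
class VariantSites:
    """Background + causal variant sites segregating in the gene drop."""

    chrom: str
    positions: np.ndarray          # int64, ascending
    ref: list[str]
    alt: list[str]
    ids: list[str | None]          # dbSNP-like IDs; None = novel
    on_chip: np.ndarray            # bool: site coincides with a chip marker
    alt_freqs: np.ndarray          # founder ALT-allele frequency
    causal_index: int

    def __len__(self) -> int:
        return len(self.positions)


def make_variant_sites(config: SimulationConfig, rng: np.random.Generator,
                       marker_map: MarkerMap, genome: SyntheticGenome,
                       models: list[GeneModel]) -> VariantSites:
    """Place background variants and the causal site.

    Each background variant is independently tagged as a chip-coinciding site
    (placed exactly at a marker position so the positional chip filter works
    as in the real pipeline) or as a coding variant inside a synthetic CDS
    (consequence class steered by ``fraction_nonsynonymous``); the remainder
    fall uniformly in non-CDS sequence. The causal site at ``causal_pos`` is
    novel, off-chip, and missense by construction.
    """
    V = config.n_background_variants
    used: set[int] = {config.causal_pos}
    chip_eligible = [int(p) for p in marker_map.positions
                     if not genome.in_segment(int(p)) and int(p) != config.causal_pos]

    cat = rng.random(V)
    is_chip = cat < config.chip_overlap_probability
    is_coding = (~is_chip) & (rng.random(V) < config.fraction_coding)
    n_chip = int(is_chip.sum())
    if n_chip > len(chip_eligible):
        raise SimulationError("more chip-coinciding variants requested than "
                              "eligible marker positions")
    chip_pos = rng.choice(len(chip_eligible), size=n_chip, replace=False)
    chip_iter = iter(chip_eligible[i] for i in chip_pos)

    positions = np.empty(V, dtype=np.int64)
    refs: list[str] = []
    alts: list[str] = []
    for i in range(V):
        if is_chip[i]:
            pos = next(chip_iter)
            if pos in used:          # marker may already host a variant
                pos = _draw_noncoding(config, rng, genome, used)
                is_chip[i] = False
            ref = genome.base(pos)
            alt = _other_base(rng, ref)
        elif is_coding[i]:
            pos, ref, alt = _draw_coding(config, rng, models, used)
        else:
            pos = _draw_noncoding(config, rng, genome, used)
            ref = genome.base(pos)
            alt = _other_base(rng, ref)
        if pos == config.causal_pos:
            logger.warning("background variant collided with causal_pos %d; "
                           "repositioned", pos)
            pos = _draw_noncoding(config, rng, genome, used)
            ref = genome.base(pos)
            alt = _other_base(rng, ref)
        used.add(pos)
        positions[i] = pos
        refs.append(ref)
        alts.append(alt)

    known = rng.random(V) < config.known_id_probability
    ids: list[str | None] = [f"rs{100000 + i}" if known[i] else None for i in range(V)]
    freqs = rng.beta(*config.variant_freq_beta, size=V)

    # implant the causal site
    disease = models[0]
    cpos = disease.genomic_position(CAUSAL_CDS_POS)
    assert cpos == config.causal_pos
    positions = np.append(positions, cpos)
    refs.append(disease.cds_seq[CAUSAL_CDS_POS - 1])    # "C"
    alts.append("T")
    ids.append(None)
    is_chip = np.append(is_chip, False)
    freqs = np.append(freqs, 0.0)

    order = np.argsort(positions, kind="stable")
    causal_index = int(np.flatnonzero(order == V)[0])
    return VariantSites(
        chrom=config.chrom,
        positions=positions[order],
        ref=[refs[i] for i in order],
        alt=[alts[i] for i in order],
        ids=[ids[i] for i in order],
        on_chip=is_chip[order],
        alt_freqs=freqs[order],
        causal_index=causal_index,
    )


def _other_base(rng, ref: str) -> str:
    others = [b for b in _BASES if b != ref]
    return others[int(rng.integers(3))]


def _draw_noncoding(config, rng, genome: SyntheticGenome, used: set[int]) -> int:
    for _ in range(1000):
        pos = int(rng.integers(1, config.chrom_length + 1))
        if pos not in used and not genome.in_segment(pos):
            return pos
    raise SimulationError("could not place a non-coding background variant")


def _draw_coding(config, rng, models: list[GeneModel], used: set[int]
                 ) -> tuple[int, str, str]:
    for _ in range(1000):
        m = models[int(rng.integers(len(models)))]
        cds_pos = int(rng.integers(1, m.cds_length + 1))
        pos = m.genomic_position(cds_pos)
        if pos in used:
            continue
        codon_i = (cds_pos - 1) // 3
        off = (cds_pos - 1) % 3
        codon = m.cds_seq[codon_i * 3:codon_i * 3 + 3]
        ref_aa = _codon_aa(codon)
        syn, nonsyn = [], []
        for b in _BASES:
            if b == codon[off]:
                continue
            alt_aa = _codon_aa(codon[:off] + b + codon[off + 1:])
            (syn if alt_aa == ref_aa else nonsyn).append(b)
        want_nonsyn = rng.random() < config.fraction_nonsynonymous
        pool = nonsyn if (want_nonsyn or not syn) else syn
        if not pool:
            pool = syn
        alt_c = pool[int(rng.integers(len(pool)))]
        ref_c = codon[off]
        if m.strand == "-":
            return pos, revcomp(ref_c), revcomp(alt_c)
        return pos, ref_c, alt_c
    raise SimulationError("could not place a coding background variant")


# ---------------------------------------------------------------------------
# Gene drop


@dataclass
class PhasedGenotypes:
    """Phased haplotypes for every pedigree member.

    ``marker_haps[i, k, j]`` is 0 (map allele1) or 1 (allele2) for individual
    i, haplotype k (0 = paternal gamete), marker j; ``variant_haps`` likewise
    codes 0 = REF, 1 = ALT over :class:`VariantSites`. Every non-founder
    haplotype is a crossover mosaic of exactly one parent's two haplotypes.
    """

    ids: list[str]
    marker_map: MarkerMap
    marker_haps: np.ndarray                 # (n, 2, M) int8
    variant_sites: VariantSites | None = None
    variant_haps: np.ndarray | None = None  # (n, 2, V) int8
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {pid: i for i, pid in enumerate(self.ids)}

    def marker_hap(self, individual_id: str) -> np.ndarray:
        return self.marker_haps[self.index[individual_id]]

    def variant_hap(self, individual_id: str) -> np.ndarray:
        if self.variant_haps is None:
            raise ValueError("no variant sites were dropped")
        return self.variant_haps[self.index[individual_id]]

    def chip_genotypes(self, ids) -> np.ndarray:
        idx = [self.index[i] for i in ids]
        return self.marker_haps[idx].sum(axis=1).astype(np.int8)


def _founder_marker_hap(rng, freqs: np.ndarray, ld: float) -> np.ndarray:
    """One founder haplotype: first-order Markov chain over markers.

    With probability ``ld`` a marker copies its left neighbour's allele,
    otherwise it is drawn fresh from the marker's allele-1 frequency; value 1
    codes allele2 so that hap0+hap1 equals the HOM1/HET/HOM2 genotype code.
    """
    m = len(freqs)
    fresh = (rng.random(m) >= freqs).astype(np.int8)  # 1 = allele2
    copy = rng.random(m) < ld
    copy[0] = False
    src = np.where(copy, 0, np.arange(m))
    src = np.maximum.accumulate(src)
    return fresh[src]


def sample_crossover_counts(config: SimulationConfig, rng: np.random.Generator,
                            n: int) -> np.ndarray:
    """Crossover counts for n transmitted haplotypes (Poisson, Haldane)."""
    morgans = config.recomb_rate * (config.chrom_length / 1e6) / 100.0
    return rng.poisson(morgans, size=n)


def gene_drop(pedigree: list[PedigreeIndividual], marker_map: MarkerMap,
              config: SimulationConfig,
              marker_freqs: np.ndarray | None = None,
              variant_sites: VariantSites | None = None,
              rng: np.random.Generator | None = None,
              founder_variant_rng: np.random.Generator | None = None
              ) -> PhasedGenotypes:
    """Drop founder haplotypes through the pedigree.

    Transmission is Mendelian: each transmitted haplotype is a crossover
    mosaic of one parent's two haplotypes, with crossover count Poisson
    (mean = recomb_rate x chromosome length in Morgans; Haldane, no
    interference) and uniform crossover positions. The mosaic is conditioned
    (by the symmetric relabelling of the parent's haplotypes) so the causal
    allele recorded in the pedigree travels with the founder's surrounding
    marker haplotype except where crossovers occurred.
    """
    streams = None
    if rng is None or marker_freqs is None or (
            variant_sites is not None and founder_variant_rng is None):
        streams = config.substreams()
    rng = rng if rng is not None else streams["drop"]
    if marker_freqs is None:
        _, marker_freqs = make_marker_map(config, streams["markers"])
    if variant_sites is not None and founder_variant_rng is None:
        founder_variant_rng = streams["founder_variants"]

    n = len(pedigree)
    M = len(marker_map)
    ids = [p.id for p in pedigree]
    index = {pid: i for i, pid in enumerate(ids)}
    marker_pos = marker_map.positions.astype(np.float64)
    marker_haps = np.empty((n, 2, M), dtype=np.int8)

    with_vars = variant_sites is not None
    if with_vars:
        V = len(variant_sites)
        var_pos = variant_sites.positions.astype(np.float64)
        variant_haps = np.empty((n, 2, V), dtype=np.int8)
    else:
        variant_haps = None

    morgans = config.recomb_rate * (config.chrom_length / 1e6) / 100.0
    L = float(config.chrom_length)
    causal = float(config.causal_pos)
    arangeM = np.arange(M)
    if with_vars:
        arangeV = np.arange(V)

    for i, p in enumerate(pedigree):
        if p.is_founder:
            for k in range(2):
                marker_haps[i, k] = _founder_marker_hap(rng, marker_freqs,
                                                        config.founder_ld)
                if with_vars:
                    # separate stream: the marker drop is identical whether or
                    # not variant sites are carried along
                    variant_haps[i, k] = (
                        founder_variant_rng.random(V)
                        < variant_sites.alt_freqs).astype(np.int8)
            if with_vars and p.causal_genotype:
                # designated carrier founder: causal allele on haplotype 0
                variant_haps[i, 0, variant_sites.causal_index] = 1
                if p.causal_genotype == 2:
                    variant_haps[i, 1, variant_sites.causal_index] = 1
            continue
        for k, (parent_id, child_has_causal) in enumerate(
                ((p.sire_id, p.causal_from_sire), (p.dam_id, p.causal_from_dam))):
            pi = index[parent_id]
            parent = pedigree[pi]
            ncross = int(rng.poisson(morgans))
            cross = np.sort(rng.uniform(0.0, L, size=ncross)) if ncross else \
                np.empty(0, dtype=np.float64)
            start = int(rng.integers(2))
            if parent.causal_genotype == 1:
                parent_causal_hap = 0 if parent.causal_from_sire else 1
                sel_at_causal = (start + int(np.searchsorted(cross, causal))) % 2
                want = parent_causal_hap if child_has_causal else 1 - parent_causal_hap
                if sel_at_causal != want:
                    start = 1 - start
            sel = (start + np.searchsorted(cross, marker_pos)) % 2
            marker_haps[i, k] = marker_haps[pi][sel, arangeM]
            if with_vars:
                selv = (start + np.searchsorted(cross, var_pos)) % 2
                variant_haps[i, k] = variant_haps[pi][selv, arangeV]

    return PhasedGenotypes(ids=ids, marker_map=marker_map,
                           marker_haps=marker_haps,
                           variant_sites=variant_sites,
                           variant_haps=variant_haps, index=index)


def mendelian_violations(pedigree: list[PedigreeIndividual],
                         phased: PhasedGenotypes) -> int:
    """Number of (individual, haplotype, locus) cells where a transmitted
    allele is absent from the corresponding parent — zero for any valid drop."""
    total = 0
    for p in pedigree:
        if p.is_founder:
            continue
        i = phased.index[p.id]
        for k, parent_id in enumerate((p.sire_id, p.dam_id)):
            pi = phased.index[parent_id]
            child = phased.marker_haps[i, k]
            par = phased.marker_haps[pi]
            total += int(((child != par[0]) & (child != par[1])).sum())
            if phased.variant_haps is not None:
                childv = phased.variant_haps[i, k]
                parv = phased.variant_haps[pi]
                total += int(((childv != parv[0]) & (childv != parv[1])).sum())
    return total


# ---------------------------------------------------------------------------
# Cohort selection, chip output, variant table


def select_cohort(pedigree: list[PedigreeIndividual], phased: PhasedGenotypes,
                  n_affected: int, n_controls: int,
                  seed: int | np.random.Generator = 0) -> PhenotypeTable:
    """Draw the genotyping cohort and nominate the sequencing quartet.

    Affected animals are sampled from homozygous-causal individuals of the
    last three generations; controls from unaffected (causal genotype 0 or 1)
    late-generation animals — mirroring a cohort "known to be unaffected", so
    silent carriers are allowed among controls. The quartet is two of the
    selected affected, one obligate carrier (a heterozygous parent of an
    affected) and one wild-type animal; its ids are stored in
    ``PhenotypeTable.quartet`` in that order.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    max_gen = max(p.generation for p in pedigree)
    late = [p for p in pedigree if p.generation >= max_gen - 2]
    aff_pool = [p.id for p in late if p.causal_genotype == 2]
    if len(aff_pool) < n_affected:
        raise SimulationError(
            f"only {len(aff_pool)} affected individuals available "
            f"(need {n_affected}); increase n_generations or "
            "founder_sire_usage_fraction")
    affected = [str(a) for a in rng.choice(aff_pool, size=n_affected, replace=False)]

    by_id = {p.id: p for p in pedigree}
    quartet_aff = [str(a) for a in rng.choice(affected, size=2, replace=False)]
    carrier_pool = sorted({par for a in quartet_aff
                           for par in (by_id[a].sire_id, by_id[a].dam_id)
                           if par and by_id[par].causal_genotype == 1})
    if not carrier_pool:
        carrier_pool = [p.id for p in late if p.causal_genotype == 1]
    if not carrier_pool:
        raise SimulationError("no heterozygous carrier available for the quartet")
    carrier = str(rng.choice(carrier_pool))

    wt_pool = [p.id for p in late if p.causal_genotype == 0 and p.id != carrier]
    if not wt_pool:
        raise SimulationError("no wild-type animal available for the quartet")
    wild_type = str(rng.choice(wt_pool))

    ctl_pool = [p.id for p in late
                if p.causal_genotype < 2 and p.id not in (carrier, wild_type)]
    if len(ctl_pool) < n_controls:
        raise SimulationError(
            f"only {len(ctl_pool)} unaffected individuals available "
            f"(need {n_controls}); increase generation_size")
    controls = [str(c) for c in rng.choice(ctl_pool, size=n_controls, replace=False)]

    status = {a: "affected" for a in affected}
    status.update({c: "control" for c in controls})
    status[carrier] = "carrier"
    status[wild_type] = "wild_type"
    return PhenotypeTable(status=status,
                          quartet=[*quartet_aff, carrier, wild_type])


def chip_genotypes(phased: PhasedGenotypes, ids,
                   error_rate: float = 0.0,
                   rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Unphased chip genotype matrix for the given animals.

    With ``error_rate`` > 0 each call is independently replaced, with that
    probability, by a uniformly drawn genotype code (which may coincide with
    the true one). Error positions at a smaller rate are a subset of those at
    a larger rate when the same generator state is used.
    """
    data = phased.chip_genotypes(ids)
    if error_rate:
        if rng is None:
            raise ValueError("an rng is required when error_rate > 0")
        u = rng.random(data.shape)
        repl = rng.integers(0, 3, size=data.shape, dtype=np.int8)
        data = np.where(u < error_rate, repl, data).astype(np.int8)
    return GenotypeMatrix(list(ids), phased.marker_map, data)


def emit_variants(phased: PhasedGenotypes, quartet: PhenotypeTable,
                  config: SimulationConfig) -> list[VariantRecord]:
    """WGS-like biallelic variant table for the sequencing quartet.

    Genotypes are read off the dropped haplotypes; the causal record is novel
    (no ID), off-chip, missense, with the recessive pattern (affected 1/1,
    carrier 0/1, wild type 0/0) guaranteed by the quartet's causal genotypes.
    """
    sites = phased.variant_sites
    if sites is None:
        raise ValueError("phased genotypes carry no variant sites")
    samples = quartet.quartet
    geno = {s: phased.variant_hap(s).sum(axis=0) for s in samples}
    records = []
    for i in range(len(sites)):
        records.append(VariantRecord(
            chrom=sites.chrom, pos=int(sites.positions[i]),
            ref=sites.ref[i], alt=sites.alt[i], known_id=sites.ids[i],
            is_chip_site=bool(sites.on_chip[i]),
            genotypes={s: int(geno[s][i]) for s in samples}))
    return records


# ---------------------------------------------------------------------------
# Whole-study convenience


@dataclass
class SimulatedStudy:
    """Everything one simulated study produces, plus the generative truth."""

    config: SimulationConfig
    pedigree: list[PedigreeIndividual]
    marker_map: MarkerMap
    marker_freqs: np.ndarray
    phased: PhasedGenotypes
    phenotypes: PhenotypeTable
    genotypes: GenotypeMatrix
    gene_models: list[GeneModel] | None = None
    genome: SyntheticGenome | None = None
    variants: list[VariantRecord] | None = None
    truth: dict = field(default_factory=dict)

    @property
    def quartet_roles(self) -> PhenotypeTable:
        """Roles restricted to the sequenced quartet (the genotype-pattern
        filter requires genotypes for every role-bearing animal)."""
        q = self.phenotypes.quartet
        return PhenotypeTable(
            status={q[0]: "affected", q[1]: "affected",
                    q[2]: "carrier", q[3]: "wild_type"},
            quartet=list(q))

    @property
    def known_ids(self) -> set[str]:
        return {v.known_id for v in (self.variants or []) if v.known_id}

    @property
    def chip_positions(self) -> set[tuple[str, int]]:
        return {(c, int(p)) for c, p in
                zip(self.marker_map.chroms, self.marker_map.positions)}


#: maximum ascertainment retries before simulate_study gives up
MAX_ASCERTAINMENT_ATTEMPTS = 60


def _cohort_feasible(pedigree: list[PedigreeIndividual],
                     config: SimulationConfig) -> bool:
    max_gen = max(p.generation for p in pedigree)
    late = [p for p in pedigree if p.generation >= max_gen - 2]
    n_aff = sum(p.causal_genotype == 2 for p in late)
    n_unaff = sum(p.causal_genotype < 2 for p in late)
    has_carrier = any(p.causal_genotype == 1 for p in late)
    has_wt = any(p.causal_genotype == 0 for p in late)
    return (n_aff >= config.n_affected
            and n_unaff >= config.n_controls + 2
            and has_carrier and has_wt)


def simulate_study(config: SimulationConfig,
                   with_variants: bool = True) -> SimulatedStudy:
    """Run the full generator: pedigree, drop, cohort, chip matrix and
    (optionally) the quartet variant table with gene models.

    A mapping study of this design exists only conditional on an outbreak —
    enough homozygous cases descending from the founder. The generator mirrors
    that ascertainment: pedigree realisations in which drift extinguishes the
    founder allele before the requested cohort exists are rejected and
    redrawn from a deterministically derived sub-seed, so a given ``seed``
    still yields one reproducible study. If no feasible pedigree appears
    within :data:`MAX_ASCERTAINMENT_ATTEMPTS`, the design itself is judged
    infeasible and a :class:`SimulationError` is raised.
    """
    pedigree = streams = None
    for attempt in range(MAX_ASCERTAINMENT_ATTEMPTS):
        streams = config.substreams(attempt)
        candidate = build_pedigree(config, streams["pedigree"])
        if _cohort_feasible(candidate, config):
            pedigree = candidate
            if attempt:
                logger.info("ascertainment: accepted pedigree attempt %d", attempt)
            break
    if pedigree is None:
        raise SimulationError(
            f"no pedigree with {config.n_affected} affected cases in "
            f"{MAX_ASCERTAINMENT_ATTEMPTS} attempts; increase "
            "founder_sire_usage_fraction, generation_size or n_generations")
    marker_map, marker_freqs = make_marker_map(config, streams["markers"])

    models = genome = sites = None
    if with_variants:
        models, genome = make_gene_models(config, streams["genes"])
        sites = make_variant_sites(config, streams["genes"], marker_map,
                                   genome, models)

    phased = gene_drop(pedigree, marker_map, config, marker_freqs, sites,
                       streams["drop"], streams["founder_variants"])
    phenotypes = select_cohort(pedigree, phased, config.n_affected,
                               config.n_controls, streams["cohort"])
    cohort_ids = (phenotypes.affected_ids + phenotypes.control_ids
                  + phenotypes.ids_with("carrier", "wild_type"))
    genotypes = chip_genotypes(phased, cohort_ids, config.genotyping_error,
                               streams["error"])
    variants = emit_variants(phased, phenotypes, config) if with_variants else None

    truth = _compute_truth(config, pedigree, phased, phenotypes)
    return SimulatedStudy(config=config, pedigree=pedigree,
                          marker_map=marker_map, marker_freqs=marker_freqs,
                          phased=phased, phenotypes=phenotypes,
                          genotypes=genotypes, gene_models=models,
                          genome=genome, variants=variants, truth=truth)


def _compute_truth(config, pedigree, phased: PhasedGenotypes,
                   phenotypes: PhenotypeTable) -> dict:
    aff_ids = phenotypes.affected_ids
    g = phased.chip_genotypes(aff_ids)          # error-free by construction
    pos = phased.marker_map.positions
    hom_shared = (g == g[0]) .all(axis=0) & ((g[0] == 0) | (g[0] == 2))
    j = int(np.searchsorted(pos, config.causal_pos))
    anchors = [a for a in (j - 1, j) if 0 <= a < len(pos) and hom_shared[a]]
    if anchors:
        lo = hi = anchors[0]
        while lo - 1 >= 0 and hom_shared[lo - 1]:
            lo -= 1
        while hi + 1 < len(pos) and hom_shared[hi + 1]:
            hi += 1
        # the shared IBD region truly extends to the flanking discordant
        # markers (exclusive), not just to the outermost concordant marker;
        # the causal position always lies inside these bounds
        start = int(pos[lo - 1]) + 1 if lo > 0 else 1
        end = int(pos[hi + 1]) - 1 if hi + 1 < len(pos) else config.chrom_length
        interval = (start, end)
    else:
        interval = None
    return {
        "causal_chrom": config.chrom,
        "causal_pos": config.causal_pos,
        "founder_id": FOUNDER_ID,
        "shared_interval": interval,
        "causal_genotypes": {p.id: p.causal_genotype for p in pedigree},
    }


def select_test_animals(study: SimulatedStudy, n: int,
                        seed: int | np.random.Generator = 0) -> list[str]:
    """Late-generation animals outside the genotyping cohort, for evaluating
    the carrier test on unseen data."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    max_gen = max(p.generation for p in study.pedigree)
    pool = [p.id for p in study.pedigree
            if p.generation >= max_gen - 2 and p.id not in study.phenotypes]
    if len(pool) < n:
        raise SimulationError(f"only {len(pool)} unseen animals available")
    return [str(a) for a in rng.choice(pool, size=n, replace=False)]


def write_study(study: SimulatedStudy, outdir, write_fasta: bool = True) -> None:
    """Write the study to disk: cohort PED/MAP, phenotype roles, quartet VCF,
    known-ID list, gene-model GFF3 (+ genome FASTA) and the truth table."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ped_info = {p.id: (p.sire_id or "0", p.dam_id or "0",
                       "1" if p.sex == "M" else "2") for p in study.pedigree}
    write_ped_map(study.marker_map, study.genotypes, study.phenotypes,
                  out / "cohort.ped", out / "cohort.map", pedigree=ped_info)
    write_phenotypes(study.phenotypes, out / "roles.tsv")
    if study.variants is not None:
        write_vcf(study.variants, study.phenotypes.quartet, out / "quartet.vcf",
                  contig_lengths={study.config.chrom: study.config.chrom_length})
        with open(out / "known_ids.txt", "w") as fh:
            for rsid in sorted(study.known_ids):
                fh.write(rsid + "\n")
    if study.gene_models is not None:
        write_gff3(study.gene_models, out / "genes.gff3")
        if write_fasta and study.genome is not None:
            study.genome.write_fasta(out / "genome.fa")
    with open(out / "truth.tsv", "w") as fh:
        t = study.truth
        iv = t["shared_interval"]
        fh.write(f"#causal\t{t['causal_chrom']}\t{t['causal_pos']}\n")
        fh.write(f"#founder\t{t['founder_id']}\n")
        if iv:
            fh.write(f"#shared_interval\t{iv[0]}\t{iv[1]}\n")
        fh.write("individual\tcausal_genotype\n")
        for pid, cg in t["causal_genotypes"].items():
            fh.write(f"{pid}\t{cg}\n")
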