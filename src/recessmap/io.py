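"""Readers, writers and in-memory containers for the standard formats the
pipeline touches: whitespace-delimited PED/MAP chip genotypes, VCF 4.2 variant
calls, and GFF3 gene models backed by a FASTA genome.

Conventions
-----------
* All coordinates at the interface are 1-based inclusive (VCF/GFF convention).
* Chip genotypes are coded against the marker map: ``HOM1`` means two copies of
  the map's allele1, so "allele 1" has the same meaning across animals.
* Contig names must match exactly between VCF, GFF3, FASTA and MAP; there is no
  alias table, and a mismatch raises :class:`~recessmap.errors.FormatError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

# chip genotype codes (against the marker map's allele1/allele2)
HOM1 = 0
HET = 1
HOM2 = 2
MISSING = -1

# sequenced-variant genotype codes (against REF/ALT)
HOM_REF = 0
HOM_ALT = 2
# HET and MISSING are shared with the chip codes above.

STATUSES = ("affected", "control", "carrier", "wild_type", "unknown")

_PED_PHENO_TO_STATUS = {"2": "affected", "1": "control", "0": "unknown", "-9": "unknown"}
_STATUS_TO_PED_PHENO = {"affected": "2", "control": "1"}


class MarkerMap:
    """Ordered chip marker positions with their two alleles.

    Wraps a DataFrame with columns ``marker_id, chrom, pos, allele1, allele2``,
    sorted by (chrom, pos) with unique positions and ``allele1 != allele2``.
    """

    COLUMNS = ("marker_id", "chrom", "pos", "allele1", "allele2")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"marker map missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
            raise FormatError(f"duplicate marker position {dup.chrom}:{dup.pos}")
        if (df["allele1"] == df["allele2"]).any():
            bad = df[df["allele1"] == df["allele2"]].iloc[0]
            raise FormatError(f"marker {bad.marker_id} has identical alleles")
        self.df = df
        self._index = {m: i for i, m in enumerate(df["marker_id"])}

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    def index_of(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerMap) and self.df.equals(other.df)


@dataclass
class GenotypeMatrix:
    """Chip genotypes: individuals x markers, coded HOM1/HET/HOM2/MISSING."""

    individuals: list[str]
    marker_map: MarkerMap
    data: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.individuals), len(self.marker_map)):
            raise ValueError("genotype matrix shape does not match individuals x markers")
        self._row = {ind: i for i, ind in enumerate(self.individuals)}

    def row(self, individual_id: str) -> np.ndarray:
        try:
            return self.data[self._row[individual_id]]
        except KeyError:
            raise KeyError(f"unknown individual {individual_id!r}") from None

    def row_series(self, individual_id: str) -> pd.Series:
        return pd.Series(self.row(individual_id), index=self.marker_map.marker_ids)

    def subset(self, ids) -> np.ndarray:
        idx = [self._row[i] for i in ids]
        return self.data[idx]


@dataclass
class PhenotypeTable:
    """Individual id -> status from the closed set affected/control/carrier/
    wild_type/unknown, plus (optionally) the ordered WGS quartet ids."""

    status: dict[str, str]
    quartet: list[str] = field(default_factory=list)

    def __post_init__(self):
        for ind, st in self.status.items():
            if st not in STATUSES:
                raise ValueError(f"invalid status {st!r} for {ind!r}")

    def ids_with(self, *statuses: str) -> list[str]:
        return [i for i, s in self.status.items() if s in statuses]

    @property
    def affected_ids(self) -> list[str]:
        return self.ids_with("affected")

    @property
    def control_ids(self) -> list[str]:
        return self.ids_with("control")

    def __getitem__(self, ind: str) -> str:
        return self.status[ind]

    def __contains__(self, ind: str) -> bool:
        return ind in self.status


# ---------------------------------------------------------------------------
# PED/MAP


def read_map(map_path) -> MarkerMap:
    """Read a PLINK-style MAP file (chrom, marker_id, [cM,] pos[, allele1, allele2]).

    Plain 4-column PLINK MAP files carry no allele columns; a 6-column dialect
    (as written by :func:`write_ped_map`) carries the two alleles so genotype
    coding is self-contained. For 4-column input the alleles are inferred later
    from the PED file.
    """
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 6:
                chrom, mid, _cm, pos, a1, a2 = fields
            elif len(fields) == 4:
                chrom, mid, _cm, pos = fields
                a1, a2 = "?", "??"  # placeholders, resolved from PED
            else:
                raise FormatError(f"{map_path}:{lineno}: expected 4 or 6 fields, got {len(fields)}")
            rows.append((mid, chrom, int(pos), a1, a2))
    if not rows:
        raise FormatError(f"{map_path}: empty marker map")
    return MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))


def read_ped_map(ped_path, map_path) -> tuple[MarkerMap, GenotypeMatrix, PhenotypeTable]:
    """Read whitespace-delimited PED + MAP chip genotypes.

    PED rows carry 6 leading columns (family, id, sire, dam, sex, phenotype)
    followed by two allele characters per marker, in MAP row order. Phenotype
    2 -> affected, 1 -> control, 0/-9 -> unknown; the allele pair "0 0" is a
    missing genotype. An allele that matches neither map allele is a format
    error naming the marker and line.
    """
    marker_map = read_map(map_path)
    n_markers = len(marker_map)
    # PED columns follow the MAP *file* order; MarkerMap may have re-sorted.
    file_order = _map_file_order(map_path, marker_map)

    a1 = marker_map.df["allele1"].to_numpy().copy()
    a2 = marker_map.df["allele2"].to_numpy().copy()
    infer_alleles = (a1 == "?").any()

    individuals: list[str] = []
    status: dict[str, str] = {}
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields "
                    f"for {n_markers} markers, got {len(fields)}"
                )
            _fam, ind, _sire, _dam, _sex, pheno = fields[:6]
            if ind in status:
                raise FormatError(f"{ped_path}:{lineno}: duplicate individual {ind!r}")
            alleles = fields[6:]
            codes = np.empty(n_markers, dtype=np.int8)
            for j_file in range(n_markers):
                j = file_order[j_file]
                x, y = alleles[2 * j_file], alleles[2 * j_file + 1]
                if x == "0" or y == "0":
                    if x != y:
                        raise FormatError(
                            f"{ped_path}:{lineno}: half-missing genotype at marker "
                            f"{marker_map.marker_ids[j]}"
                        )
                    codes[j] = MISSING
                    continue
                if infer_alleles:
                    _register_allele(a1, a2, j, x, marker_map, ped_path, lineno)
                    _register_allele(a1, a2, j, y, marker_map, ped_path, lineno)
                n1 = (x == a1[j]) + (y == a1[j])
                n2_ = (x == a2[j]) + (y == a2[j])
                if n1 + n2_ != 2:
                    raise FormatError(
                        f"{ped_path}:{lineno}: allele {x!r}/{y!r} at marker "
                        f"{marker_map.marker_ids[j]} matches neither map allele "
                        f"({a1[j]}/{a2[j]})"
                    )
                codes[j] = HOM1 if n1 == 2 else (HOM2 if n2_ == 2 else HET)
            individuals.append(ind)
            status[ind] = _PED_PHENO_TO_STATUS.get(pheno, "unknown")
            rows.append(codes)
    if infer_alleles:
        # monomorphic markers keep a placeholder second allele
        marker_map.df["allele1"] = a1
        marker_map.df["allele2"] = a2
    data = np.vstack(rows) if rows else np.empty((0, n_markers), dtype=np.int8)
    return marker_map, GenotypeMatrix(individuals, marker_map, data), PhenotypeTable(status)


def _map_file_order(map_path, marker_map: MarkerMap) -> list[int]:
    order = []
    with open(map_path) as fh:
        for line in fh:
            fields = line.split()
            if fields:
                order.append(marker_map.index_of(fields[1]))
    return order


def _register_allele(a1, a2, j, x, marker_map, path, lineno):
    if a1[j] == "?":
        a1[j] = x
    elif x != a1[j] and a2[j] == "??":
        a2[j] = x
    elif x not in (a1[j], a2[j]):
        raise FormatError(
            f"{path}:{lineno}: marker {marker_map.marker_ids[j]} has more than "
            f"two alleles ({a1[j]}, {a2[j]}, {x})"
        )


def write_ped_map(marker_map: MarkerMap, genotypes: GenotypeMatrix,
                  phenotypes: PhenotypeTable, ped_path, map_path,
                  pedigree: dict[str, tuple[str, str, str]] | None = None) -> None:
    """Write PED/MAP in the 6-column MAP dialect (alleles included).

    ``pedigree`` optionally maps individual id -> (sire, dam, sex_code) for the
    PED parent/sex columns; unknown parents are written as 0. Statuses other
    than affected/control are written as phenotype 0 (unknown).
    """
    df = marker_map.df
    with open(map_path, "w") as fh:
        for r in df.itertuples():
            fh.write(f"{r.chrom}\t{r.marker_id}\t0\t{r.pos}\t{r.allele1}\t{r.allele2}\n")
    a1 = df["allele1"].to_numpy()
    a2 = df["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for ind in genotypes.individuals:
            sire, dam, sex = (pedigree or {}).get(ind, ("0", "0", "0"))
            pheno = _STATUS_TO_PED_PHENO.get(phenotypes.status.get(ind, "unknown"), "0")
            codes = genotypes.row(ind)
            pairs = []
            for j, c in enumerate(codes):
                if c == MISSING:
                    pairs.append("0 0")
                elif c == HOM1:
                    pairs.append(f"{a1[j]} {a1[j]}")
                elif c == HOM2:
                    pairs.append(f"{a2[j]} {a2[j]}")
                else:
                    pairs.append(f"{a1[j]} {a2[j]}")
            fh.write(f"FAM {ind} {sire} {dam} {sex} {pheno} " + " ".join(pairs) + "\n")


def write_phenotypes(phenotypes: PhenotypeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tstatus\n")
        for ind, st in phenotypes.status.items():
            fh.write(f"{ind}\t{st}\n")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return PhenotypeTable(dict(zip(df["individual"], df["status"])))


# ---------------------------------------------------------------------------
# VCF


@dataclass
class VariantRecord:
    """One biallelic variant with per-animal genotypes.

    ``genotypes`` maps sample id to HOM_REF/HET/HOM_ALT/MISSING against this
    record's ALT allele. ``known_id`` is None for novel sites (VCF ID ".").
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    known_id: str | None = None
    is_chip_site: bool = False
    genotypes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: REF equals ALT")
        for a in (self.ref, self.alt):
            if not a or set(a) - set("ACGT"):
                raise ValueError(f"{self.chrom}:{self.pos}: invalid allele {a!r}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def read_vcf(vcf_path, sample_roles: PhenotypeTable,
             chip_positions: set[tuple[str, int]] | None = None) -> list[VariantRecord]:
    """Read a VCF 4.2 into biallelic :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per ALT allele; for a split
    record a genotype is the copy number of *that* ALT (a 1/2 call is HET for
    both records). Records are returned sorted by (chrom, pos). Samples named
    in ``sample_roles`` must be present in the header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    absent = [s for s in sample_roles.status if s not in samples]
    if absent:
        raise ConfigurationError(f"samples in phenotype table absent from VCF header: {absent}")
    records: list[VariantRecord] = []
    for v in vcf:
        gts = v.genotypes  # [[a, b, phased], ...]
        for k, alt in enumerate(v.ALT, start=1):
            if set(v.REF) - set("ACGT") or set(alt) - set("ACGT"):
                logger.warning("skipping %s:%d with non-ACGT alleles", v.CHROM, v.POS)
                continue
            geno = {}
            for s, gt in zip(samples, gts):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    geno[s] = MISSING
                else:
                    geno[s] = int(a == k) + int(b == k)
            records.append(VariantRecord(
                chrom=str(v.CHROM), pos=int(v.POS), ref=v.REF, alt=alt,
                known_id=v.ID if v.ID not in (None, ".") else None,
                is_chip_site=bool(chip_positions and (str(v.CHROM), int(v.POS)) in chip_positions),
                genotypes=geno,
            ))
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    return records


def write_vcf(records: list[VariantRecord], sample_ids: list[str], path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write biallelic records as a minimal VCF 4.2 (GT only)."""
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=recessmap\n")
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            gts = "\t".join(gt_str[r.genotypes.get(s, MISSING)] for s in sample_ids)
            fh.write(f"{r.chrom}\t{r.pos}\t{r.known_id or '.'}\t{r.ref}\t{r.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3 + FASTA)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A protein-coding transcript: ordered CDS segments plus the spliced CDS.

    ``exons`` are CDS segments in ascending genomic order (1-based inclusive);
    ``cds_seq`` is the spliced coding sequence in transcript (5'->3')
    orientation, i.e. reverse-complemented for minus-strand models.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]
    cds_seq: str
    gene_start: int = 0
    gene_end: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted(self.exons)
        if not self.gene_start:
            self.gene_start = self.exons[0][0]
        if not self.gene_end:
            self.gene_end = self.exons[-1][1]
        if len(self.cds_seq) != sum(e - s + 1 for s, e in self.exons):
            raise ValueError(f"{self.transcript_id}: CDS sequence length does not match exons")

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.gene_start <= pos <= self.gene_end

    def cds_position(self, pos: int) -> int | None:
        """1-based coding coordinate of a genomic position, or None if the
        position falls outside the CDS segments (strand-aware)."""
        offset = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= pos <= e:
                    return offset + (pos - s) + 1
                offset += e - s + 1
        else:
            for s, e in reversed(self.exons):
                if s <= pos <= e:
                    return offset + (e - pos) + 1
                offset += e - s + 1
        return None

    def genomic_position(self, cds_pos: int) -> int:
        """Genomic coordinate of a 1-based coding position (inverse of
        :meth:`cds_position`)."""
        if not 1 <= cds_pos <= self.cds_length:
            raise IndexError(f"c.{cds_pos} outside CDS of length {self.cds_length}")
        offset = 0
        exons = self.exons if self.strand == "+" else list(reversed(self.exons))
        for s, e in exons:
            span = e - s + 1
            if cds_pos <= offset + span:
                within = cds_pos - offset - 1
                return s + within if self.strand == "+" else e - within
            offset += span
        raise AssertionError("unreachable")


def read_gene_models(gff_path, fasta_path) -> list[GeneModel]:
    """Load protein-coding transcripts from GFF3 + FASTA.

    CDS exons are assembled in transcript orientation (minus-strand models are
    reverse-complemented on access); models whose CDS length is not divisible
    by 3 are excluded with a warning. A CDS referencing a contig missing from
    the FASTA raises :class:`FormatError`.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    fasta = Fasta(str(fasta_path))
    models: list[GeneModel] = []
    for tr in db.features_of_type(("mRNA", "transcript")):
        cds = sorted(db.children(tr, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        if tr.seqid not in fasta:
            raise FormatError(f"transcript {tr.id}: contig {tr.seqid!r} missing from FASTA")
        length = sum(f.end - f.start + 1 for f in cds)
        if length % 3 != 0:
            logger.warning("excluding transcript %s: CDS length %d not divisible by 3",
                           tr.id, length)
            continue
        parts = [str(fasta[tr.seqid][f.start - 1:f.end]) for f in cds]
        if tr.strand == "-":
            seq = "".join(revcomp(p) for p in reversed(parts))
        else:
            seq = "".join(parts)
        gene = tr.attributes.get("gene_name", tr.attributes.get("gene", [tr.id]))[0]
        span = _gene_span(db, tr)
        models.append(GeneModel(
            transcript_id=tr.id, gene=gene, chrom=str(tr.seqid), strand=tr.strand,
            exons=[(f.start, f.end) for f in cds], cds_seq=seq.upper(),
            gene_start=span[0], gene_end=span[1],
        ))
    return models


def _gene_span(db, tr) -> tuple[int, int]:
    for parent in db.parents(tr, featuretype="gene"):
        return parent.start, parent.end
    return tr.start, tr.end


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene/mRNA/CDS features for a list of models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(f"{m.chrom}\trecessmap\tgene\t{m.gene_start}\t{m.gene_end}\t.\t"
                     f"{m.strand}\t.\tID=gene:{m.gene};gene_name={m.gene}\n")
            fh.write(f"{m.chrom}\trecessmap\tmRNA\t{m.gene_start}\t{m.gene_end}\t.\t"
                     f"{m.strand}\t.\tID={m.transcript_id};Parent=gene:{m.gene};"
                     f"gene_name={m.gene}\n")
            order = m.exons if m.strand == "+" else list(reversed(m.exons))
            cum = 0
            phased = {}
            for s, e in order:
                phased[(s, e)] = (3 - cum % 3) % 3
                cum += e - s + 1
            for i, (s, e) in enumerate(m.exons):
                fh.write(f"{m.chrom}\trecessmap\tCDS\t{s}\t{e}\t.\t{m.strand}\t"
                         f"{phased[(s, e)]}\t"
                         f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}\n")
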