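"""Haplotype-based indirect carrier test.

The disease-associated haplotype is read directly off the mapped homozygous
interval: every affected animal in the training cohort is homozygous for the
shared allele at every member marker, so those alleles define the risk
haplotype without statistical phasing. A new animal is then classified from
its unphased chip genotypes at the signature markers:

* homozygous for the risk allele at every informative marker
  -> ``affected_genotype`` (compatible with two copies of the risk haplotype);
* heterozygous or homozygous-risk everywhere, with at least one heterozygous
  marker -> ``carrier`` (compatible with exactly one intact risk haplotype);
* homozygous for the non-risk allele at any marker -> ``non_carrier``
  (one non-risk homozygote excludes carrying an intact risk haplotype);
* fewer informative (non-missing) markers than ``min_informative``
  -> ``ambiguous``.

Being linkage-based, the test is *indirect*: an animal carrying the marker
haplotype without the causal allele (a recombinant, or a coincidental
identical-by-state match) is misclassified — the structural limitation that
eventually motivates a direct mutation assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .hommap import ALLELE1, HomozygosityInterval
from .io import HET, HOM1, HOM2, MISSING, GenotypeMatrix

AFFECTED_GENOTYPE = "affected_genotype"
CARRIER = "carrier"
NON_CARRIER = "non_carrier"
AMBIGUOUS = "ambiguous"

#: default fraction of signature markers that must be informative for a call
DEFAULT_MIN_INFORMATIVE_FRACTION = 0.8


@dataclass
class HaplotypeSignature:
    """Ordered risk-allele assignment over the mapped interval's markers."""

    chrom: str
    marker_ids: list[str]
    risk_alleles: list[int]     # ALLELE1 or ALLELE2 per marker
    min_informative: int

    def __post_init__(self):
        if len(self.marker_ids) != len(self.risk_alleles):
            raise ValueError("one risk allele is required per signature marker")
        if not 1 <= self.min_informative <= len(self.marker_ids):
            raise ConfigurationError(
                f"min_informative={self.min_informative} outside "
                f"[1, {len(self.marker_ids)}]")

    def __len__(self) -> int:
        return len(self.marker_ids)


def derive_signature(genotypes: GenotypeMatrix, interval: HomozygosityInterval,
                     affected_ids, min_informative: int | None = None
                     ) -> HaplotypeSignature:
    """Build the risk-haplotype signature from a detected interval.

    The risk allele at each marker is the interval's shared allele; as a
    guard the affected training animals are re-checked and any marker where a
    typed affected is not homozygous for it is excluded (none exists for an
    interval produced by detection on the same cohort).
    """
    if not interval.marker_ids:
        raise ConfigurationError("empty interval")
    keep_ids, keep_risk = [], []
    aff = genotypes.subset(list(affected_ids))
    for mid, allele in zip(interval.marker_ids, interval.shared_alleles):
        col = aff[:, genotypes.marker_map.index_of(mid)]
        hom = HOM1 if allele == ALLELE1 else HOM2
        typed = col[col >= 0]
        if (typed == hom).all():
            keep_ids.append(mid)
            keep_risk.append(allele)
    if not keep_ids:
        raise ConfigurationError("no signature marker survives the affected check")
    if min_informative is None:
        min_informative = max(1, int(np.ceil(
            DEFAULT_MIN_INFORMATIVE_FRACTION * len(keep_ids))))
    if min_informative > len(keep_ids):
        raise ConfigurationError(
            f"min_informative={min_informative} exceeds the "
            f"{len(keep_ids)}-marker signature")
    return HaplotypeSignature(chrom=interval.chrom, marker_ids=keep_ids,
                              risk_alleles=keep_risk,
                              min_informative=min_informative)


def classify(genotype_row, signature: HaplotypeSignature) -> str:
    """Classify one animal from unphased genotypes at the signature markers.

    ``genotype_row`` maps marker id -> genotype code (HOM1/HET/HOM2/MISSING);
    a pandas Series or dict both work. Markers absent from the row count as
    missing.
    """
    informative = 0
    any_het = False
    any_hom_nonrisk = False
    all_hom_risk = True
    for mid, allele in zip(signature.marker_ids, signature.risk_alleles):
        g = genotype_row.get(mid, MISSING)
        if g is None or g == MISSING:
            continue
        informative += 1
        hom_risk = HOM1 if allele == ALLELE1 else HOM2
        hom_nonrisk = HOM2 if allele == ALLELE1 else HOM1
        if g == hom_nonrisk:
            any_hom_nonrisk = True
            all_hom_risk = False
        elif g == HET:
            any_het = True
            all_hom_risk = False
    if informative < signature.min_informative:
        return AMBIGUOUS
    if any_hom_nonrisk:
        return NON_CARRIER
    if all_hom_risk:
        return AFFECTED_GENOTYPE
    assert any_het
    return CARRIER


def classify_cohort(genotypes: GenotypeMatrix, signature: HaplotypeSignature,
                    ids=None) -> pd.Series:
    """Classify many animals at once; returns a Series indexed by id."""
    ids = list(ids) if ids is not None else list(genotypes.individuals)
    calls = {i: classify(genotypes.row_series(i), signature) for i in ids}
    return pd.Series(calls, name="call")


def write_signature(signature: HaplotypeSignature, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#chrom\t{signature.chrom}\n")
        fh.write(f"#min_informative\t{signature.min_informative}\n")
        fh.write("marker_id\trisk_allele\n")
        for mid, a in zip(signature.marker_ids, signature.risk_alleles):
            fh.write(f"{mid}\t{a}\n")


def read_signature(path) -> HaplotypeSignature:
    chrom, min_inf = None, None
    markers, risk = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#chrom"):
                chrom = line.split("\t")[1].strip()
            elif line.startswith("#min_informative"):
                min_inf = int(line.split("\t")[1])
            elif line.startswith("marker_id"):
                continue
            elif line.strip():
                mid, a = line.split("\t")
                markers.append(mid)
                risk.append(int(a))
    if chrom is None or min_inf is None:
        raise ConfigurationError(f"{path}: malformed signature file")
    return HaplotypeSignature(chrom=chrom, marker_ids=markers,
                              risk_alleles=risk, min_informative=min_inf)
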