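"""Homozygosity mapping for a fully penetrant recessive trait.

For each chip marker the affected cohort is summarised by its genotype counts
(n1 homozygous allele1, n2 heterozygous, n3 homozygous allele2) and the control
cohort by its allele-1 frequency f1. A likelihood-ratio statistic compares the
affected genotype distribution with Hardy-Weinberg expectation at f1:

    lrt = 2 * [ sup_p l(p) - l(f1) ],
    l(p) = n1*ln(p^2) + n2*ln(2p(1-p)) + n3*ln((1-p)^2)

with 0*ln(0) = 0 and the supremum attained at the affected-sample MLE
p_hat = (2*n1 + n2) / (2*(n1 + n2 + n3)). Extreme control frequencies are
reported clamped (exactly 0 -> 0.1, exactly 1 -> 0.9) before the statistic is
formed, so the null log-likelihood stays finite; intermediate frequencies are
never altered.

The mapped locus appears as a run of consecutive markers at which every typed
affected animal is homozygous for the same allele — the shared haplotype
inherited identical-by-descent from the founder carrier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .errors import ConfigurationError, UndefinedFrequencyError
from .io import HET, HOM1, HOM2, GenotypeMatrix, MarkerMap, PhenotypeTable

logger = logging.getLogger(__name__)

ALLELE1 = 1
ALLELE2 = 2

#: minimum fraction of affected animals that must be typed for a marker to
#: enter the scan and interval detection
MIN_TYPED_FRACTION = 0.9

STAT_COLUMNS = ("marker_id", "chrom", "pos", "n1", "n2", "n3", "lrt", "f1")


def marker_counts(genotypes: GenotypeMatrix, affected_ids, marker_id: str
                  ) -> tuple[int, int, int]:
    """Affected genotype counts (n1, n2, n3) at one marker; missing excluded."""
    j = genotypes.marker_map.index_of(marker_id)
    col = genotypes.subset(list(affected_ids))[:, j]
    return int((col == HOM1).sum()), int((col == HET).sum()), int((col == HOM2).sum())


def control_freq(genotypes: GenotypeMatrix, control_ids, marker_id: str) -> float:
    """Control allele-1 frequency with the extreme-value reporting rule.

    f1 = (2*hom1 + het) / (2 * typed controls); a raw value of exactly 0 is
    reported as 0.1 and exactly 1 as 0.9 (so downstream likelihoods are
    finite); values strictly between 0 and 1 are unchanged.
    """
    j = genotypes.marker_map.index_of(marker_id)
    col = genotypes.subset(list(control_ids))[:, j]
    typed = int((col >= 0).sum())
    if typed == 0:
        raise UndefinedFrequencyError(f"no typed control at marker {marker_id!r}")
    raw = (2 * int((col == HOM1).sum()) + int((col == HET).sum())) / (2 * typed)
    return _clamp_extremes(raw)


def _clamp_extremes(raw: float) -> float:
    if raw == 0.0:
        return 0.1
    if raw == 1.0:
        return 0.9
    return raw


def marker_lrt(counts: tuple[int, int, int], f1: float) -> float:
    """Likelihood-ratio statistic of the affected genotype counts against
    Hardy-Weinberg at the (clamped) control allele-1 frequency f1."""
    n1, n2, n3 = counts
    n = n1 + n2 + n3
    if n < 1:
        raise ValueError("marker_lrt requires at least one typed affected animal")
    if not 0.0 < f1 < 1.0:
        raise ValueError(f"f1 must lie strictly in (0, 1); got {f1} "
                         "(extreme frequencies must be clamped upstream)")
    p_hat = (2 * n1 + n2) / (2 * n)
    lrt = 2.0 * (_trinomial_ll(n1, n2, n3, p_hat) - _trinomial_ll(n1, n2, n3, f1))
    return max(float(lrt), 0.0)


def _trinomial_ll(n1, n2, n3, p):
    return (xlogy(n1, p * p) + xlogy(n2, 2.0 * p * (1.0 - p))
            + xlogy(n3, (1.0 - p) * (1.0 - p)))


def scan(genotypes: GenotypeMatrix, marker_map: MarkerMap,
         phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Per-marker affected counts, control frequency and LRT for every marker
    with >= 90% of affected typed; one row per marker, ordered by (chrom, pos).

    Returns a DataFrame with columns marker_id, chrom, pos, n1, n2, n3, lrt, f1.
    """
    affected = phenotypes.affected_ids
    controls = phenotypes.control_ids
    if not affected:
        raise ConfigurationError("no affected animal in the phenotype table")
    if not controls:
        raise ConfigurationError("no control animal in the phenotype table")

    aff = genotypes.subset(affected)
    ctl = genotypes.subset(controls)
    n1 = (aff == HOM1).sum(axis=0)
    n2 = (aff == HET).sum(axis=0)
    n3 = (aff == HOM2).sum(axis=0)
    typed_aff = n1 + n2 + n3

    c_hom1 = (ctl == HOM1).sum(axis=0)
    c_het = (ctl == HET).sum(axis=0)
    typed_ctl = (ctl >= 0).sum(axis=0)

    keep = typed_aff >= MIN_TYPED_FRACTION * len(affected)
    n_lowcall = int((~keep).sum())
    if n_lowcall:
        logger.warning("dropping %d markers with < %.0f%% of affected typed",
                       n_lowcall, 100 * MIN_TYPED_FRACTION)
    no_ctl = keep & (typed_ctl == 0)
    if no_ctl.any():
        logger.warning("dropping %d markers with zero typed controls", int(no_ctl.sum()))
        keep &= typed_ctl > 0

    idx = np.flatnonzero(keep)
    raw = (2.0 * c_hom1[idx] + c_het[idx]) / (2.0 * typed_ctl[idx])
    f1 = np.where(raw == 0.0, 0.1, np.where(raw == 1.0, 0.9, raw))
    n = typed_aff[idx].astype(float)
    p_hat = (2.0 * n1[idx] + n2[idx]) / (2.0 * n)
    lrt = 2.0 * (_trinomial_ll(n1[idx], n2[idx], n3[idx], p_hat)
                 - _trinomial_ll(n1[idx], n2[idx], n3[idx], f1))
    lrt = np.maximum(lrt, 0.0)

    df = pd.DataFrame({
        "marker_id": marker_map.marker_ids[idx],
        "chrom": marker_map.chroms[idx],
        "pos": marker_map.positions[idx],
        "n1": n1[idx], "n2": n2[idx], "n3": n3[idx],
        "lrt": lrt, "f1": f1,
    })
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


@dataclass
class HomozygosityInterval:
    """A maximal run of consecutive markers at which all typed affected
    animals are homozygous for the same allele."""

    chrom: str
    start_bp: int          # position of the first qualifying marker
    end_bp: int            # position of the last qualifying marker
    marker_ids: list[str]
    shared_alleles: list[int]  # ALLELE1 or ALLELE2, one per member marker
    score: float = 0.0         # sum of member lrt values

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def detect_intervals(stats: pd.DataFrame, genotypes: GenotypeMatrix,
                     phenotypes: PhenotypeTable, min_markers: int = 5
                     ) -> list[HomozygosityInterval]:
    """All maximal runs of >= min_markers consecutive scanned markers at which
    every typed affected animal is homozygous AND all share the same allele.

    Runs are ranked by score (sum of member lrt), ties broken by n_markers and
    then by leftmost position. Consecutive means adjacent rows of the scan
    table (markers dropped from the scan do not interrupt a run).
    """
    if stats.empty:
        raise ConfigurationError("empty marker-statistics table")
    n1 = stats["n1"].to_numpy()
    n2 = stats["n2"].to_numpy()
    n3 = stats["n3"].to_numpy()
    typed = n1 + n2 + n3
    qualifies = (n2 == 0) & (typed > 0) & ((n1 == 0) | (n3 == 0))
    shared = np.where(n1 > 0, ALLELE1, ALLELE2)

    intervals: list[HomozygosityInterval] = []
    chroms = stats["chrom"].to_numpy()
    i, m = 0, len(stats)
    while i < m:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and qualifies[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        if j - i + 1 >= min_markers:
            sub = stats.iloc[i:j + 1]
            iv = HomozygosityInterval(
                chrom=str(chroms[i]),
                start_bp=int(sub["pos"].iloc[0]),
                end_bp=int(sub["pos"].iloc[-1]),
                marker_ids=list(sub["marker_id"]),
                shared_alleles=[int(a) for a in shared[i:j + 1]],
                score=float(sub["lrt"].sum()),
            )
            _check_interval_invariant(iv, genotypes, phenotypes)
            intervals.append(iv)
        i = j + 1
    intervals.sort(key=lambda iv: (-iv.score, -iv.n_markers, iv.chrom, iv.start_bp))
    return intervals


def _check_interval_invariant(iv: HomozygosityInterval, genotypes: GenotypeMatrix,
                              phenotypes: PhenotypeTable) -> None:
    """Guard: every typed affected is homozygous for the shared allele at
    every member marker (re-checked directly on the genotype matrix)."""
    aff = genotypes.subset(phenotypes.affected_ids)
    for mid, allele in zip(iv.marker_ids, iv.shared_alleles):
        col = aff[:, genotypes.marker_map.index_of(mid)]
        hom = HOM1 if allele == ALLELE1 else HOM2
        typed = col[col >= 0]
        if not (typed == hom).all():
            raise AssertionError(
                f"interval invariant violated at marker {mid}: typed affected "
                f"not all homozygous for the shared allele")


def write_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, columns=list(STAT_COLUMNS),
                 float_format="%.6g")


def read_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_intervals(intervals: list[HomozygosityInterval], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart_bp\tend_bp\tn_markers\tscore\tmarker_ids\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start_bp}\t{iv.end_bp}\t{iv.n_markers}"
                     f"\t{iv.score:.6g}\t{','.join(iv.marker_ids)}\n")
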