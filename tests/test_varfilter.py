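"""Variant cascade, consequence annotation and conservation scoring."""

import numpy as np
import pytest

import recessmap as rm
from recessmap.errors import ConfigurationError, UnsupportedVariantError
from recessmap.varfilter import CASCADE_STEPS, CascadeReport

# independent standard-genetic-code oracle (table literal, not Biopython)
_GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def plus_model(cds: str, start: int = 1001, gene: str = "G") -> rm.GeneModel:
    return rm.GeneModel(f"{gene}.t1", gene, "1", "+",
                        [(start, start + len(cds) - 1)], cds)


def snv(pos, ref, alt, chrom="1", **kw):
    return rm.VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


class TestAnnotateConsequence:
    def test_codon_arithmetic_at_cds_376(self):
        cds = "ATG" + "GCT" * 124 + "TAA"     # 126 codons; swap codon 126 later
        cds = cds[:375] + "CGC" + cds[378:]
        model = plus_model(cds)
        v = snv(1001 + 375, "C", "T")
        c = rm.annotate_consequence(v, [model])
        assert (c.cds_pos, c.codon_index, c.codon_offset) == (376, 126, 0)
        assert (c.ref_aa, c.alt_aa) == ("R", "C")
        assert c.consequence_class == "missense"
        assert c.hgvs_c == "c.376C>T"
        assert c.hgvs_p == "p.R126C"

    def test_lysine_to_arginine_at_offset_one(self):
        cds = "ATGAAATAA"                      # M K *
        model = plus_model(cds)
        c = rm.annotate_consequence(snv(1001 + 4, "A", "G"), [model])
        assert (c.codon_index, c.codon_offset) == (2, 1)
        assert (c.ref_aa, c.alt_aa) == ("K", "R")
        assert c.consequence_class == "missense"

    def test_intronic_and_intergenic(self):
        m = rm.GeneModel("T", "G", "1", "+", [(100, 105), (200, 205)],
                         "ATGGCTGCTTAA", gene_start=100, gene_end=205)
        assert rm.annotate_consequence(snv(150, "A", "G"), [m]).consequence_class \
            == "intronic"
        assert rm.annotate_consequence(snv(500, "A", "G"), [m]).consequence_class \
            == "intergenic"

    def test_indel_unsupported(self):
        with pytest.raises(UnsupportedVariantError):
            rm.annotate_consequence(snv(1001, "AT", "A"), [plus_model("ATGTAA")])

    def test_ref_mismatch_raises(self):
        with pytest.raises(ValueError, match="does not match"):
            rm.annotate_consequence(snv(1001, "G", "T"), [plus_model("ATGTAA")])

    def test_exhaustive_codon_partition(self):
        """All 64 codons x 9 single-base changes classify per the genetic code."""
        bases = "ACGT"
        for codon, ref_aa in _GENETIC_CODE.items():
            cds = "ATG" + codon + "GGGTAA"
            model = plus_model(cds)
            for off in range(3):
                for b in bases:
                    if b == codon[off]:
                        continue
                    v = snv(1001 + 3 + off, codon[off], b)
                    c = rm.annotate_consequence(v, [model])
                    alt_aa = _GENETIC_CODE[codon[:off] + b + codon[off + 1:]]
                    if ref_aa == alt_aa:
                        expected = "synonymous"
                    elif alt_aa == "*":
                        expected = "nonsense"
                    elif ref_aa == "*":
                        expected = "stop_lost"
                    else:
                        expected = "missense"
                    assert c.consequence_class == expected, (codon, off, b)
                    assert (c.ref_aa, c.alt_aa) == (ref_aa, alt_aa)

    def test_minus_strand_involution(self):
        """The mirrored minus-strand representation of a plus-strand fixture
        yields the identical consequence."""
        L = 2000
        cds = "ATG" + "CGC" + "AAA" + "TAA"
        start = 501
        plus = plus_model(cds, start=start)
        # mirror the contig: position p -> L - p + 1, strand flips, alleles
        # complement; the transcript-level CDS is unchanged
        end = start + len(cds) - 1
        minus = rm.GeneModel("T.m", "G", "1", "-",
                             [(L - end + 1, L - start + 1)], cds)
        for cds_pos, ref, alt in [(4, "C", "T"), (8, "A", "G"), (12, "A", "T")]:
            p = start + cds_pos - 1
            c_plus = rm.annotate_consequence(snv(p, ref, alt), [plus])
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            c_minus = rm.annotate_consequence(
                snv(L - p + 1, comp[ref], comp[alt]), [minus])
            assert c_plus == c_minus


class TestInframeArithmetic:
    def test_two_codons_become_six(self):
        assert rm.inframe_replacement_codons(2, 15, 3) == 6

    def test_pure_inframe_deletion(self):
        assert rm.inframe_replacement_codons(2, 0, 3) == 1

    def test_frameshift_rejected(self):
        with pytest.raises(ValueError):
            rm.inframe_replacement_codons(2, 4, 0)


class TestFilters:
    def _interval(self, start=1000, end=2000, chrom="1"):
        return rm.HomozygosityInterval(chrom=chrom, start_bp=start, end_bp=end,
                                       marker_ids=[], shared_alleles=[])

    def test_region_boundaries_inclusive(self):
        iv = self._interval()
        inside = [snv(1000, "A", "G"), snv(2000, "A", "G"), snv(1500, "A", "G")]
        outside = [snv(999, "A", "G"), snv(2001, "A", "G"),
                   snv(1500, "A", "G", chrom="2")]
        assert rm.filter_region(inside + outside, iv) == inside

    def test_genotype_pattern(self):
        roles = rm.PhenotypeTable({"A1": "affected", "A2": "affected",
                                   "C": "carrier", "W": "wild_type"})
        good = snv(10, "C", "T", genotypes={"A1": 2, "A2": 2, "C": 1, "W": 0})
        bad_aff = snv(11, "C", "T", genotypes={"A1": 1, "A2": 2, "C": 1, "W": 0})
        bad_wt = snv(12, "C", "T", genotypes={"A1": 2, "A2": 2, "C": 1, "W": 1})
        assert rm.filter_genotype_pattern([good, bad_aff, bad_wt], roles) == [good]

    def test_missing_policy(self):
        roles = rm.PhenotypeTable({"A1": "affected", "C": "carrier"})
        v = snv(10, "C", "T", genotypes={"A1": 2, "C": rm.MISSING})
        assert rm.filter_genotype_pattern([v], roles, allow_missing=False) == []
        assert rm.filter_genotype_pattern([v], roles, allow_missing=True) == [v]

    def test_requires_affected(self):
        roles = rm.PhenotypeTable({"C": "carrier"})
        with pytest.raises(ConfigurationError):
            rm.filter_genotype_pattern([], roles)

    def test_known_substeps_in_order(self):
        vs = [snv(10, "A", "G", known_id="rs123"),
              snv(20, "A", "G"),                       # novel, on chip
              snv(30, "A", "G")]
        surv, (n_ids, n_chip) = rm.filter_known(vs, {"rs123"}, {("1", 20)})
        assert surv == [vs[2]]
        assert (n_ids, n_chip) == (2, 1)

    def test_any_assigned_id_mode(self):
        vs = [snv(10, "A", "G", known_id="rs999"), snv(20, "A", "G")]
        surv, _ = rm.filter_known(vs, None, None)
        assert surv == [vs[1]]

    def test_substep_order_invariance_of_final_set(self):
        """Swapping the ID and chip sub-steps changes intermediate counts but
        never the surviving set (independent set subtractions)."""
        rng = np.random.default_rng(5)
        vs = []
        for i in range(60):
            vs.append(snv(10 + i, "A", "G",
                          known_id=f"rs{i}" if rng.random() < 0.5 else None))
        chip = {("1", 10 + i) for i in range(60) if rng.random() < 0.4}
        ids = {f"rs{i}" for i in range(0, 60, 3)}
        surv_a, counts_a = rm.filter_known(vs, ids, chip)
        # swapped order
        after_chip = [v for v in vs if (v.chrom, v.pos) not in chip]
        surv_b = [v for v in after_chip if v.known_id not in ids]
        counts_b = (len(after_chip), len(surv_b))
        assert {id(v) for v in surv_a} == {id(v) for v in surv_b}
        assert counts_a != counts_b  # intermediate decomposition differs


class TestCascade:
    def test_report_renders_study_scale_counts(self):
        """Formatting fixture: a report carrying genome-scale counts renders
        as the canonical two-column table."""
        report = CascadeReport(steps=list(zip(CASCADE_STEPS,
                                              (9025, 1594, 973, 678, 2))))
        lines = report.format_table().splitlines()
        assert lines[0] == "step\tn_remaining"
        assert lines[1] == "interval\t9025"
        assert lines[-1] == "nonsynonymous\t2"

    def test_nondecreasing_counts_rejected(self):
        with pytest.raises(ValueError):
            CascadeReport(steps=list(zip(CASCADE_STEPS, (10, 12, 5, 5, 1))))

    def test_empty_variant_list(self, small_top_interval):
        roles = rm.PhenotypeTable({"A1": "affected"})
        report = rm.run_cascade([], small_top_interval, roles)
        assert [n for _, n in report.steps] == [0, 0, 0, 0, 0]
        assert report.candidates == []

    def test_simulated_causal_survives_with_counts_matching_brute_force(
            self, small_study, small_top_interval):
        study = small_study
        report = rm.run_cascade(study.variants, small_top_interval,
                                study.quartet_roles, known_ids=None,
                                chip_positions=study.chip_positions,
                                models=study.gene_models)
        counts = [n for _, n in report.steps]
        assert counts == sorted(counts, reverse=True)
        # brute-force recount of each step
        iv = small_top_interval
        s1 = [v for v in study.variants if v.chrom == iv.chrom
              and iv.start_bp <= v.pos <= iv.end_bp]
        q = study.phenotypes.quartet
        s2 = [v for v in s1 if v.genotypes[q[0]] == 2 and v.genotypes[q[1]] == 2
              and v.genotypes[q[2]] == 1 and v.genotypes[q[3]] == 0]
        s3 = [v for v in s2 if v.known_id is None]
        s4 = [v for v in s3 if (v.chrom, v.pos) not in study.chip_positions]
        assert counts[:4] == [len(s1), len(s2), len(s3), len(s4)]
        causal_pos = study.config.causal_pos
        assert any(v.pos == causal_pos for v, _ in report.candidates)

    def test_candidate_ranking_prefers_novel_then_conserved(self):
        iv = rm.HomozygosityInterval(chrom="1", start_bp=1, end_bp=10_000,
                                     marker_ids=[], shared_alleles=[])
        roles = rm.PhenotypeTable({"A1": "affected"})
        cds = "ATG" + "CGC" * 10 + "TAA"
        model = plus_model(cds, start=100)
        mk = lambda off, rid: snv(100 + 3 + off * 3, "C", "T", known_id=rid,
                                  genotypes={"A1": 2})
        vs = [mk(0, "rs1"), mk(1, None), mk(2, None)]
        cons = {("1", vs[1].pos): 0.2, ("1", vs[2].pos): 0.9}
        report = rm.run_cascade(vs, iv, roles, known_ids=set(),
                                chip_positions=set(), models=[model],
                                conservation=cons)
        order = [v.pos for v, _ in report.candidates]
        assert order == [vs[2].pos, vs[1].pos, vs[0].pos]


class TestConservation:
    def test_fully_conserved_column(self):
        assert rm.conservation_score(["MKR"] * 6, 1) == 1.0

    def test_mitochondrial_carrier_family_composition(self):
        """A 53-sequence alignment in which 19 share the majority residue
        scores 19/53 at that column."""
        col = ["T"] * 19 + ["A"] * 10 + ["S"] * 10 + ["V"] * 8 + ["I"] * 6
        seqs = [f"A{r}G" for r in col]
        assert rm.conservation_score(seqs, 1) == pytest.approx(19 / 53)

    def test_four_way_tie_resolves_to_reference(self):
        seqs = ["A", "C", "D", "E"]
        assert rm.conservation_score(seqs, 0) == 0.25

    def test_gaps_excluded(self):
        seqs = ["AK", "-K", "-R"]
        assert rm.conservation_score(seqs, 0) == 1.0
        assert rm.conservation_score(seqs, 1) == pytest.approx(2 / 3)

    def test_all_gap_column(self):
        with pytest.raises(ValueError):
            rm.conservation_score(["-", "-"], 0)
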