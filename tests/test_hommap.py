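"""Homozygosity-mapping statistics and interval detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recessmap as rm
from recessmap.errors import ConfigurationError, UndefinedFrequencyError
from recessmap.hommap import ALLELE1

from conftest import grid_lrt, toy_marker_map, toy_matrix

H1, HE, H2, MI = rm.HOM1, rm.HET, rm.HOM2, rm.MISSING


class TestMarkerCounts:
    def test_direct_counts_exclude_missing(self):
        gm = toy_matrix({"a1": [H1], "a2": [HE], "a3": [H2], "a4": [MI]})
        assert rm.marker_counts(gm, {"a1", "a2", "a3", "a4"}, "m0") == (1, 1, 1)

    def test_all_homozygous_signature(self):
        gm = toy_matrix({f"a{i}": [H1] for i in range(12)})
        assert rm.marker_counts(gm, {f"a{i}" for i in range(12)}, "m0") == (12, 0, 0)

    def test_empty_affected_set(self):
        gm = toy_matrix({"a1": [H1]})
        assert rm.marker_counts(gm, set(), "m0") == (0, 0, 0)

    def test_unknown_marker_raises(self):
        gm = toy_matrix({"a1": [H1]})
        with pytest.raises(KeyError):
            rm.marker_counts(gm, {"a1"}, "nope")


class TestControlFreq:
    def test_absent_allele_reported_as_point_one(self):
        gm = toy_matrix({"c1": [H2], "c2": [H2]})
        assert rm.control_freq(gm, {"c1", "c2"}, "m0") == 0.1

    def test_fixed_allele_reported_as_point_nine(self):
        gm = toy_matrix({"c1": [H1], "c2": [H1]})
        assert rm.control_freq(gm, {"c1", "c2"}, "m0") == 0.9

    def test_intermediate_frequency_unchanged(self):
        gm = toy_matrix({"c1": [H1], "c2": [HE]})
        assert rm.control_freq(gm, {"c1", "c2"}, "m0") == pytest.approx(0.75)

    def test_near_extreme_values_not_clamped(self):
        # 50 controls, one het: raw 1/100 stays 0.01 (only exact 0/1 clamp)
        rows = {f"c{i}": [H2] for i in range(49)}
        rows["c49"] = [HE]
        gm = toy_matrix(rows)
        assert rm.control_freq(gm, set(rows), "m0") == pytest.approx(0.01)

    def test_zero_typed_controls(self):
        gm = toy_matrix({"c1": [MI]})
        with pytest.raises(UndefinedFrequencyError):
            rm.control_freq(gm, {"c1"}, "m0")


class TestMarkerLrt:
    def test_all_hom1_against_half(self):
        # closed form: 2 * 12 * ln 4
        assert rm.marker_lrt((12, 0, 0), 0.5) == pytest.approx(24 * np.log(4), abs=1e-9)

    def test_null_counts_give_zero(self):
        assert rm.marker_lrt((3, 6, 3), 0.5) == 0.0

    def test_all_hom2_against_clamped_low_frequency(self):
        # all affected homozygous allele2, controls fixed for allele2 (f1
        # clamped to 0.1): 2 * 20 * ln(1/0.9)
        expected = 40 * np.log(1 / 0.9)
        assert rm.marker_lrt((0, 0, 10), 0.1) == pytest.approx(expected, abs=1e-9)
        assert grid_lrt(0, 0, 10, 0.1) == pytest.approx(expected, abs=1e-6)

    def test_invalid_f1_raises(self):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                rm.marker_lrt((1, 0, 0), bad)

    def test_zero_affected_raises(self):
        with pytest.raises(ValueError):
            rm.marker_lrt((0, 0, 0), 0.5)

    @given(n1=st.integers(0, 30), n2=st.integers(0, 30), n3=st.integers(0, 30),
           f1=st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_nonnegative(self, n1, n2, n3, f1):
        if n1 + n2 + n3 == 0:
            return
        assert rm.marker_lrt((n1, n2, n3), f1) >= 0.0

    @given(n1=st.integers(0, 20), n2=st.integers(0, 20), n3=st.integers(0, 20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_zero_exactly_when_mle_equals_null(self, n1, n2, n3):
        n = n1 + n2 + n3
        if n == 0:
            return
        p_hat = (2 * n1 + n2) / (2 * n)
        if 0.0 < p_hat < 1.0:
            assert rm.marker_lrt((n1, n2, n3), p_hat) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decreasing_in_f1_when_all_hom1(self):
        f1s = np.linspace(0.05, 0.95, 19)
        vals = [rm.marker_lrt((8, 0, 0), f) for f in f1s]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestScan:
    def test_null_cohort_has_zero_lrt(self):
        # affected and control genotype columns identical -> p_hat equals the
        # raw control frequency at every marker
        mm = toy_marker_map(3)
        rows = {}
        for i in range(6):
            col = [H1 if i < 3 else H2, HE, H1 if i % 2 else HE]
            rows[f"a{i}"] = col
            rows[f"c{i}"] = col
        gm = toy_matrix(rows, mm)
        ph = rm.PhenotypeTable({f"a{i}": "affected" for i in range(6)}
                               | {f"c{i}": "control" for i in range(6)})
        stats = rm.scan(gm, mm, ph)
        assert np.allclose(stats["lrt"], 0.0, atol=1e-10)

    def test_low_call_rate_marker_dropped(self):
        mm = toy_marker_map(2)
        # marker 0: 11/12 affected typed (kept); marker 1: 10/12 (dropped)
        rows = {f"a{i}": [H1 if i < 11 else MI, H1 if i < 10 else MI]
                for i in range(12)}
        rows["c0"] = [HE, HE]
        gm = toy_matrix(rows, mm)
        ph = rm.PhenotypeTable({f"a{i}": "affected" for i in range(12)}
                               | {"c0": "control"})
        stats = rm.scan(gm, mm, ph)
        assert list(stats["marker_id"]) == ["m0"]

    def test_requires_affected(self):
        mm = toy_marker_map(1)
        gm = toy_matrix({"c0": [H1]}, mm)
        with pytest.raises(ConfigurationError):
            rm.scan(gm, mm, rm.PhenotypeTable({"c0": "control"}))

    def test_simulated_cohort_peak_inside_truth_interval(self, small_study,
                                                         small_scan):
        truth = small_study.truth
        lo, hi = truth["shared_interval"]
        inside = small_scan[(small_scan["pos"] >= lo) & (small_scan["pos"] <= hi)]
        assert ((inside["n2"] == 0) & ((inside["n1"] == 0) | (inside["n3"] == 0))).all()
        peak = small_scan.loc[small_scan["lrt"].idxmax()]
        assert lo <= peak["pos"] <= hi


def brute_force_intervals(stats, min_markers):
    """Enumeration oracle: all maximal qualifying windows."""
    n1 = stats["n1"].to_numpy()
    n2 = stats["n2"].to_numpy()
    n3 = stats["n3"].to_numpy()
    chrom = stats["chrom"].to_numpy()
    q = [(n2[i] == 0) and (n1[i] + n3[i] > 0) and (n1[i] == 0 or n3[i] == 0)
         for i in range(len(stats))]
    out = []
    for i in range(len(stats)):
        for j in range(i, len(stats)):
            if not all(q[i:j + 1]) or len(set(chrom[i:j + 1])) != 1:
                continue
            maximal = ((i == 0 or not q[i - 1] or chrom[i - 1] != chrom[i])
                       and (j == len(stats) - 1 or not q[j + 1]
                            or chrom[j + 1] != chrom[j]))
            if maximal and j - i + 1 >= min_markers:
                out.append((int(stats["pos"].iloc[i]), int(stats["pos"].iloc[j])))
    return sorted(out)


class TestDetectIntervals:
    def _stats_from(self, gm, mm, ph):
        return rm.scan(gm, mm, ph)

    def test_all_het_yields_no_interval(self):
        mm = toy_marker_map(6)
        rows = {f"a{i}": [HE] * 6 for i in range(4)}
        rows["c0"] = [H1] * 6
        gm = toy_matrix(rows, mm)
        ph = rm.PhenotypeTable({f"a{i}": "affected" for i in range(4)}
                               | {"c0": "control"})
        stats = self._stats_from(gm, mm, ph)
        assert rm.detect_intervals(stats, gm, ph, min_markers=1) == []

    def test_single_embedded_run(self):
        # markers 3..7 (0-based) all-affected-hom1; elsewhere heterozygous
        mm = toy_marker_map(10)
        pattern = [HE] * 3 + [H1] * 5 + [HE] * 2
        rows = {f"a{i}": list(pattern) for i in range(4)}
        rows["c0"] = [HE] * 10
        gm = toy_matrix(rows, mm)
        ph = rm.PhenotypeTable({f"a{i}": "affected" for i in range(4)}
                               | {"c0": "control"})
        stats = self._stats_from(gm, mm, ph)
        found = rm.detect_intervals(stats, gm, ph, min_markers=3)
        assert len(found) == 1
        iv = found[0]
        assert (iv.start_bp, iv.end_bp) == (4000, 8000)
        assert iv.marker_ids == ["m3", "m4", "m5", "m6", "m7"]
        assert iv.shared_alleles == [ALLELE1] * 5
        assert brute_force_intervals(stats, 3) == [(4000, 8000)]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n_mark, n_aff = 60, 6
        mm = toy_marker_map(n_mark)
        # random genotypes with planted homozygous stretches
        data = rng.integers(0, 3, size=(n_aff + 4, n_mark)).astype(np.int8)
        for _ in range(3):
            s = int(rng.integers(0, n_mark - 8))
            allele = rng.choice([H1, H2])
            data[:n_aff, s:s + int(rng.integers(3, 9))] = allele
        ids = [f"a{i}" for i in range(n_aff)] + [f"c{i}" for i in range(4)]
        gm = rm.GenotypeMatrix(ids, mm, data)
        ph = rm.PhenotypeTable({f"a{i}": "affected" for i in range(n_aff)}
                               | {f"c{i}": "control" for i in range(4)})
        stats = self._stats_from(gm, mm, ph)
        found = rm.detect_intervals(stats, gm, ph, min_markers=3)
        assert sorted((iv.start_bp, iv.end_bp) for iv in found) \
            == brute_force_intervals(stats, 3)

    def test_ranked_by_score(self, small_study, small_scan):
        found = rm.detect_intervals(small_scan, small_study.genotypes,
                                    small_study.phenotypes)
        scores = [iv.score for iv in found]
        assert scores == sorted(scores, reverse=True)

    def test_top_interval_contains_causal(self, small_study, small_top_interval):
        cfg = small_study.config
        assert small_top_interval.contains(cfg.chrom, cfg.causal_pos)

    def test_empty_stats_rejected(self, small_study):
        with pytest.raises(ConfigurationError):
            rm.detect_intervals(pd.DataFrame(), small_study.genotypes,
                                small_study.phenotypes)
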