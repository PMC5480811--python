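import numpy as np
import pandas as pd
import pytest
from scipy import stats

from selpleio.selection_scan import (EhhCurve, call_candidate_signals,
                                     ehh_curve, ihs_scan, integrate_ihh,
                                     permute_ihs_p, standardize_ihs)

from conftest import make_panel, random_panel


def brute_force_ehh(hap, core, target, m):
    """EHH by explicit pair enumeration between core and marker m (inclusive)."""
    carriers = np.flatnonzero(hap[:, core] == target)
    lo, hi = (m, core) if m < core else (core, m)
    seg = hap[np.ix_(carriers, np.arange(lo, hi + 1))]
    n = len(carriers)
    same = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(seg[i], seg[j]):
                same += 1
    return same / (n * (n - 1) / 2)


class TestEhhCurve:
    def test_ehh_is_one_at_core(self):
        hap = np.array([[1, 0], [1, 1], [0, 0], [0, 1]], dtype=np.int8)
        c = ehh_curve(make_panel(hap), 0, "derived", "right")
        assert c.ehh[0] == 1.0 and c.dist_cM[0] == 0.0

    def test_group_split_2_1_1(self):
        """4 carriers splitting into sizes {2,1,1}: EHH = C(2,2)/C(4,2) = 1/6."""
        hap = np.array([
            [1, 0, 0], [1, 0, 0], [1, 1, 0], [1, 0, 1],
            [0, 0, 0], [0, 0, 0]], dtype=np.int8)
        # at marker 1, carriers split {0,1,3} vs {2}; at marker 2: {0,1},{2},{3}
        c = ehh_curve(make_panel(hap), 0, "derived", "right", cutoff=0.0)
        assert c.ehh[1] == pytest.approx(3 / 6)
        assert c.ehh[2] == pytest.approx(1 / 6)

    def test_identical_carriers_keep_ehh_one(self):
        hap = np.array([[1, 1, 0, 1]] * 4 + [[0, 0, 0, 0]] * 2, dtype=np.int8)
        c = ehh_curve(make_panel(hap), 0, "derived", "right", cutoff=0.0)
        assert np.all(c.ehh == 1.0)

    def test_fewer_than_two_carriers_raises(self):
        hap = np.array([[1, 0], [0, 0], [0, 1], [0, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="carry"):
            ehh_curve(make_panel(hap), 0, "derived", "right")

    def test_monotone_non_increasing(self, rng):
        for _ in range(20):
            panel = random_panel(rng, n_haps=16, n_snps=30)
            for direction in ("left", "right"):
                c = ehh_curve(panel, 15, "derived", direction, cutoff=0.0)
                assert np.all(np.diff(c.ehh) <= 1e-12)

    def test_matches_brute_force_pair_enumeration(self, rng):
        """Partition-refinement EHH equals explicit pair counting exactly."""
        for _ in range(25):
            panel = random_panel(rng, n_haps=14, n_snps=25)
            core = int(rng.integers(5, 20))
            allele = ["ancestral", "derived"][int(rng.integers(2))]
            target = 1 if allele == "derived" else 0
            if min((panel.hap_matrix[:, core] == target).sum(),
                   (panel.hap_matrix[:, core] != target).sum()) < 2:
                continue
            c = ehh_curve(panel, core, allele, "right", cutoff=0.0)
            for k, e in enumerate(c.ehh[1:], start=1):
                assert e == pytest.approx(
                    brute_force_ehh(panel.hap_matrix, core, target, core + k),
                    abs=1e-12)


def curve(points, reached_end=False, pos=None):
    d = np.array([p[0] for p in points])
    e = np.array([p[1] for p in points])
    if pos is None:
        pos = (d * 1e4).astype(np.int64) + 1000
    return EhhCurve("rs", "derived", "right", d, e, np.asarray(pos), reached_end)


class TestIntegrateIhh:
    def test_hand_trapezoid_with_truncation(self):
        """Points (0,1.0),(0.1,0.5),(0.2,0.02) at cutoff 0.05: area 0.075."""
        left = curve([(0.0, 1.0)])
        right = curve([(0.0, 1.0), (0.1, 0.5), (0.2, 0.02)])
        assert integrate_ihh(left, right, cutoff=0.05) == pytest.approx(0.075)

    def test_rectangle(self):
        left = curve([(0.0, 1.0)])
        right = curve([(0.0, 1.0), (0.1, 1.0), (0.2, 1.0), (0.25, 0.01)])
        assert integrate_ihh(left, right, cutoff=0.05) == pytest.approx(0.2)

    def test_chromosome_end_undefined(self):
        left = curve([(0.0, 1.0)])
        right = curve([(0.0, 1.0), (0.1, 0.4)], reached_end=True)
        assert np.isnan(integrate_ihh(left, right, cutoff=0.05))

    def test_gap_undefined(self):
        left = curve([(0.0, 1.0)])
        right = curve([(0.0, 1.0), (0.1, 0.5), (0.2, 0.01)],
                      pos=[0, 300_000, 310_000])
        assert np.isnan(integrate_ihh(left, right, cutoff=0.05,
                                      max_gap_bp=200_000))

    def test_mismatched_cores_raise(self):
        a = curve([(0.0, 1.0)])
        b = EhhCurve("other", "derived", "left", np.array([0.0]),
                     np.array([1.0]), np.array([0]), False)
        with pytest.raises(ValueError):
            integrate_ihh(a, b)


class TestIhsScan:
    def test_kernel_matches_curve_integration(self, rng):
        """The compiled scan equals the curve-based reference path."""
        for _ in range(10):
            panel = random_panel(rng, n_haps=20, n_snps=40, cM_per_Mb=2000.0)
            scores = ihs_scan(panel, maf_min=0.0)
            for j in range(panel.n_snps):
                row = scores.iloc[j]
                if row["reason"] in ("maf", "carriers"):
                    continue
                areas = {}
                for al in ("ancestral", "derived"):
                    l = ehh_curve(panel, j, al, "left")
                    r = ehh_curve(panel, j, al, "right")
                    areas[al] = integrate_ihh(l, r)
                if row["reason"] == "":
                    assert row["ihh_a"] == pytest.approx(areas["ancestral"],
                                                         abs=1e-12)
                    assert row["ihh_d"] == pytest.approx(areas["derived"],
                                                         abs=1e-12)
                elif row["reason"] == "zero_ihh":
                    assert areas["ancestral"] == 0.0 or areas["derived"] == 0.0
                else:
                    assert np.isnan(areas["ancestral"]) or np.isnan(areas["derived"])

    def test_ihs_zero_when_ihh_equal(self, rng):
        panel = random_panel(rng, n_haps=20, n_snps=40, cM_per_Mb=2000.0)
        scores = ihs_scan(panel)
        d = scores.dropna(subset=["ihs_raw"])
        assert len(d) > 0
        np.testing.assert_allclose(d["ihs_raw"],
                                   np.log(d["ihh_a"] / d["ihh_d"]), atol=1e-12)

    def test_low_maf_flagged(self):
        hap = np.zeros((40, 3), dtype=np.int8)
        hap[0, 0] = 1  # MAF 0.025
        hap[:20, 1] = 1
        hap[:10, 2] = 1
        scores = ihs_scan(make_panel(hap), maf_min=0.05)
        assert scores.loc[0, "reason"] == "maf"

    def test_sign_symmetry(self, rng):
        """Swapping ancestral/derived at the core negates ihs_raw there."""
        panel = random_panel(rng, n_haps=20, n_snps=41, cM_per_Mb=2000.0)
        scores = ihs_scan(panel)
        j = 20
        if scores.loc[j, "reason"] != "":
            pytest.skip("core undefined in this draw")
        flipped = panel.hap_matrix.copy()
        flipped[:, j] = 1 - flipped[:, j]
        panel2 = make_panel(flipped, positions=panel.positions_bp,
                            cM_per_Mb=2000.0)
        scores2 = ihs_scan(panel2)
        assert scores2.loc[j, "ihs_raw"] == pytest.approx(
            -scores.loc[j, "ihs_raw"], abs=1e-12)


class TestStandardize:
    def make_scores(self, raw, daf=None):
        n = len(raw)
        return pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(n)], "chrom": "1",
            "pos_bp": np.arange(n) * 1000 + 1,
            "daf": daf if daf is not None else np.full(n, 0.5),
            "ihh_a": 1.0, "ihh_d": 1.0,
            "ihs_raw": np.asarray(raw, dtype=float), "reason": [""] * n})

    def test_single_bin_hand_example(self):
        """Raw {1,2,3} standardize to {-1,0,1} (mean 2, sample SD 1)."""
        out = standardize_ihs(self.make_scores([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out["ihs_std"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_zero_spread_bin_flagged(self):
        out = standardize_ihs(self.make_scores([2.0, 2.0, 2.0]))
        assert out["ihs_std"].isna().all()
        assert (out["reason"] == "bin").all()

    def test_nominal_p_two_sided_tail(self):
        out = standardize_ihs(self.make_scores([1.0, 2.0, 3.0]))
        assert out.loc[2, "nominal_p"] == pytest.approx(
            2 * stats.norm.sf(1.0), abs=1e-12)
        # |z| = 2 corresponds to p = 0.0455
        assert 2 * stats.norm.sf(2.0) == pytest.approx(0.0455, abs=5e-5)

    def test_bins_standardized_independently(self, rng):
        raw = rng.normal(0, 2, 400)
        daf = np.concatenate([np.full(200, 0.2), np.full(200, 0.7)])
        out = standardize_ihs(self.make_scores(raw, daf))
        for b, grp in out.groupby("daf_bin"):
            assert abs(grp["ihs_std"].mean()) < 1e-10
            assert grp["ihs_std"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestPermuteIhs:
    def base_scores(self, rng, n=500):
        df = TestStandardize().make_scores(rng.normal(0, 1, n))
        return standardize_ihs(df)

    def test_extreme_target_hits_floor(self, rng):
        scores = self.base_scores(rng)
        scores.loc[0, "ihs_std"] = 99.0  # exceeds everything
        out = permute_ihs_p(scores, n_perm=10_000, seed=1)
        assert out.loc[0, "permuted_p"] == pytest.approx(1 / 10_001)

    def test_median_target_near_half(self, rng):
        scores = self.base_scores(rng, n=1001)
        med = np.abs(scores["ihs_std"]).median()
        j = (np.abs(scores["ihs_std"]) - med).abs().idxmin()
        out = permute_ihs_p(scores, n_perm=10_000, seed=2)
        assert out.loc[j, "permuted_p"] == pytest.approx(0.5, abs=0.02)

    def test_small_class_widened(self, rng):
        raw = rng.normal(0, 1, 60)
        daf = np.concatenate([np.full(55, 0.5), np.full(5, 0.9)])
        scores = standardize_ihs(
            TestStandardize().make_scores(raw, daf), bin_width=0.025)
        # 5-SNP class must widen (and, with empty neighbors, keep widening)
        out = permute_ihs_p(scores, n_perm=100, seed=3, min_class_size=10)
        assert out["permuted_p"].notna().sum() >= 55


class TestCandidateSignals:
    def scores_from(self, pos, std, perm):
        n = len(pos)
        return pd.DataFrame({
            "snp_id": [f"rs{p}" for p in pos], "chrom": "1",
            "pos_bp": np.asarray(pos), "daf": 0.5, "ihh_a": 1.0, "ihh_d": 1.0,
            "ihs_raw": std, "reason": [""] * n, "daf_bin": 0,
            "ihs_std": np.asarray(std, dtype=float),
            "nominal_p": 0.05, "permuted_p": np.asarray(perm, dtype=float)})

    def test_isolated_snp_fails_cluster_rule(self):
        scores = self.scores_from([1000, 200_000], [3.5, 0.1], [0.001, 0.9])
        out = call_candidate_signals(scores, {"G": ["rs1000", "rs200000"]})
        assert out.empty

    def test_three_adjacent_snps_one_signal(self):
        """{2.4, 3.1, 2.2} all significant: one signal, apex 3.1, class 3-4."""
        scores = self.scores_from([1000, 11_000, 21_000],
                                  [2.4, 3.1, 2.2], [0.01, 0.01, 0.01])
        out = call_candidate_signals(
            scores, {"G": list(scores["snp_id"])})
        assert len(out) == 1
        row = out.iloc[0]
        assert row["apex_snp"] == "rs11000"
        assert row["apex_abs_ihs"] == pytest.approx(3.1)
        assert row["magnitude_class"] == "3-4"
        assert row["n_members"] == 3

    def test_very_strong_class(self):
        scores = self.scores_from([1000, 11_000, 21_000],
                                  [4.2, 2.5, 2.5], [0.01, 0.01, 0.01])
        out = call_candidate_signals(scores, {"G": list(scores["snp_id"])})
        assert out.iloc[0]["magnitude_class"] == ">4"

    def test_negative_ihs_counts_via_absolute_value(self):
        scores = self.scores_from([1000, 11_000, 21_000],
                                  [-2.4, -3.1, -2.2], [0.01, 0.01, 0.01])
        out = call_candidate_signals(scores, {"G": list(scores["snp_id"])})
        assert len(out) == 1 and out.iloc[0]["apex_abs_ihs"] == pytest.approx(3.1)

    def test_permutation_p_gate(self):
        scores = self.scores_from([1000, 11_000, 21_000],
                                  [2.4, 3.1, 2.2], [0.2, 0.2, 0.2])
        out = call_candidate_signals(scores, {"G": list(scores["snp_id"])})
        assert out.empty
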