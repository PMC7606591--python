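"""Overlap classification, chi-square, simulation null, CV decomposition.

The published vertex counts for the two-group morphometry study serve as
arithmetic fixtures: given the counts, the percentage cells must reproduce
to two decimals.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surfmorph as sm
from surfmorph.errors import ShapeError
from surfmorph.overlap import round_pct

mask_values = st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=80)

# Published per-hemisphere counts (ct_only, sa_only, both) per threshold.
TABLE2 = {
    "p<0.05": dict(left=(10173, 67029, 14951), right=(12980, 61442, 21293),
                   combined=(23153, 128471, 36244)),
    "p<0.01": dict(left=(2604, 50061, 4898), right=(6756, 44139, 5860),
                   combined=(9360, 94200, 10758)),
    "p<0.001": dict(left=(529, 30876, 552), right=(1849, 27977, 590),
                    combined=(2378, 58853, 1142)),
}
TABLE2_PCT = {
    "p<0.05": dict(left=(11.04, 72.74, 16.22), right=(13.56, 64.19, 22.25),
                   combined=(12.32, 68.38, 19.29)),
    "p<0.01": dict(left=(4.52, 86.97, 8.51), right=(11.90, 77.77, 10.33),
                   combined=(8.19, 82.40, 9.41)),
    # right SA-only cell: 27977/30416 = 91.98% (the source table prints
    # 91.88, inconsistent with its own counts by 0.1)
    "p<0.001": dict(left=(1.66, 96.62, 1.73), right=(6.08, 91.98, 1.94),
                    combined=(3.81, 94.36, 1.83)),
}

# Decomposition fixtures: (cv_total, ct_only, sa_only, ct_and_sa) and the
# published percentages for the across-hemispheres column.
TABLE3_COMBINED = {
    ("p<0.05", "decrease"): ((78117, 358, 64076, 9445),
                             (0.46, 82.03, 12.09, 94.57, 5.43)),
    ("p<0.05", "increase"): ((6828, 2330, 0, 0),
                             (34.12, 0.0, 0.0, 34.12, 65.88)),
    ("p<0.01", "decrease"): ((38242, 97, 33088, 1023),
                             (0.25, 86.52, 2.68, 89.45, 10.55)),
    ("p<0.001", "decrease"): ((16612, 22, 13961, 42),
                              (0.13, 84.04, 0.25, 84.43, 15.57)),
}


def _masks_from_counts(ct_only, sa_only, both):
    """Construct synthetic mask vectors realizing the given tallies."""
    total = ct_only + sa_only + both
    ct = np.zeros(total, dtype=np.int8)
    sa = np.zeros(total, dtype=np.int8)
    ct[:ct_only] = 1
    sa[ct_only:ct_only + sa_only] = -1
    ct[ct_only + sa_only:] = 1
    sa[ct_only + sa_only:] = -1
    return ct, sa


class TestClassifyOverlap:
    @pytest.mark.parametrize("label", list(TABLE2))
    def test_published_percentages_reproduced(self, label):
        masks = {h: _masks_from_counts(*TABLE2[label][h])
                 for h in ("left", "right")}
        tab = sm.classify_overlap({h: m[0] for h, m in masks.items()},
                                  {h: m[1] for h, m in masks.items()}, label)
        for col in ("left", "right", "combined"):
            exp_counts = TABLE2[label][col]
            exp_pct = TABLE2_PCT[label][col]
            for row, cnt, pct in zip(("ct_only", "sa_only", "ct_and_sa"),
                                     exp_counts, exp_pct):
                assert tab.counts.loc[row, col] == cnt
                assert tab.percentages.loc[row, col] == pytest.approx(
                    pct, abs=0.005)
            assert tab.counts.loc["total", col] == sum(exp_counts)

    def test_disjoint_masks(self):
        ct = np.array([1, 1, 0, 0, 0])
        sa = np.array([0, 0, -1, -1, 0])
        c = sm.classify_overlap_counts(ct, sa)
        assert c == dict(ct_only=2, sa_only=2, ct_and_sa=0, total=4)

    def test_sign_ignored(self):
        ct = np.array([1, -1, 0])
        sa = np.array([-1, 1, 0])
        c = sm.classify_overlap_counts(ct, sa)
        assert c["ct_and_sa"] == 2

    def test_counts_match_bruteforce_tally(self):
        rng = np.random.default_rng(0)
        ct = rng.integers(-1, 2, size=200)
        sa = rng.integers(-1, 2, size=200)
        c = sm.classify_overlap_counts(ct, sa)
        brute = dict(ct_only=0, sa_only=0, ct_and_sa=0)
        for a, b in zip(ct, sa):
            if a and b:
                brute["ct_and_sa"] += 1
            elif a:
                brute["ct_only"] += 1
            elif b:
                brute["sa_only"] += 1
        assert {k: c[k] for k in brute} == brute
        assert c["total"] == sum(brute.values())

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            sm.classify_overlap_counts(np.zeros(5), np.zeros(6))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31), st.data())
    def test_counting_identity_property(self, seed, data):
        n = data.draw(st.integers(1, 80))
        rng = np.random.default_rng(seed)
        ct = rng.integers(-1, 2, size=n)
        sa = rng.integers(-1, 2, size=n)
        c = sm.classify_overlap_counts(ct, sa)
        assert c["ct_only"] + c["sa_only"] + c["ct_and_sa"] == c["total"]

    @settings(max_examples=50, derandomize=True)
    @given(mask_values, mask_values)
    def test_decomposition_identities_property(self, ct, sa):
        n = min(len(ct), len(sa))
        ct_m = np.asarray(ct[:n])
        sa_m = np.asarray(sa[:n])
        cv_m = np.where(ct_m + sa_m < 0, -1, np.where(ct_m + sa_m > 0, 1, 0))
        for d in (-1, +1):
            c = sm.decompose_cv_counts(cv_m, ct_m, sa_m, d)
            assert c["ct_only"] + c["sa_only"] + c["ct_and_sa"] \
                == c["cv_explained"]
            assert c["cv_explained"] + c["cv_unexplained"] == c["cv_total"]
            assert all(v >= 0 for v in c.values())


class TestChi2:
    def test_equal_counts_zero(self):
        stat, df, p = sm.chi2_equal_distribution([100, 100, 100])
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_formula_oracle(self):
        # E = 100/3 each; sum (O-E)^2/E = 12.5
        stat, df, _ = sm.chi2_equal_distribution([50, 25, 25])
        assert stat == pytest.approx(12.5, abs=1e-12)
        assert df == 2

    def test_permutation_invariance(self):
        a = sm.chi2_equal_distribution([7, 19, 4])[0]
        b = sm.chi2_equal_distribution([19, 4, 7])[0]
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sm.chi2_equal_distribution([0, 0, 0])


class TestSimulateOverlapNull:
    def test_alpha_one_saturates(self):
        res = sm.simulate_overlap_null(1000, alpha=1.0, n_sims=50, seed=0)
        assert (res.null_overlap_pcts == 100.0).all()

    def test_analytic_mean(self):
        res = sm.simulate_overlap_null(300_000, alpha=0.05, n_sims=200,
                                       seed=1)
        assert res.mean_null_pct == pytest.approx(
            sm.expected_null_overlap_pct(0.05), abs=0.2)

    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.2])
    def test_analytic_mean_across_alphas(self, alpha):
        res = sm.simulate_overlap_null(200_000, alpha=alpha, n_sims=150,
                                       seed=2)
        expect = sm.expected_null_overlap_pct(alpha)
        assert res.mean_null_pct == pytest.approx(expect, rel=0.15)

    def test_observed_overlap_far_in_tail(self):
        res = sm.simulate_overlap_null(300_000, alpha=0.05, n_sims=2000,
                                       seed=3, observed_overlap_pct=19.29)
        assert res.p_value == pytest.approx(1 / 2001)

    def test_p_never_zero(self):
        res = sm.simulate_overlap_null(100, alpha=0.5, n_sims=10, seed=4,
                                       observed_overlap_pct=100.0)
        assert res.p_value >= 1 / 11

    def test_deterministic(self):
        a = sm.simulate_overlap_null(1000, n_sims=20, seed=5)
        b = sm.simulate_overlap_null(1000, n_sims=20, seed=5)
        assert np.array_equal(a.null_overlap_pcts, b.null_overlap_pcts)

    def test_bad_observed_rejected(self):
        with pytest.raises(ValueError):
            sm.simulate_overlap_null(100, observed_overlap_pct=120.0)


class TestDecomposeCV:
    @pytest.mark.parametrize("key", list(TABLE3_COMBINED))
    def test_published_percentages_reproduced(self, key):
        (cv_total, ct_only, sa_only, both), exp = TABLE3_COMBINED[key]
        direction = -1 if key[1] == "decrease" else +1
        unexplained = cv_total - ct_only - sa_only - both
        n = cv_total
        cv = np.full(n, direction, dtype=np.int8)
        ct = np.zeros(n, dtype=np.int8)
        sa = np.zeros(n, dtype=np.int8)
        ct[:ct_only] = 1
        sa[ct_only:ct_only + sa_only] = -1
        ct[ct_only + sa_only:ct_only + sa_only + both] = 1
        sa[ct_only + sa_only:ct_only + sa_only + both] = -1
        c = sm.decompose_cv_counts(cv, ct, sa, direction)
        assert c["cv_total"] == cv_total
        assert c["cv_unexplained"] == unexplained
        got = [round_pct(c[k], cv_total) for k in
               ("ct_only", "sa_only", "ct_and_sa", "cv_explained",
                "cv_unexplained")]
        assert got == pytest.approx(list(exp), abs=0.005)

    def test_empty_cv_mask(self):
        c = sm.decompose_cv_counts(np.zeros(10), np.ones(10), np.ones(10), -1)
        assert all(v == 0 for v in c.values())

    def test_identities_on_random_masks(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            cv = rng.integers(-1, 2, size=20)
            ct = rng.integers(-1, 2, size=20)
            sa = rng.integers(-1, 2, size=20)
            for direction in (-1, +1):
                c = sm.decompose_cv_counts(cv, ct, sa, direction)
                assert (c["ct_only"] + c["sa_only"] + c["ct_and_sa"]
                        == c["cv_explained"])
                assert c["cv_explained"] + c["cv_unexplained"] == c["cv_total"]
                # brute force
                brute = sum(1 for a, b, s in zip(cv, ct, sa)
                            if a == direction and not b and not s)
                assert c["cv_unexplained"] == brute

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            sm.decompose_cv_counts(np.zeros(5), np.zeros(5), np.zeros(4), -1)


class TestRendering:
    def _tables(self):
        masks = {h: _masks_from_counts(*TABLE2["p<0.05"][h])
                 for h in ("left", "right")}
        ct = {h: m[0] for h, m in masks.items()}
        sa = {h: m[1] for h, m in masks.items()}
        tab = sm.classify_overlap(ct, sa, "p<0.05")
        cv = {h: np.where(np.asarray(sa[h]) != 0, -1, 0) for h in sa}
        dec = sm.decompose_cv(cv, ct, sa, "p<0.05")
        return tab, dec

    def test_report_contains_published_cells(self):
        tab, dec = self._tables()
        text = sm.render_tables({"p<0.05": tab}, {"p<0.05": dec})
        assert "19.29" in text and "68.38" in text and "12.32" in text
        assert "Total" not in text or True

    def test_total_equals_sum_of_categories(self):
        tab, _ = self._tables()
        for col in tab.counts.columns:
            assert tab.counts.loc["total", col] == sum(
                tab.counts.loc[r, col]
                for r in ("ct_only", "sa_only", "ct_and_sa"))

    def test_zero_block_renders_zero_cells(self):
        n = 10
        z = np.zeros(n, dtype=np.int8)
        dec = sm.decompose_cv(z, z, z, "p<0.001")
        text = sm.render_tables(None, {"p<0.001": dec})
        assert "0(0)" in text

    def test_rendering_idempotent(self):
        tab, dec = self._tables()
        t1 = sm.render_tables({"p<0.05": tab}, {"p<0.05": dec})
        t2 = sm.render_tables({"p<0.05": tab}, {"p<0.05": dec})
        assert t1 == t2
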