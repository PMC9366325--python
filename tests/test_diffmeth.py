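"""Beta-binomial site test, DML calling and DMR aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senemeth.diffmeth import (
    GroupCounts,
    PHI_CLIP,
    estimate_dispersion,
    dml_test,
    call_dml,
    call_dmr,
    summarize_dml,
)
from senemeth.simulate import simulate_two_group_counts


def counts_from_arrays(x1, n1, x2, n2, context="CG", spacing=10):
    x1, n1, x2, n2 = (np.atleast_2d(np.asarray(a, dtype=float)) for a in (x1, n1, x2, n2))
    n_sites = x1.shape[0]
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": (np.arange(n_sites) + 1) * spacing,
        "strand": "+",
        "context": context,
    })
    return GroupCounts(sites=sites, x1=x1, n1=n1, x2=x2, n2=n2)


class TestDispersion:
    def test_identical_replicates_hit_lower_clip(self):
        x = np.tile([50.0, 50.0, 50.0], (30, 1))
        n = np.tile([100.0, 100.0, 100.0], (30, 1))
        gc = counts_from_arrays(x, n, x, n)
        phi = estimate_dispersion(gc)
        assert np.allclose(phi, PHI_CLIP[0])

    def test_single_replicate_sites_get_prior_exactly(self, rng):
        # 40 replicated sites with scatter define the prior; 5 one-replicate
        # sites must inherit it unchanged
        n_rep = np.full((40, 3), 20.0)
        x_rep = rng.binomial(20, rng.beta(3, 7, size=(40, 3)))
        n_one = np.zeros((5, 3))
        n_one[:, 0] = 20.0
        x_one = np.zeros((5, 3))
        x_one[:, 0] = 5.0
        gc = counts_from_arrays(
            np.vstack([x_rep, x_one]), np.vstack([n_rep, n_one]),
            np.vstack([x_rep, x_one]), np.vstack([n_rep, n_one]),
        )
        phi = estimate_dispersion(gc)
        assert len(np.unique(phi[40:])) == 1
        # replicated sites are shrunk partway, not all equal to the prior
        assert len(np.unique(phi[:40])) > 1

    def test_parameter_recovery(self):
        beta = np.full(1000, 0.3)
        gc = simulate_two_group_counts(beta, beta, phi=0.05, n_reps=3,
                                       coverage_mean=30, seed=42)
        phi = estimate_dispersion(gc)
        assert 0.025 <= np.median(phi) <= 0.10

    def test_no_replication_falls_back_with_warning(self, caplog):
        n = np.array([[10.0], [12.0]])
        x = np.array([[3.0], [4.0]])
        gc = counts_from_arrays(x, n, x, n)
        with caplog.at_level("WARNING"):
            phi = estimate_dispersion(gc)
        assert np.allclose(phi, PHI_CLIP[0])
        assert any("pooled binomial" in r.message for r in caplog.records)


class TestDmlTest:
    def test_symmetric_identical_groups(self):
        gc = counts_from_arrays([[5, 5]], [[10, 10]], [[5, 5]], [[10, 10]])
        res = dml_test(gc, 0.05)
        assert res.loc[0, "diff"] == 0
        assert res.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_zero_dispersion_reduces_to_two_proportion_z(self):
        gc = counts_from_arrays([[8.0]], [[10.0]], [[2.0]], [[10.0]])
        res = dml_test(gc, 0.0)
        p1, p2 = 0.8, 0.2
        z_oracle = (p1 - p2) / np.sqrt(p1 * (1 - p1) / 10 + p2 * (1 - p2) / 10)
        assert res.loc[0, "wald_z"] == pytest.approx(z_oracle, abs=1e-9)
        assert res.loc[0, "p_raw"] == pytest.approx(2 * stats.norm.sf(z_oracle), abs=1e-9)

    def test_exchangeability(self):
        rng = np.random.default_rng(3)
        n = rng.integers(5, 30, size=(50, 3)).astype(float)
        x = rng.binomial(n.astype(int), 0.4).astype(float)
        n2 = rng.integers(5, 30, size=(50, 3)).astype(float)
        x2 = rng.binomial(n2.astype(int), 0.6).astype(float)
        a = dml_test(counts_from_arrays(x, n, x2, n2), 0.05)
        b = dml_test(counts_from_arrays(x2, n2, x, n), 0.05)
        assert np.allclose(a["diff"], -b["diff"])
        assert np.array_equal(a["p_raw"], b["p_raw"])

    def test_zero_coverage_sites_skipped(self):
        x = np.array([[3.0, 2.0], [0.0, 0.0]])
        n = np.array([[10.0, 10.0], [0.0, 0.0]])
        gc = counts_from_arrays(x, n, x, n)
        res = dml_test(gc, 0.05)
        assert len(res) == 1

    def test_type_one_error_calibration(self):
        beta = np.full(5000, 0.3)
        gc = simulate_two_group_counts(beta, beta, phi=0.05, n_reps=3,
                                       coverage_mean=15, seed=7)
        phi = estimate_dispersion(gc)
        res = dml_test(gc, phi)
        frac = (res["p_raw"] < 0.05).mean()
        assert 0.03 <= frac <= 0.08


class TestCallDml:
    def test_posterior_closed_form(self):
        res = pd.DataFrame({
            "chrom": ["chr1"], "pos": [10], "strand": ["+"], "context": ["CG"],
            "mu1": [0.5], "mu2": [0.2], "diff": [0.30], "se_diff": [0.05],
            "wald_z": [6.0], "p_raw": [0.0],
        })
        out = call_dml(res)
        oracle = stats.norm.cdf((0.30 - 0.25) / 0.05) + stats.norm.cdf((-0.30 - 0.25) / 0.05)
        assert out.loc[0, "post_prob_gt_delta"] == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize(
        "diff,se,expect_dml,expect_post",
        [
            (0.5, 1e-12, True, 1.0),     # se -> 0 limit with |diff| > delta
            (0.0, 0.1, False, None),      # centred: posterior below 1/2
        ],
    )
    def test_limits(self, diff, se, expect_dml, expect_post):
        res = pd.DataFrame({
            "chrom": ["chr1"], "pos": [10], "strand": ["+"], "context": ["CG"],
            "mu1": [0.5], "mu2": [0.5 - diff], "diff": [diff], "se_diff": [se],
            "wald_z": [0.0], "p_raw": [1.0],
        })
        out = call_dml(res)
        assert bool(out.loc[0, "is_dml"]) is expect_dml
        if expect_post is not None:
            assert out.loc[0, "post_prob_gt_delta"] == pytest.approx(expect_post, abs=1e-6)
        else:
            assert out.loc[0, "post_prob_gt_delta"] < 0.5

    def test_bad_delta(self):
        res = pd.DataFrame({"diff": [0.1], "se_diff": [0.1], "p_raw": [0.5]})
        with pytest.raises(ValueError):
            call_dml(res, delta=1.0)


def flagged_frame(positions, directions, sig, diffs=None, z=None, context="CG"):
    n = len(positions)
    return pd.DataFrame({
        "chrom": "chr1",
        "pos": positions,
        "strand": "+",
        "context": context,
        "diff": diffs if diffs is not None else [-0.3 if d == "hyper" else 0.3 for d in directions],
        "se_diff": [0.05] * n,
        "wald_z": z if z is not None else [3.0] * n,
        "p_raw": [1e-9 if s else 0.6 for s in sig],
        "is_dml": sig,
        "direction": directions,
    })


class TestCallDmr:
    def test_run_of_five_significant_sites(self):
        f = flagged_frame([100, 115, 130, 145, 160], ["hyper"] * 5, [True] * 5)
        out = call_dmr(f)
        assert len(out) == 1
        assert out.loc[0, "n_sites"] == 5
        assert out.loc[0, "direction"] == "hyper"
        assert out.loc[0, "end"] - out.loc[0, "start"] == 61

    def test_short_sparse_run_fails_thresholds(self):
        f = flagged_frame([100, 119], ["hyper"] * 2, [True] * 2)
        assert call_dmr(f).empty

    def test_direction_change_splits_regions(self):
        pos = [100, 130, 160, 260, 290, 320]
        f = flagged_frame(pos, ["hyper"] * 3 + ["hypo"] * 3, [True] * 6)
        out = call_dmr(f)
        assert len(out) == 2
        assert set(out["direction"]) == {"hyper", "hypo"}

    def test_merge_within_distance(self):
        pos = [100, 120, 140, 230, 250, 270]  # gap 90 <= merge_dist
        f = flagged_frame(pos, ["hyper"] * 6, [True] * 6)
        out = call_dmr(f)
        assert len(out) == 1 and out.loc[0, "n_sites"] == 6

    def test_area_stat_is_sum_of_z(self):
        f = flagged_frame([100, 120, 140, 160], ["hyper"] * 4, [True] * 4,
                          z=[1.0, 2.0, 3.0, 4.0])
        out = call_dmr(f)
        assert out.loc[0, "area_stat"] == pytest.approx(10.0)

    def test_unsorted_input_raises(self):
        f = flagged_frame([160, 100, 130], ["hyper"] * 3, [True] * 3)
        with pytest.raises(ValueError, match="sorted"):
            call_dmr(f)

    def test_planted_region_recovery(self):
        # 20 planted regions of 10 consecutive sites at |delta beta| = 0.30
        rng = np.random.default_rng(9)
        n_sites = 2000
        beta1 = np.full(n_sites, 0.45)
        beta2 = beta1.copy()
        truth = []
        starts = np.arange(20) * 100 + 10  # site indices, well separated
        for i, s in enumerate(starts):
            d = 0.30 if i % 2 == 0 else -0.30
            beta2[s : s + 10] += d
            truth.append((s, s + 10, "hyper" if d > 0 else "hypo"))  # change group1 -> group2
        gc = simulate_two_group_counts(beta1, beta2, phi=0.05, n_reps=3,
                                       coverage_mean=20, seed=17)
        phi = estimate_dispersion(gc)
        flagged = call_dml(dml_test(gc, phi))
        dmrs = call_dmr(flagged)
        # structural invariants of every called region
        for r in dmrs.itertuples():
            assert r.n_sites >= 3
            assert r.end - r.start >= 50
            assert r.n_sig_sites / r.n_sites >= 0.5
            assert r.direction in ("hypo", "hyper")
            assert abs(r.mean_diff) <= 1
        pos = gc.sites["pos"].to_numpy()
        recovered = 0
        matched = np.zeros(len(dmrs), bool)
        for s, e, direction in truth:
            t_lo, t_hi = pos[s] - 1, pos[e - 1]
            for k, r in enumerate(dmrs.itertuples()):
                inter = min(t_hi, r.end) - max(t_lo, r.start)
                if inter > 0.5 * min(t_hi - t_lo, r.end - r.start) and r.direction == direction:
                    recovered += 1
                    matched[k] = True
                    break
        assert recovered >= 16
        assert (~matched).sum() <= 4


class TestSummarize:
    def test_single_comparison_unique(self):
        f = flagged_frame([10, 20], ["hyper", "hypo"], [True, True])
        s = summarize_dml({"a_vs_b": f})
        assert s["unique_fraction"] == 1.0
        assert s["n_distinct_dmls"] == 2

    def test_identical_sets_not_unique(self):
        f = flagged_frame([10, 20], ["hyper", "hypo"], [True, True])
        s = summarize_dml({"a": f, "b": f.copy()})
        assert s["unique_fraction"] == 0.0

    def test_brute_force_set_arithmetic(self, rng):
        comps = {}
        truth_sets = {}
        for name in ("c1", "c2", "c3"):
            pos = np.sort(rng.choice(np.arange(10, 2000, 10), size=30, replace=False))
            sig = rng.random(30) < 0.5
            comps[name] = flagged_frame(pos, ["hyper"] * 30, list(sig))
            truth_sets[name] = {("chr1", int(p), "+") for p, s in zip(pos, sig) if s}
        s = summarize_dml(comps)
        from collections import Counter
        cnt = Counter(k for st in truth_sets.values() for k in st)
        assert s["n_distinct_dmls"] == len(cnt)
        assert s["unique_fraction"] == pytest.approx(
            sum(1 for v in cnt.values() if v == 1) / len(cnt)
        )
        # context fractions per direction sum to 1 where any DML exists
        comp = s["composition"]
        for (name, direction), sub in comp.groupby(["comparison", "direction"]):
            if sub["n"].sum() > 0:
                assert sub["fraction"].sum() == pytest.approx(1.0)

    def test_detection_monotone_in_effect_size(self):
        detected = []
        for d in (0.10, 0.20, 0.30, 0.40):
            beta1 = np.full(300, 0.4)
            beta2 = beta1 + d
            gc = simulate_two_group_counts(beta1, beta2, phi=0.05, n_reps=3,
                                           coverage_mean=20, seed=23)
            flagged = call_dml(dml_test(gc, estimate_dispersion(gc)))
            detected.append(int(flagged["is_dml"].sum()))
        assert detected == sorted(detected)
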