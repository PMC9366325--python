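"""Promoter derivation, interval algebra, compartment labels, metagene and
sample concordance."""

import numpy as np
import pandas as pd
import pytest

from senemeth.architecture import (
    derive_promoters,
    intersect_intervals,
    closest_interval,
    assign_compartment,
    assign_compartment_intervals,
    methylation_by_compartment,
    metagene_profile,
    sample_concordance,
)
from senemeth.io import CX_COLUMNS, MethylomeSample


def iv(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "kind", "id"])


def sample_from(pos_beta, stage="Blt", rep="1", context="CG", depth=10):
    rows = [
        ("chr1", int(p), "+", int(round(b * depth)), depth - int(round(b * depth)), context, "CGA")
        for p, b in pos_beta
    ]
    return MethylomeSample(stage, rep, pd.DataFrame(rows, columns=CX_COLUMNS))


class TestDerivePromoters:
    def test_plus_strand_atg_at_3000(self):
        genes = iv([("chr1", 2999, 4000, "+", "gene", "g1")])  # ATG 1-based 3000
        p = derive_promoters(genes, 2500)
        assert (p.loc[0, "start"], p.loc[0, "end"]) == (499, 2999)

    def test_minus_strand_atg_at_3000(self):
        genes = iv([("chr1", 2000, 3000, "-", "gene", "g1")])  # ATG 1-based 3000
        p = derive_promoters(genes, 2500, chrom_lengths={"chr1": 10_000})
        assert (p.loc[0, "start"], p.loc[0, "end"]) == (3000, 5500)

    def test_clipped_at_chromosome_start(self):
        genes = iv([("chr1", 99, 600, "+", "gene", "g1")])  # ATG 1-based 100
        p = derive_promoters(genes, 2500)
        assert (p.loc[0, "start"], p.loc[0, "end"]) == (0, 99)
        assert p.loc[0, "end"] - p.loc[0, "start"] == 99

    def test_missing_strand_errors(self):
        genes = iv([("chr1", 10, 20, ".", "gene", "g1")])
        with pytest.raises(ValueError, match="strand"):
            derive_promoters(genes)


def brute_force_pairs(a, b):
    out = set()
    for x in a.itertuples():
        for y in b.itertuples():
            if x.chrom == y.chrom and min(x.end, y.end) > max(x.start, y.start):
                out.add((x.id, y.id, min(x.end, y.end) - max(x.start, y.start)))
    return out


def brute_force_closest(a, b):
    out = {}
    for x in a.itertuples():
        best = None
        for y in b.itertuples():
            if y.chrom != x.chrom:
                continue
            if min(x.end, y.end) > max(x.start, y.start):
                cand = (0, y.start, y.id, True)
            elif y.start >= x.end:
                cand = (y.start - x.end, y.start, y.id, False)
            else:
                cand = (x.start - y.end, y.start, y.id, False)
            if best is None or (cand[0], cand[1], cand[2]) < (best[0], best[1], best[2]):
                best = cand
        out[x.id] = best
    return out


def random_intervals(rng, n, prefix, span=2000):
    starts = rng.integers(0, span, size=n)
    lens = rng.integers(1, 60, size=n)
    df = iv([
        ("chr1", int(s), int(s + l), "+", "x", f"{prefix}{i}")
        for i, (s, l) in enumerate(zip(starts, lens))
    ])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


class TestIntervalAlgebra:
    def test_adjacent_intervals_distance_zero_no_overlap(self):
        a = iv([("chr1", 0, 10, "+", "x", "a0")])
        b = iv([("chr1", 10, 20, "+", "x", "b0")])
        assert intersect_intervals(a, b).empty
        c = closest_interval(a, b)
        assert c.loc[0, "distance"] == 0 and not c.loc[0, "overlap"]

    def test_overlap_length(self):
        a = iv([("chr1", 0, 10, "+", "x", "a0")])
        b = iv([("chr1", 5, 15, "+", "x", "b0")])
        hit = intersect_intervals(a, b)
        assert len(hit) == 1 and hit.loc[0, "overlap"] == 5
        c = closest_interval(a, b)
        assert c.loc[0, "distance"] == 0 and bool(c.loc[0, "overlap"])

    def test_fuzz_against_quadratic_oracle(self, rng):
        for trial in range(20):
            a = random_intervals(rng, 20, "a")
            b = random_intervals(rng, 20, "b")
            hits = intersect_intervals(a, b)
            got = set(zip(hits["a_id"], hits["b_id"], hits["overlap"]))
            assert got == brute_force_pairs(a, b)
            cl = closest_interval(a, b)
            oracle = brute_force_closest(a, b)
            for r in cl.itertuples():
                dist, bstart, bid, ov = oracle[r.a_id]
                assert (r.distance, r.b_id, r.overlap) == (dist, bid, ov)

    def test_no_b_on_chromosome(self):
        a = iv([("chr2", 0, 10, "+", "x", "a0")])
        b = iv([("chr1", 5, 15, "+", "x", "b0")])
        c = closest_interval(a, b)
        assert c.loc[0, "b_id"] is None and np.isnan(c.loc[0, "distance"])


class TestAssignCompartment:
    def setup_method(self):
        self.genes = iv([("chr1", 5000, 7000, "+", "gene", "g1")])
        self.tes = iv([
            ("chr1", 3000, 3500, "+", "TE", "te_in_prom"),
            ("chr1", 9000, 9500, "+", "TE", "te_out"),
        ])
        self.promoters = derive_promoters(self.genes, 2500)

    def test_te_inside_promoter_precedence(self):
        lab = assign_compartment(["chr1"], [3100], self.genes, self.tes, self.promoters)
        assert lab[0] == "TE_in_promoter"

    def test_all_labels(self):
        chroms = ["chr1"] * 5
        pos = [3100, 9100, 6000, 4000, 100]
        lab = assign_compartment(chroms, pos, self.genes, self.tes, self.promoters)
        assert list(lab) == [
            "TE_in_promoter", "TE_outside_promoter", "ORF", "promoter_no_TE", "intergenic",
        ]

    def test_midpoint_rule_for_intervals(self):
        intervals = iv([("chr1", 6900, 7300, "+", "DMR", "d1")])  # midpoint 7100 -> intergenic
        lab = assign_compartment_intervals(intervals, self.genes, self.tes, self.promoters)
        assert lab[0] == "intergenic"

    def test_tiling_matches_per_base_oracle(self, rng):
        L = 20_000
        genes = random_intervals(rng, 5, "g", span=L)
        genes["kind"] = "gene"
        tes = random_intervals(rng, 5, "t", span=L)
        tes["kind"] = "TE"
        promoters = derive_promoters(genes, 500)
        pos = np.arange(0, L, 7)
        lab = assign_compartment(np.full(len(pos), "chr1", dtype=object), pos, genes, tes, promoters)

        te_in_prom = {
            t.id for t in tes.itertuples()
            for p in promoters.itertuples()
            if min(t.end, p.end) > max(t.start, p.start)
        }

        def oracle(x):
            in_te_in = any(t.start <= x < t.end for t in tes.itertuples() if t.id in te_in_prom)
            in_te_out = any(t.start <= x < t.end for t in tes.itertuples() if t.id not in te_in_prom)
            in_gene = any(g.start <= x < g.end for g in genes.itertuples())
            in_prom = any(p.start <= x < p.end for p in promoters.itertuples())
            if in_te_in:
                return "TE_in_promoter"
            if in_te_out:
                return "TE_outside_promoter"
            if in_gene:
                return "ORF"
            if in_prom:
                return "promoter_no_TE"
            return "intergenic"

        expected = [oracle(int(x)) for x in pos]
        assert list(lab) == expected
        # fractions are a partition of unity
        fr = pd.Series(lab).value_counts(normalize=True)
        assert fr.sum() == pytest.approx(1.0)


class TestMethylationByCompartment:
    def test_fully_methylated_compartment(self):
        genes = iv([("chr1", 0, 100, "+", "gene", "g1")])
        s = sample_from([(50, 1.0), (60, 1.0)])
        out = methylation_by_compartment([s], genes, genes.iloc[0:0], genes.iloc[0:0])
        cell = out[(out["compartment"] == "ORF") & (out["context"] == "CG")]
        assert cell["mean_meth"].iloc[0] == pytest.approx(1.0)

    def test_total_is_coverage_weighted_mean_of_disjoint_classes(self):
        genes = iv([("chr1", 0, 100, "+", "gene", "g1")])
        tes = iv([("chr1", 200, 300, "+", "TE", "t1")])
        s = sample_from([(50, 0.8), (250, 0.2)])
        out = methylation_by_compartment([s], genes, tes, genes.iloc[0:0])
        total = out[(out["compartment"] == "total") & (out["context"] == "CG")]["mean_meth"].iloc[0]
        assert total == pytest.approx((8 + 2) / 20)

    def test_planted_te_cg_level_recovered(self, fixture_samples, small_genome, small_config):
        genome, features, _ = small_genome
        genes = features[features["kind"] == "gene"]
        tes = features[features["kind"] == "TE"]
        from senemeth.architecture import derive_promoters as dp
        promoters = dp(genes, small_config.promoter_length,
                       {c: len(genome[c]) for c in genome})
        blt = [s for s in fixture_samples if s.stage == "Blt"]
        out = methylation_by_compartment(blt, genes, tes, promoters)
        cell = out[(out["compartment"] == "TE") & (out["context"] == "CG")]["mean_meth"].iloc[0]
        assert abs(cell - 0.85) < 0.02


class TestMetagene:
    def make_uniform(self, beta=0.5):
        pos_beta = [(p, beta) for p in range(1, 5001, 25)]
        return sample_from(pos_beta)

    def test_flat_profile(self):
        genes = iv([("chr1", 2000, 3000, "+", "gene", "g1")])
        prof = metagene_profile([self.make_uniform()], genes)
        vals = prof["mean_meth"].dropna()
        assert len(vals) > 30
        assert np.allclose(vals, 0.5)

    def test_gene_of_exactly_min_length_excluded(self):
        genes = iv([("chr1", 2000, 2400, "+", "gene", "g1")])  # length exactly 400
        prof = metagene_profile([self.make_uniform()], genes)
        assert prof["n_genes"].sum() == 0

    def test_minus_strand_profile_mirrors(self):
        rng = np.random.default_rng(4)
        pos_beta = [(p, float(b)) for p, b in zip(range(1, 5001, 10), rng.random(500))]
        s = sample_from(pos_beta)
        plus = iv([("chr1", 2000, 3000, "+", "gene", "g1")])
        minus = plus.copy()
        minus["strand"] = "-"
        p1 = metagene_profile([s], plus)["mean_meth"].to_numpy()
        p2 = metagene_profile([s], minus)["mean_meth"].to_numpy()
        np.testing.assert_allclose(p1, p2[::-1])

    def test_bad_flank(self):
        genes = iv([("chr1", 2000, 3000, "+", "gene", "g1")])
        with pytest.raises(ValueError, match="divisible"):
            metagene_profile([self.make_uniform()], genes, flank=1030)


class TestConcordance:
    def test_duplicate_sample_zero_distance(self):
        a = sample_from([(p, 0.3) for p in range(1, 1000, 20)], rep="1")
        b = sample_from([(p, 0.3) for p in range(1, 1000, 20)], rep="2")
        dist, scores, _ = sample_concordance([a, b])
        assert dist.iloc[0, 1] == pytest.approx(0.0)

    def test_manhattan_matches_direct_loop(self):
        rng = np.random.default_rng(8)
        pos = list(range(1, 501, 50))  # 10 bins
        b1 = rng.random(10)
        b2 = rng.random(10)
        a = sample_from(list(zip(pos, b1)), rep="1", depth=100)
        b = sample_from(list(zip(pos, b2)), rep="2", depth=100)
        dist, _, _ = sample_concordance([a, b])
        beta_a = np.round(b1 * 100) / 100
        beta_b = np.round(b2 * 100) / 100
        assert dist.iloc[0, 1] == pytest.approx(np.abs(beta_a - beta_b).sum(), abs=1e-12)

    def test_replicates_cluster_by_stage(self, fixture_samples):
        dist, scores, explained = sample_concordance(fixture_samples)
        labels = list(dist.columns)
        stages = [l.split("_")[0] for l in labels]
        d = dist.to_numpy()
        for i, l in enumerate(labels):
            order = np.argsort(d[i])
            nn = order[order != i][0]
            assert stages[nn] == stages[i], f"{l} nearest neighbour is {labels[nn]}"

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            sample_concordance([sample_from([(1, 0.5)])])
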