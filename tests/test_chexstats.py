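"""Background rates, exact tests vs enumeration, clustering, enrichment."""

import itertools
from math import comb, inf

import numpy as np
import pandas as pd
import pytest

from chexseq import chexstats
from chexseq.chexstats import (
    StrandRatio,
    background_rate,
    binarized_jaccard_cluster,
    fisher_association,
    highly_expressed,
    jaccard_distance,
    normalize_library,
    quantile_normalize,
    region_enrichment,
    select_trend_genes,
    sequence_complexity,
    strand_ratio_test,
    stratify_expression_by_tss_distance,
    tss_dynamics,
)
from chexseq.priming import PrimingSite


def site(pos, chrom="chr1", strand="+"):
    return PrimingSite(chrom=chrom, pos=pos, strand=strand, quality="A1", sample_id="S1")


class TestBackground:
    @pytest.mark.parametrize(
        "control,noncontrol,expected",
        [(381, 2640, 14.4), (14704, 53357, 27.6), (0, 100, 0.0), (1890, 2640, 71.6)],
    )
    def test_rate(self, control, noncontrol, expected):
        assert background_rate(control, noncontrol) == expected

    def test_zero_denominator_undefined(self):
        with pytest.raises(ValueError):
            background_rate(5, 0)


class TestStrandRatio:
    def test_ratio_and_count_floor(self):
        assert StrandRatio("exon", 6, 3, "S1").ratio == 2.0
        assert StrandRatio("exon", 3, 1, "S1").ratio is None  # total 4 < 5
        assert StrandRatio("exon", 5, 0, "S1").ratio == inf

    def test_ranksum_small_example(self):
        # {1,2} vs {3,4}: 6 equally likely rank assignments, 2 as extreme
        _, p = strand_ratio_test([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    def test_ranksum_matches_enumeration(self, rng):
        """Exact p equals brute-force enumeration over rank assignments."""
        for _ in range(10):
            n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(1.0, n + m + 1))  # distinct, no ties
            a, b = list(pooled[:n]), list(pooled[n:])
            _, p = strand_ratio_test(a, b)
            u_obs = sum(1 for x in a for y in b if x > y)
            stat_obs = min(u_obs, n * m - u_obs)
            hits = total = 0
            for combo in itertools.combinations(range(n + m), n):
                grp = set(combo)
                ua = sum(
                    1
                    for i in grp
                    for j in range(n + m)
                    if j not in grp and pooled[i] > pooled[j]
                )
                total += 1
                if min(ua, n * m - ua) <= stat_obs:
                    hits += 1
            assert p == pytest.approx(hits / total)

    def test_too_few_samples_skipped(self):
        with pytest.raises(ValueError):
            strand_ratio_test([1.0], [2.0, 3.0])


class TestFisher:
    def test_perfect_association(self):
        universe = set(range(10))
        primed = set(range(5))
        res = fisher_association(primed, primed, universe)
        assert res.table == ((5, 0), (0, 5))
        assert res.p_value == pytest.approx(2 / 252)
        assert res.odds_ratio == inf

    def test_independence(self):
        universe = set(range(100))
        primed = set(range(50))
        high = set(range(25, 75))
        res = fisher_association(primed, high, universe)
        assert res.table == ((25, 25), (25, 25))
        assert res.odds_ratio == 1.0 and res.p_value == 1.0

    def test_empty_primed(self):
        res = fisher_association(set(), set(range(5)), set(range(10)))
        assert res.odds_ratio == 0.0
        assert res.pct_primed_expressed == 0.0

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            fisher_association(set(), set(), set())

    def test_matches_hypergeometric_enumeration(self, rng):
        """Two-sided p equals the sum of point probabilities <= observed."""
        for _ in range(10):
            a, b, c, d = (int(x) for x in rng.integers(0, 6, 4))
            n = a + b + c + d
            if n == 0 or (a + b) == 0:
                continue
            universe = set(range(n))
            items = list(universe)
            primed = set(items[: a + b])
            high = set(items[:a]) | set(items[a + b : a + b + c])
            res = fisher_association(primed, high, universe)

            def point_prob(x):
                return (
                    comb(a + b, x)
                    * comb(c + d, (a + c) - x)
                    / comb(n, a + c)
                    if 0 <= (a + c) - x <= c + d
                    else 0.0
                )

            p_obs = point_prob(a)
            p_two = sum(
                point_prob(x)
                for x in range(0, a + b + 1)
                if point_prob(x) <= p_obs + 1e-12
            )
            assert res.p_value == pytest.approx(p_two, rel=1e-9)

    def test_highly_expressed_policy(self):
        expr = pd.Series({"g1": 0.0, "g2": 1.0, "g3": 5.0, "g4": 10.0})
        assert highly_expressed(expr) == {"g3", "g4"}
        assert highly_expressed(expr, universe={"g1", "g2", "g3", "g4", "g5"}) == {"g3", "g4"}


class TestStratification:
    def _model(self):
        from chexseq.genemodel import build_genic_regions

        rows = []
        for i, start in enumerate(range(10_000, 110_000, 10_000)):
            gid = f"G{i}"
            rows.append(("chr1", "gene", start, start + 4_000, "+", gid, gid + ".1"))
            rows.append(("chr1", "exon", start, start + 4_000, "+", gid, gid + ".1"))
        frame = pd.DataFrame(
            rows,
            columns=["chrom", "feature", "start", "end", "strand", "gene_id", "transcript_id"],
        )
        return build_genic_regions(frame, chrom_lengths={"chr1": 200_000})

    def test_site_at_tss_in_zero_stratum(self):
        model = self._model()
        expr = pd.Series({f"G{i}": 10.0 for i in range(10)})
        out = stratify_expression_by_tss_distance([site(10_000)], model, expr)
        assert list(out.gene_id) == ["G0"]
        assert out.distance.iloc[0] == 0
        assert str(out.stratum.iloc[0]) == "0-250"

    def test_beyond_max_dist_excluded(self):
        model = self._model()
        expr = pd.Series({f"G{i}": 10.0 for i in range(10)})
        out = stratify_expression_by_tss_distance([site(13_000)], model, expr)
        assert out.empty  # 3,000 bp > 2,500

    def test_perfect_anticorrelation(self):
        model = self._model()
        # one site per gene at increasing distance; expression = C - |distance|
        sites, expr = [], {}
        for i in range(10):
            d = 100 + 200 * i
            sites.append(site(10_000 + 10_000 * i + d))
            expr[f"G{i}"] = 5_000.0 - d
        out = stratify_expression_by_tss_distance(sites, model, pd.Series(expr))
        assert out.attrs["spearman_r"] == pytest.approx(-1.0)


class TestDynamics:
    def test_ecdf_examples(self, toy_model):
        series = tss_dynamics(
            {"pre": [site(10_000 - 100), site(10_050), site(10_200)]}, toy_model
        )
        assert series.ecdf("pre", 100) == pytest.approx(2 / 3)
        series2 = tss_dynamics(
            {"a": [site(10_050)], "b": [site(10_050)]}, toy_model
        )
        assert series2.distances["a"].tolist() == series2.distances["b"].tolist()

    def test_fe_follows_planted_proximal_fraction(self, toy_model, rng):
        """FE per timepoint strictly follows the planted ordering."""
        fractions = {"pre": 0.9, "15min": 0.3, "1h": 0.1, "2h": 0.5, "24h": 0.7}
        sites_by_tp = {}
        for tp, frac in fractions.items():
            sites_tp = []
            for _ in range(600):
                if rng.random() < frac:
                    pos = 10_000 + int(rng.integers(-1_000, 1_001))
                else:
                    sign = 1 if rng.random() < 0.5 else -1
                    pos = 10_000 + sign * int(rng.integers(1_001, 5_001))
                sites_tp.append(site(pos))
            sites_by_tp[tp] = sites_tp
        series = tss_dynamics(sites_by_tp, toy_model)
        order = sorted(fractions, key=fractions.get)
        fes = [series.fe[tp] for tp in order]
        assert fes == sorted(fes)

    def test_trend_gene_selection(self):
        trend = np.array([5.0, 1.0, 0.5, 2.0, 4.0])
        counts = pd.DataFrame(
            {
                "t0": [50, 10, 7.0],
                "t1": [10, 50, 7.0],
                "t2": [5, 55, 7.0],
                "t3": [20, 40, 7.0],
                "t4": [40, 20, 7.0],
            },
            index=["up", "down", "flat"],
        )
        cor, anti, r = select_trend_genes(counts, trend, normalize=False)
        assert cor == ["up"] and anti == ["down"]
        assert "flat" not in r.index  # zero variance skipped
        assert r["up"] == pytest.approx(1.0)

    def test_differential_selection_rule(self):
        base = pd.Series({"g1": 10.0, "g2": 10.0, "g3": 1.0, "g4": 0.0})
        treat = pd.Series({"g1": 50.0, "g2": 11.0, "g3": 2.0, "g4": 8.0})
        out = chexstats.select_differential_genes(base, treat, min_fold=2.0, min_count=5)
        assert set(out.index) == {"g1", "g4"}  # g3 fails min_count, g2 the fold
        assert out.loc["g1", "direction"] == "gain"
        loss = chexstats.select_differential_genes(treat, base, min_fold=2.0, min_count=5)
        assert (loss.direction == "loss").sum() == 2

    def test_library_normalization_equalizes_totals(self):
        counts = pd.DataFrame({"s1": [1.0, 3.0], "s2": [10.0, 30.0]})
        normed = normalize_library(counts)
        assert normed.sum(axis=0).nunique() == 1


class TestClustering:
    def test_jaccard_examples(self):
        a = np.array([1, 1, 0], dtype=bool)
        b = np.array([1, 0, 1], dtype=bool)
        assert jaccard_distance(a, b) == pytest.approx(2 / 3)
        assert jaccard_distance(a, a) == 0.0

    def test_closest_pair_merges_first(self):
        lengths = {"chr1": 50_000}
        tracks = {
            "t1": [("chr1", 0, 10_000)],
            "t2": [("chr1", 0, 11_000)],
            "t3": [("chr1", 40_000, 50_000)],
        }
        dm, link, order, newick = binarized_jaccard_cluster(tracks, lengths, bin_size=1_000)
        assert dm.loc["t1", "t2"] < dm.loc["t1", "t3"]
        # the first merge joins t1 and t2 -> they are adjacent leaves
        assert abs(order.index("t1") - order.index("t2")) == 1
        assert newick.endswith(";") and "t3" in newick

    def test_identical_tracks_distance_zero(self):
        lengths = {"chr1": 10_000}
        iv = [("chr1", 100, 900)]
        dm, *_ = binarized_jaccard_cluster({"a": iv, "b": iv}, lengths, bin_size=500)
        assert dm.loc["a", "b"] == 0.0


class TestEnrichment:
    def test_fold_enrichment_example(self, rng):
        # 100 sites, track covers 10% of the genome, 30 inside -> FE = 3
        lengths = {"chr1": 100_000}
        track = [("chr1", 0, 10_000)]
        sites = [site(int(p)) for p in rng.integers(0, 10_000, 30)]
        sites += [site(int(p)) for p in rng.integers(10_000, 100_000, 70)]
        assert region_enrichment(sites, track, lengths) == pytest.approx(3.0)

    def test_uniform_sites_near_one(self, rng):
        lengths = {"chr1": 100_000}
        track = [("chr1", 20_000, 60_000)]
        sites = [site(int(p)) for p in rng.integers(0, 100_000, 5_000)]
        assert region_enrichment(sites, track, lengths) == pytest.approx(1.0, abs=0.1)

    def test_empty_track_undefined(self):
        with pytest.raises(ValueError):
            region_enrichment([site(5)], [], {"chr1": 100})

    def test_quantile_normalize_examples(self):
        out = quantile_normalize(pd.Series([3.0, 1.0, 2.0]))
        assert out.tolist() == [1.0, 0.0, 0.5]

    def test_quantile_normalize_monotone_idempotent(self, rng):
        x = pd.Series(rng.normal(size=50))
        q = quantile_normalize(x)
        assert (q.sort_index().diff().dropna()[x.sort_index().diff().dropna() > 0] > 0).all()
        assert np.allclose(quantile_normalize(q), q)


class TestComplexity:
    def test_homopolymer_zero(self):
        assert sequence_complexity("AAAAAAAA") == 0.0

    def test_uniform_dinucleotides_one(self):
        # de Bruijn-style cycle covering all 16 dinucleotides equally
        seq = "AACAGATCCGCTGGTT"
        assert sequence_complexity(seq + seq[0]) == pytest.approx(1.0)

    def test_alternating_dinucleotide(self):
        # 9-mer ACACACACA: 4x AC and 4x CA -> 1 bit / 4 bits
        assert sequence_complexity("ACACACACA") == pytest.approx(0.25)
        assert sequence_complexity("ACACACAC") == pytest.approx(0.25, abs=0.01)

    def test_too_short_undefined(self):
        with pytest.raises(ValueError):
            sequence_complexity("A")


def test_strand_ratios_from_samples(toy_model):
    sites_by_sample = {
        "S1": [site(11_000, strand="-")] * 4 + [site(11_005, strand="+")] * 2
    }
    ratios = chexstats.strand_ratios(sites_by_sample, toy_model)
    exon = next(r for r in ratios if r.region == "exon")
    assert (exon.antisense, exon.sense) == (4, 2)
    assert exon.ratio == 2.0
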