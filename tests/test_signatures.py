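import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from scnctype.signatures import (
    CentroidSignature,
    GeneSet,
    SsgseaParams,
    WeightedSignature,
    ne_score,
    parse_gmt,
    ssgsea_score,
    weighted_zscore_score,
)


def ssgsea_oracle(values, index, set_genes, alpha):
    """Direct-summation ssGSEA oracle for one sample: explicit loop over
    the descending-ranked gene list, no vectorization shared with the
    implementation."""
    x = np.asarray(values, float)
    n = len(x)
    ranks = rankdata(x)
    order = np.argsort(-x, kind="stable")
    in_set = np.array([g in set_genes for g in index])
    n_in = in_set.sum()
    denom_in = sum(ranks[i] ** alpha for i in order if in_set[i])
    cum_in = cum_out = 0.0
    total = 0.0
    for i in order:
        if in_set[i]:
            cum_in += ranks[i] ** alpha / denom_in
        else:
            cum_out += 1.0 / (n - n_in)
        total += cum_in - cum_out
    return total


class TestParseGmt:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tA\tB\n")
        coll = parse_gmt(p)
        assert coll["S1"].genes == ("A", "B")

    def test_duplicate_set_names_error(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\td\tA\nS1\td\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_gmt(p)

    def test_duplicate_genes_deduplicated_with_warning(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S2\td\tA\tA\tB\n")
        with pytest.warns(UserWarning, match="duplicate"):
            coll = parse_gmt(p)
        assert len(coll["S2"]) == 2

    def test_short_line_error(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\n")
        with pytest.raises(ValueError, match="fewer than 3"):
            parse_gmt(p)


class TestSsgsea:
    def test_matches_bruteforce_oracle(self, random_expr, rng):
        genes = list(random_expr.index)
        gs = GeneSet("rand", tuple(rng.choice(genes, 20, replace=False)))
        params = SsgseaParams(alpha=0.25, normalize="none")
        scores = ssgsea_score(random_expr, gs, params)
        for s in random_expr.columns:
            expected = ssgsea_oracle(
                random_expr[s].to_numpy(), genes, set(gs.genes), 0.25
            )
            assert scores[s] == pytest.approx(expected, abs=1e-9)

    def test_alpha_zero_matches_unweighted_oracle(self, random_expr, rng):
        """alpha = 0 reduces to the unweighted Kolmogorov-style running sum."""
        genes = list(random_expr.index)
        gs = GeneSet("rand", tuple(rng.choice(genes, 15, replace=False)))
        scores = ssgsea_score(random_expr, gs, SsgseaParams(0.0, "none"))
        s = random_expr.columns[0]
        x = random_expr[s].to_numpy()
        order = np.argsort(-x, kind="stable")
        in_set = np.isin(np.array(genes)[order], list(gs.genes))
        running = np.cumsum(in_set) / in_set.sum() - np.cumsum(~in_set) / (~in_set).sum()
        assert scores[s] == pytest.approx(running.sum(), abs=1e-9)

    def test_invariant_under_monotone_transform(self, random_expr):
        gs = GeneSet("top", tuple(random_expr.index[:5]))
        params = SsgseaParams(normalize="none")
        a = ssgsea_score(random_expr, gs, params)
        b = ssgsea_score(np.exp(random_expr / 3.0) + 7.0, gs, params)
        assert np.allclose(a, b, atol=1e-9)

    def test_top_placement_is_maximum_by_enumeration(self):
        """Exhaustive check over all 120 size-3 sets of a 10-gene sample:
        the set occupying the top 3 ranks scores highest."""
        genes = [f"g{i}" for i in range(10)]
        df = pd.DataFrame(
            {"s": np.arange(10, 0, -1, dtype=float)}, index=genes
        )
        params = SsgseaParams(normalize="none")
        scores = {
            combo: ssgsea_score(df, GeneSet("c", combo), params)["s"]
            for combo in itertools.combinations(genes, 3)
        }
        top = ("g0", "g1", "g2")  # ranks 1-3 (highest expression)
        bottom = ("g7", "g8", "g9")
        assert scores[top] > scores[bottom]
        assert scores[top] == max(scores.values())

    def test_gene_order_invariance(self, random_expr, rng):
        gs = GeneSet("rand", tuple(rng.choice(random_expr.index, 12, replace=False)))
        shuffled = random_expr.sample(frac=1.0, random_state=3)
        a = ssgsea_score(random_expr, gs)
        b = ssgsea_score(shuffled, gs)
        assert np.allclose(a, b, atol=1e-12)

    def test_no_overlap_is_error(self, random_expr):
        with pytest.raises(ValueError, match="no gene"):
            ssgsea_score(random_expr, GeneSet("x", ("ZZZ",)))


def _random_centroid(rng, n=50):
    genes = tuple(f"g{i}" for i in range(n))
    return CentroidSignature(
        genes=genes,
        ne_centroid=rng.normal(size=n),
        nonne_centroid=rng.normal(size=n),
    )


class TestNeScore:
    def test_matches_two_correlation_oracle(self, rng):
        sig = _random_centroid(rng)
        df = pd.DataFrame(
            rng.normal(5, 2, size=(50, 6)).clip(min=0),
            index=sig.genes,
            columns=[f"S{j}" for j in range(6)],
        )
        res = ne_score(df, sig)
        for j, s in enumerate(df.columns):
            x = df[s].to_numpy()
            expected = (
                np.corrcoef(x, sig.ne_centroid)[0, 1]
                - np.corrcoef(x, sig.nonne_centroid)[0, 1]
            ) / 2.0
            assert res.scores[j] == pytest.approx(expected, abs=1e-12)

    def test_score_one_at_ne_centroid_with_anticorrelated_centroids(self):
        genes = tuple(f"g{i}" for i in range(10))
        ne_c = np.arange(10, dtype=float)
        sig = CentroidSignature(genes, ne_c, 9.0 - ne_c)  # rho = -1
        df = pd.DataFrame({"s": ne_c}, index=genes)
        res = ne_score(df, sig)
        assert res.scores[0] == pytest.approx(1.0, abs=1e-12)
        assert res.labels[0] == "NE"

    def test_identical_centroids_score_zero_all_nonne(self, rng):
        genes = tuple(f"g{i}" for i in range(10))
        c = rng.normal(size=10)
        sig = CentroidSignature(genes, c, c.copy())
        df = pd.DataFrame(
            rng.normal(size=(10, 4)), index=genes, columns=list("abcd")
        )
        res = ne_score(df, sig)
        assert np.allclose(res.scores, 0.0, atol=1e-12)
        assert res.labels == ["non-NE"] * 4

    def test_score_bounded_in_unit_interval(self, rng):
        sig = _random_centroid(rng)
        df = pd.DataFrame(
            rng.lognormal(1, 1, size=(50, 30)),
            index=sig.genes,
            columns=[f"S{j}" for j in range(30)],
        )
        res = ne_score(df, sig)
        assert (res.scores >= -1).all() and (res.scores <= 1).all()

    def test_constant_sample_is_error(self, rng):
        sig = _random_centroid(rng, n=10)
        df = pd.DataFrame({"s": np.full(10, 3.0)}, index=sig.genes)
        with pytest.raises(ValueError, match="constant"):
            ne_score(df, sig)

    def test_too_few_overlapping_genes_is_error(self, rng):
        sig = _random_centroid(rng, n=10)
        df = pd.DataFrame(
            {"s": [1.0, 2.0], "t": [2.0, 1.0]}, index=["g0", "ZZZ"]
        )
        with pytest.raises(ValueError, match="at least 3"):
            ne_score(df, sig)


class TestWeightedScore:
    def test_constant_genes_score_zero(self):
        df = pd.DataFrame(
            [[2.0, 2.0, 2.0], [7.0, 7.0, 7.0]], index=["a", "b"],
            columns=list("xyz"),
        )
        sig = WeightedSignature({"a": 1.0, "b": 1.0})
        assert (weighted_zscore_score(df, sig) == 0).all()

    def test_direct_arithmetic(self):
        # two genes with z-rows (1,-1): scores (2, -2) under unit weights
        df = pd.DataFrame(
            [[1.0, -1.0], [1.0, -1.0]], index=["a", "b"], columns=["s1", "s2"]
        )
        sig = WeightedSignature({"a": 1.0, "b": 1.0})
        scores = weighted_zscore_score(df, sig)
        # z of (1,-1) with ddof=1 is (0.7071, -0.7071); sum over 2 genes
        assert scores["s1"] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert scores["s2"] == pytest.approx(-np.sqrt(2), abs=1e-12)

    def test_scores_sum_to_zero_across_cohort(self, random_expr, rng):
        genes = rng.choice(random_expr.index, 17, replace=False)
        sig = WeightedSignature({g: rng.normal() for g in genes})
        assert weighted_zscore_score(random_expr, sig).mean() == pytest.approx(
            0.0, abs=1e-9
        )

    def test_no_overlap_is_error(self, random_expr):
        with pytest.raises(ValueError, match="no signature gene"):
            weighted_zscore_score(random_expr, WeightedSignature({"ZZZ": 1.0}))
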