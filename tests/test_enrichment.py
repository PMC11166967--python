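"""Enrichment statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spaceskin import enrichment
from spaceskin._utils import ValidationError


def brute_force_ora_p(universe_size, set_size, query_size, overlap):
    """Exact tail probability by enumerating all query draws."""
    universe = range(universe_size)
    members = set(range(set_size))
    hits = total = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        if len(members & set(draw)) >= overlap:
            hits += 1
    return hits / total


def brute_force_es(scores, members, weight):
    """Independent running-sum recomputation (plain python loop)."""
    genes = list(scores.index)
    k = sum(g in members for g in genes)
    n = len(genes)
    denom = sum(abs(scores[g]) ** weight for g in genes if g in members)
    cur, best = 0.0, 0.0
    for g in genes:
        if g in members:
            cur += (abs(scores[g]) ** weight) / denom if denom > 0 else 1.0 / k
        else:
            cur -= 1.0 / (n - k)
        if abs(cur) > abs(best):
            best = cur
    return best


class TestORA:
    def test_full_overlap_exact_value(self):
        uni = [f"g{i}" for i in range(20)]
        res = enrichment.ora(uni[:5], uni, {"S": ("d", uni[:5])}, min_size=0)
        assert res["pvalue"][0] == pytest.approx(1 / 15504, rel=1e-12)

    def test_zero_overlap_p_is_one(self):
        uni = [f"g{i}" for i in range(10)]
        res = enrichment.ora(uni[:3], uni, {"S": ("d", uni[5:])}, min_size=0)
        assert res["pvalue"][0] == pytest.approx(1.0)

    def test_small_set_excluded_by_strict_threshold(self):
        uni = [f"g{i}" for i in range(30)]
        coll = {"small": ("d", uni[:15]), "big": ("d", uni[:16])}
        res = enrichment.ora(uni[:5], uni, coll, min_size=15)
        assert res["set"].tolist() == ["big"]  # size > 15 is strict

    @pytest.mark.parametrize("u,k,q,seed", [(15, 4, 5, 0), (20, 5, 5, 1),
                                            (25, 6, 4, 2), (12, 3, 6, 3)])
    def test_matches_enumeration(self, u, k, q, seed):
        rng = np.random.default_rng(seed)
        uni = [f"g{i}" for i in range(u)]
        members = list(rng.choice(uni, size=k, replace=False))
        query = list(rng.choice(uni, size=q, replace=False))
        res = enrichment.ora(query, uni, {"S": ("d", members)}, min_size=0)
        overlap = len(set(members) & set(query))
        # enumeration oracle works on canonical relabeled indices
        expect = brute_force_ora_p(u, k, q, overlap)
        assert res["pvalue"][0] == pytest.approx(expect, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            enrichment.ora(["a"], [], {"S": ("d", ["a"])})


class TestRunningSum:
    def _ranked(self, n=10):
        return pd.Series(np.arange(n, 0, -1, dtype=float),
                         index=[f"g{i}" for i in range(n)])

    def test_top_block_es_plus_one(self):
        es, _ = enrichment.enrichment_score(self._ranked(),
                                            {"g0", "g1", "g2"})
        assert es == pytest.approx(1.0)

    def test_bottom_block_es_minus_one(self):
        scores = self._ranked() - 20.0  # all negative
        es, _ = enrichment.enrichment_score(scores, {"g7", "g8", "g9"})
        assert es == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        scores = pd.Series(rng.normal(size=8),
                           index=[f"g{i}" for i in range(8)])
        ranked = enrichment.make_ranked_list(scores)
        members = set(rng.choice(ranked.index, size=3, replace=False))
        es, _ = enrichment.enrichment_score(ranked, members)
        assert es == pytest.approx(brute_force_es(ranked, members, 1.0),
                                   abs=1e-12)

    def test_weight_zero_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.random(12) + 0.5,
                           index=[f"g{i}" for i in range(12)])
        ranked = enrichment.make_ranked_list(scores)
        members = {"g1", "g4", "g7"}
        es1, _ = enrichment.enrichment_score(ranked, members, weight=0.0)
        rescaled = enrichment.make_ranked_list(scores ** 3 * 7)
        es2, _ = enrichment.enrichment_score(rescaled, members, weight=0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)


class TestRunningSumProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(-10, 10, allow_nan=False, width=32),
                    min_size=4, max_size=20, unique=True),
           st.integers(min_value=1, max_value=3),
           st.floats(0.0, 2.0))
    def test_es_bounded_and_matches_oracle(self, values, k, weight):
        """|ES| <= 1 for any scores/weight, and the score equals the
        brute-force running-sum recomputation."""
        genes = [f"g{i}" for i in range(len(values))]
        ranked = enrichment.make_ranked_list(pd.Series(values, index=genes))
        members = set(genes[:k])
        es, _ = enrichment.enrichment_score(ranked, members, weight=weight)
        assert abs(es) <= 1 + 1e-12
        assert es == pytest.approx(brute_force_es(ranked, members, weight),
                                   abs=1e-12)


class TestLeadingEdge:
    def test_whole_set_when_on_top(self):
        scores = pd.Series([5.0, 4, 3, 2, 1],
                           index=["a", "b", "c", "d", "e"])
        assert enrichment.leading_edge(scores, {"a", "b"}) == ["a", "b"]

    def test_single_gene_when_extremum_first(self):
        scores = pd.Series([100.0, 1, 0.9, 0.8, 0.7, 0.6],
                           index=["a", "b", "c", "d", "e", "f"])
        assert enrichment.leading_edge(scores, {"a", "f"}) == ["a"]

    def test_negative_es_takes_tail_members(self):
        scores = pd.Series([5.0, 4, 3, -2, -4],
                           index=["a", "b", "c", "d", "e"])
        le = enrichment.leading_edge(scores, {"d", "e"})
        assert le == ["d", "e"]


class TestGseaPermutation:
    def test_permutation_p_matches_full_enumeration(self):
        # 6-gene ranking, 2-member set: the gene-label null has C(6,2)=15
        # equally likely membership placements
        scores = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0, -3.0],
                           index=list("abcdef"))
        members = {"a", "b"}
        ranked = enrichment.make_ranked_list(scores)
        es, _ = enrichment.enrichment_score(ranked, members)
        perm_es = []
        for combo in itertools.combinations(ranked.index, 2):
            perm_es.append(enrichment.enrichment_score(ranked,
                                                       set(combo))[0])
        same = [e for e in perm_es if e * np.sign(es) > 0]
        exact = sum(abs(e) >= abs(es) for e in same) / len(same)

        n_perm = 2000
        res = enrichment.gsea(ranked, {"S": ("d", list(members))},
                              min_size=1, n_perm=n_perm, seed=0)
        p_hat = res["pvalue"][0]
        se = math.sqrt(exact * (1 - exact) / n_perm) + 1e-9
        assert abs(p_hat - exact) <= 3 * se + 2 / n_perm

    def test_absent_set_skipped_with_warning(self, caplog):
        scores = pd.Series([2.0, 1.0, -1.0, -2.0, 0.5, 1.5, -0.5, 0.1,
                            0.2, 0.3], index=[f"g{i}" for i in range(10)])
        with caplog.at_level("WARNING"):
            res = enrichment.gsea(scores, {"S": ("d", ["zz"])}, min_size=1,
                                  n_perm=100, seed=0)
        assert len(res) == 0

    def test_nes_sign_matches_es(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(size=40),
                           index=[f"g{i}" for i in range(40)])
        coll = {f"S{j}": ("d", list(rng.choice(scores.index, 5,
                                               replace=False)))
                for j in range(5)}
        res = enrichment.gsea(scores, coll, min_size=1, n_perm=200, seed=1)
        assert (np.sign(res["NES"]) == np.sign(res["ES"])).all()
        assert (res["ES"].abs() <= 1 + 1e-12).all()
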