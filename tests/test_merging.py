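"""Merge-group construction and significance-preserving gene addition."""

import numpy as np
import pytest

from bicnet.core import Bicluster, PipelineParams
from bicnet.fixtures import generate, single_block_spec
from bicnet.merging import (
    build_merge_groups,
    largest_feasible_prefix,
    merge_all,
    merge_group,
)
from bicnet.significance import NullCache, score_biclusters

from _oracles import largest_feasible_prefix_by_scan


def _bic(genes, conds, p=0.01):
    return Bicluster(frozenset(genes), frozenset(conds), t_stat=0.9, p_value=p)


class TestBuildMergeGroups:
    def test_distinct_condition_sets_stay_apart(self):
        bics = [_bic("abc", "xy"), _bic("abc", "yz")]
        groups = build_merge_groups(bics)
        assert len(groups) == 2 and all(len(g.members) == 1 for g in groups)

    def test_same_conditions_disjoint_genes_stay_apart(self):
        bics = [_bic("abc", "xy"), _bic("def", "xy")]
        groups = build_merge_groups(bics)
        assert len(groups) == 2

    def test_gene_overlap_is_transitive(self):
        a = _bic("abc", "xy")
        b = _bic("cde", "xy")
        c = _bic("efg", "xy")
        groups = build_merge_groups([a, b, c])
        assert len(groups) == 1 and len(groups[0].members) == 3
        assert groups[0].union_genes == frozenset("abcdefg")


class TestLargestFeasiblePrefix:
    @pytest.mark.parametrize("n,k_star", [(0, 0), (1, 0), (1, 1), (7, 3), (10, 10), (13, 0)])
    def test_equals_scan_for_monotone_predicates(self, n, k_star):
        feasible = lambda k: k <= k_star
        assert largest_feasible_prefix(feasible, n) == k_star
        assert largest_feasible_prefix_by_scan(feasible, n) == k_star

    def test_returns_feasible_value_even_if_non_monotone(self):
        # feasible at 0,1,2 and again at 5 only
        feasible = lambda k: k <= 2 or k == 5
        k = largest_feasible_prefix(feasible, 6)
        assert feasible(k)


@pytest.fixture(scope="module")
def block_setup():
    matrix, truth = generate(single_block_spec(seed=21))
    params = PipelineParams(min_row=5, min_col=3, bins=7, sd_coeff=0.7,
                            alpha=0.05, n_perm=500, search_n_perm=500, seed=21)
    cache = NullCache(matrix, base_seed=params.seed)
    return matrix, truth[0], params, cache


class TestMergeGroup:
    def _split_block(self, truth):
        genes = sorted(truth.genes)
        left = Bicluster(frozenset(genes[:10]), truth.conditions)
        right = Bicluster(frozenset(genes[5:]), truth.conditions)
        return left, right

    def test_singleton_group_returned_unchanged(self, block_setup):
        matrix, truth, params, cache = block_setup
        b = _bic("abc", "xy", p=0.02)
        group = build_merge_groups([b])[0]
        assert merge_group(group, matrix, params, cache) is b

    def test_split_block_reassembled(self, block_setup):
        matrix, truth, params, cache = block_setup
        left, right = self._split_block(truth)
        score_biclusters([left, right], matrix, params.n_perm, cache)
        group = build_merge_groups([left, right])[0]
        merged = merge_group(group, matrix, params, cache)
        assert merged.genes == truth.genes
        assert merged.p_value <= params.alpha

    def test_binary_search_agrees_with_scan_when_monotone(self, block_setup):
        matrix, truth, params, cache = block_setup
        left, right = self._split_block(truth)
        score_biclusters([left, right], matrix, params.n_perm, cache)
        group = build_merge_groups([left, right])[0]
        seed = min(group.members, key=lambda b: b.p_value)
        candidates = sorted(group.union_genes - seed.genes)

        from bicnet.significance import empirical_pvalue

        def feasible(k):
            if k == 0:
                return True
            b = Bicluster(seed.genes | frozenset(candidates[:k]), group.conditions)
            return empirical_pvalue(b, matrix, params.n_perm, cache) <= params.alpha

        flags = [feasible(k) for k in range(len(candidates) + 1)]
        if all(a >= b for a, b in zip(flags, flags[1:])):  # monotone
            assert largest_feasible_prefix(feasible, len(candidates)) == \
                largest_feasible_prefix_by_scan(feasible, len(candidates))


class TestMergeAll:
    def test_unrelated_biclusters_pass_through(self, noise_matrix):
        params = PipelineParams(min_row=3, min_col=2, n_perm=200, seed=1)
        cache = NullCache(noise_matrix, base_seed=1)
        bics = [
            Bicluster(frozenset(noise_matrix.gene_ids[:5]), frozenset(noise_matrix.condition_ids[:3])),
            Bicluster(frozenset(noise_matrix.gene_ids[50:55]), frozenset(noise_matrix.condition_ids[5:8])),
        ]
        score_biclusters(bics, noise_matrix, params.n_perm, cache)
        merged = merge_all(bics, noise_matrix, params, cache)
        assert {(b.genes, b.conditions) for b in merged} == {(b.genes, b.conditions) for b in bics}

    def test_many_overlapping_fragments_collapse_to_one(self):
        matrix, truth = generate(single_block_spec(seed=9))
        t = truth[0]
        genes = sorted(t.genes)
        params = PipelineParams(min_row=5, min_col=3, n_perm=500, search_n_perm=500, seed=9)
        cache = NullCache(matrix, base_seed=9)
        fragments = [
            Bicluster(frozenset(genes[i:i + 6]), t.conditions)
            for i in range(0, 10)
        ]
        score_biclusters(fragments, matrix, params.n_perm, cache)
        merged = merge_all(fragments, matrix, params, cache)
        assert len(merged) == 1
        assert merged[0].genes == t.genes
        assert merged[0].p_value <= params.alpha

    def test_idempotent_and_contracting(self):
        matrix, truth = generate(single_block_spec(seed=5))
        t = truth[0]
        genes = sorted(t.genes)
        params = PipelineParams(min_row=5, min_col=3, n_perm=500, search_n_perm=500, seed=5)
        cache = NullCache(matrix, base_seed=5)
        bics = [
            Bicluster(frozenset(genes[:10]), t.conditions),
            Bicluster(frozenset(genes[5:]), t.conditions),
            Bicluster(frozenset(genes[:8]), frozenset(sorted(t.conditions)[:3])),
        ]
        score_biclusters(bics, matrix, params.n_perm, cache)
        once = merge_all(bics, matrix, params, cache)
        assert len(once) <= len(bics)
        assert all(b.p_value <= params.alpha for b in once)
        twice = merge_all(once, matrix, params, cache)
        assert [(b.genes, b.conditions) for b in twice] == [(b.genes, b.conditions) for b in once]
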