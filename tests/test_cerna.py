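import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amcen import (bh_fdr, classify_differential, coexpression_filter,
                   enumerate_pairs, expand_triples, intersect_aberrant,
                   make_table, match_dmg_mirna, restrict_to_curated,
                   two_group_t)
from amcen.cerna import CeRNAPair, CeRNATriple, assemble_triples

from conftest import make_matrix
from oracles import bh_stepup


def _pair(mrna="G", lncrna="L", shared=("mir-a",), n=None, m=None, N=10):
    x = len(shared)
    return CeRNAPair(mrna=mrna, lncrna=lncrna, N=N, n=n or x, m=m or x, x=x,
                     shared_mirnas=frozenset(shared), p_hyper=0.01)


class TestBH:
    def test_singleton_identity(self):
        assert bh_fdr([0.05]).tolist() == [0.05]

    def test_constant_vector_unchanged(self):
        assert bh_fdr([0.3] * 5) == pytest.approx([0.3] * 5)

    def test_matches_stepup_oracle_on_worked_vector(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205]
        assert bh_fdr(p) == pytest.approx(bh_stepup(p), abs=1e-12)

    @settings(derandomize=True, max_examples=150)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_oracle_and_dominates_input(self, p):
        adj = bh_fdr(p)
        assert adj == pytest.approx(bh_stepup(p), abs=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_empty_and_invalid(self):
        assert bh_fdr([]).size == 0
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestMatchDmgMirna:
    table = make_table([("G1", "miR-a"), ("G2", "miR-b")], "mrna-mirna")

    def test_filters_to_gene_set(self):
        sub = match_dmg_mirna({"G1"}, self.table)
        assert sub.edges == {("G1", "mir-a")}
        assert len(sub.targets()) == 1  # the universe N

    def test_disjoint_genes_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            sub = match_dmg_mirna({"G9"}, self.table)
        assert len(sub) == 0 and "empty" in caplog.text

    def test_wrong_table_kind_rejected(self):
        ppi = make_table([("A", "B")], "ppi")
        with pytest.raises(ValueError, match="mrna-mirna"):
            match_dmg_mirna({"A"}, ppi)

    def test_planted_edges_survive(self, default_dataset):
        ds = default_dataset
        genes = {t[0] for t in ds.truth.true_triples}
        sub = match_dmg_mirna(genes, ds.mrna_mirna)
        for g, mi, _ in ds.truth.true_triples:
            assert (g, mi) in sub.edges


class TestCoexpression:
    def test_perfect_linearity(self):
        mrna = make_matrix([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]], ["G"])
        lnc = make_matrix([[2.0, 4.0, 6.0]], [[8.0, 10.0, 12.0]], ["L"])
        (kept,) = coexpression_filter([_pair()], mrna, lnc)
        assert kept.pcc == pytest.approx(1.0)
        assert kept.fdr == pytest.approx(0.0, abs=1e-12)

    def test_pcc_threshold_is_strict(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(size=12)
        mrna = make_matrix([x[:6]], [x[6:]], ["G"])
        lnc = make_matrix([y[:6]], [y[6:]], ["L"])
        r = float(np.corrcoef(x, y)[0, 1])
        # a pair sitting exactly on the threshold is rejected (strict >)
        assert coexpression_filter([_pair()], mrna, lnc, pcc_threshold=r,
                                   fdr_threshold=1.0) == []
        kept = coexpression_filter([_pair()], mrna, lnc,
                                   pcc_threshold=r - 1e-9, fdr_threshold=1.0)
        assert len(kept) == 1 and kept[0].pcc == pytest.approx(r)

    def test_bh_over_four_pairs(self):
        # four pairs whose correlation p-values adjust to a common 0.04-style
        # plateau: all fdrs equal max(p) * 4 / 4 ... = the BH oracle values
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 20))
        noise = rng.normal(size=(4, 20))
        y = np.stack([0.9 * (xi - xi.mean()) / xi.std() + 0.4 * ni
                      for xi, ni in zip(x, noise)])
        mrna = make_matrix(x[:, :10], x[:, 10:], [f"G{i}" for i in range(4)])
        lnc = make_matrix(y[:, :10], y[:, 10:], [f"L{i}" for i in range(4)])
        pairs = [_pair(f"G{i}", f"L{i}") for i in range(4)]
        kept = coexpression_filter(pairs, mrna, lnc, pcc_threshold=-1.0,
                                   fdr_threshold=1.1)
        assert [k.fdr for k in kept] == pytest.approx(
            bh_stepup([k.p_corr for k in kept]), abs=1e-12)

    def test_missing_or_flat_profiles_dropped(self, caplog):
        mrna = make_matrix([[1, 2, 3], [5, 5, 5]], [[4, 5, 6], [5, 5, 5]],
                           ["G", "FLAT"])
        lnc = make_matrix([[1, 2, 3]], [[4, 5, 6]], ["L"])
        pairs = [_pair("G", "L"), _pair("FLAT", "L"), _pair("G", "MISSING")]
        with caplog.at_level("WARNING"):
            kept = coexpression_filter(pairs, mrna, lnc)
        assert [(k.mrna, k.lncrna) for k in kept] == [("G", "L")]
        assert "zero-variance" in caplog.text and "absent" in caplog.text


class TestTriples:
    def test_zero_shared_pairs_never_enumerated(self):
        mm = make_table([("G1", "miR-a")], "mrna-mirna")
        ml = make_table([("miR-b", "L1")], "mirna-lncrna")
        assert enumerate_pairs(match_dmg_mirna({"G1"}, mm), ml) == []

    def test_expansion_identity(self):
        pairs = [_pair("G1", "L1", ("mir-a", "mir-b"), n=3, m=2),
                 _pair("G2", "L2", ("mir-c",), n=2, m=1)]
        triples = expand_triples(pairs)
        assert len(triples) == sum(p.x for p in pairs)
        assert all(t.mirna in t.parent_pair.shared_mirnas for t in triples)

    def test_reported_edges_exist_in_inputs(self, default_dataset):
        ds = default_dataset
        genes = ds.truth.true_hyperlow | ds.truth.true_hypohigh
        sub = match_dmg_mirna(genes, ds.mrna_mirna)
        triples = assemble_triples(sub, ds.mirna_lncrna, ds.expression,
                                   ds.lnc_expression)
        for t in triples:
            assert (t.mrna, t.mirna) in ds.mrna_mirna.edges
            assert (t.mirna, t.lncrna) in ds.mirna_lncrna.edges

    def test_planted_triples_recovered(self, default_dataset):
        ds = default_dataset
        expr_calls = classify_differential(two_group_t(ds.expression),
                                           mode="expression")
        meth_calls = classify_differential(two_group_t(ds.methylation),
                                           mode="methylation")
        aberrant = intersect_aberrant(expr_calls, meth_calls)
        reported = set()
        for genes in (aberrant.hyper_low, aberrant.hypo_high):
            sub = match_dmg_mirna(set(genes), ds.mrna_mirna)
            for t in assemble_triples(sub, ds.mirna_lncrna, ds.expression,
                                      ds.lnc_expression):
                reported.add((t.mrna, t.mirna, t.lncrna))
        truth = set(ds.truth.true_triples)
        assert len(truth & reported) >= 0.8 * len(truth)
        assert len(reported - truth) <= 0.2 * max(1, len(reported))


class TestCurated:
    def test_prefix_normalization(self):
        t = CeRNATriple("G", "mir-30a", "L",
                        _pair("G", "L", ("mir-30a",)))
        kept = restrict_to_curated([t], ["miR-30a"])
        assert len(kept) == 1 and kept[0].curated

    def test_full_list_is_identity_and_restriction_shrinks(self):
        pairs = _pair("G", "L", ("mir-1", "mir-2"), n=2, m=2)
        triples = expand_triples([pairs])
        assert len(restrict_to_curated(triples, ["hsa-miR-1", "hsa-miR-2"])) == 2
        assert len(restrict_to_curated(triples, ["hsa-miR-1"])) == 1

    def test_empty_curated_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            restrict_to_curated([], [])


def test_pair_invariant_enforced():
    with pytest.raises(ValueError, match="min"):
        CeRNAPair("G", "L", N=5, n=2, m=3, x=4,
                  shared_mirnas=frozenset(["a", "b", "c", "d"]), p_hyper=0.1)
    with pytest.raises(ValueError, match="members"):
        CeRNAPair("G", "L", N=5, n=2, m=3, x=2,
                  shared_mirnas=frozenset(["a"]), p_hyper=0.1)
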