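"""Component-network builders against independent oracles."""

import math

import numpy as np
import pytest

from funlink.builders import (
    BlastHit,
    DomainAssignment,
    ExpressionMatrix,
    build_coexpression,
    build_domain,
    build_homology,
    build_interolog,
    combine_expression,
    transfer_annotations,
)
from funlink.netcore import EvidenceNetwork, OrthologMap
from funlink.simdata import simulate_blast_hits


def pearson_oracle(x, y):
    """Textbook Pearson r over pairwise-complete observations."""
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 2:
        return np.nan
    dx, dy = x - x.mean(), y - y.mean()
    denom = math.sqrt((dx**2).sum() * (dy**2).sum())
    return np.nan if denom == 0 else float((dx * dy).sum() / denom)


class TestCombineExpression:
    def test_single_experiment_is_row_zscore(self):
        values = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 8.0]])
        exp = ExpressionMatrix("e1", ["g1", "g2"], ["s1", "s2", "s3"], values)
        out = combine_expression([exp])
        for i in range(2):
            row = values[i]
            expected = (row - row.mean()) / row.std()
            np.testing.assert_allclose(out.values[i], expected)

    def test_gene_absent_from_one_experiment_gets_missing_block(self):
        e1 = ExpressionMatrix("e1", ["g1", "g2"], ["a", "b", "c"],
                              np.arange(6.0).reshape(2, 3))
        e2 = ExpressionMatrix("e2", ["g1"], ["d", "e"], np.array([[1.0, 2.0]]))
        out = combine_expression([e1, e2])
        row_g2 = out.values[out.genes.index("g2")]
        assert np.isnan(row_g2[3:]).all() and not np.isnan(row_g2[:3]).any()
        assert out.samples == ["e1:a", "e1:b", "e1:c", "e2:d", "e2:e"]

    def test_constant_row_excluded(self):
        exp = ExpressionMatrix("e1", ["flat", "g"], ["a", "b", "c"],
                               np.array([[2.0, 2.0, 2.0], [1.0, 2.0, 4.0]]))
        out = combine_expression([exp])
        assert out.genes == ["g"]

    def test_de_gene_filter_and_empty_error(self):
        exp = ExpressionMatrix("e1", ["g1", "g2"], ["a", "b"],
                               np.array([[1.0, 2.0], [3.0, 1.0]]))
        out = combine_expression([exp], de_genes={"g2"})
        assert out.genes == ["g2"]
        with pytest.raises(ValueError, match="usable"):
            combine_expression([exp], de_genes={"absent"})


class TestCoexpression:
    def test_identical_rows_give_r_one(self):
        exp = ExpressionMatrix("e", ["a", "b"], list("stu"),
                               np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        net = build_coexpression(exp, threshold=0.7)
        assert net.score("a", "b") == pytest.approx(1.0)

    def test_negative_correlation_makes_no_edge(self):
        exp = ExpressionMatrix("e", ["a", "b"], list("stuv"),
                               np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.1, 1.0]]))
        assert pearson_oracle(exp.values[0], exp.values[1]) < -0.9
        net = build_coexpression(exp, threshold=0.7)
        assert len(net) == 0

    def test_three_gene_worked_example(self):
        values = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0001], [3.0, 1.0, 2.0]])
        exp = ExpressionMatrix("e", ["a", "b", "c"], list("stu"), values)
        net = build_coexpression(exp, threshold=0.7)
        assert net.has_edge("a", "b") and len(net) == 1

    def test_agrees_with_bruteforce_oracle(self, rng):
        values = rng.standard_normal((20, 10))
        values[rng.random((20, 10)) < 0.1] = np.nan  # pairwise-complete path
        genes = [f"g{i:02d}" for i in range(20)]
        exp = ExpressionMatrix("e", genes, [f"s{j}" for j in range(10)], values)
        net = build_coexpression(exp, threshold=0.3, min_pairs=3)
        for i in range(20):
            for j in range(i + 1, 20):
                r = pearson_oracle(values[i], values[j])
                n_shared = int((~(np.isnan(values[i]) | np.isnan(values[j]))).sum())
                if n_shared >= 3 and not np.isnan(r) and r >= 0.3:
                    assert net.score(genes[i], genes[j]) == pytest.approx(r, abs=1e-10)
                else:
                    assert not net.has_edge(genes[i], genes[j])

    def test_needs_two_genes(self):
        exp = ExpressionMatrix("e", ["a"], ["s", "t"], np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            build_coexpression(exp)


class TestHomology:
    LENGTHS = {"q": 100, "s": 120}

    def make_hit(self, **kw):
        base = dict(query="q", subject="s", pident=50.0, align_len=60, evalue=1e-6)
        base.update(kw)
        return BlastHit(**base)

    def test_passing_hit_scores_neg_log10_evalue(self):
        net = build_homology([self.make_hit()], self.LENGTHS)
        assert net.score("q", "s") == pytest.approx(6.0)

    @pytest.mark.parametrize(
        "kw",
        [dict(evalue=1e-3), dict(align_len=40), dict(pident=39.0)],
        ids=["evalue", "coverage", "similarity"],
    )
    def test_each_filter_rejects(self, kw):
        assert len(build_homology([self.make_hit(**kw)], self.LENGTHS)) == 0

    def test_boundary_evalue_is_strict(self):
        assert len(build_homology([self.make_hit(evalue=1e-4)], self.LENGTHS)) == 0

    def test_reciprocal_hits_collapse_to_max(self):
        hits = [self.make_hit(evalue=1e-6),
                self.make_hit(query="s", subject="q", evalue=1e-8)]
        net = build_homology(hits, self.LENGTHS)
        assert len(net) == 1 and net.score("q", "s") == pytest.approx(8.0)

    def test_zero_evalue_clamps_to_180(self):
        net = build_homology([self.make_hit(evalue=0.0)], self.LENGTHS)
        assert net.score("q", "s") == pytest.approx(180.0)

    def test_missing_query_length_raises(self):
        with pytest.raises(KeyError):
            build_homology([self.make_hit()], {"other": 10})

    def test_edge_count_matches_independent_filter_on_random_hits(self):
        sim = simulate_blast_hits(n_proteins=80, n_true_pairs=500, seed=7)
        net = build_homology(sim.hits, sim.query_lengths)
        # independent row-by-row re-implementation of the three filters
        kept = set()
        for h in sim.hits:
            qlen = sim.query_lengths[h.query]
            if (h.align_len / qlen >= 0.5 and h.pident >= 40.0 and h.evalue < 1e-4
                    and h.query != h.subject):
                kept.add(tuple(sorted((h.query, h.subject))))
        assert len(net) == len(kept)
        assert {(u, v) for u, v, _ in net.edges()} == kept


class TestDomain:
    def test_shared_domain_count_is_score(self):
        assign = DomainAssignment({"p1": {"D1", "D2", "D3"}, "p2": {"D2", "D3"}})
        net = build_domain(assign)
        assert net.score("p1", "p2") == 2.0

    def test_disjoint_sets_no_edge(self):
        net = build_domain(DomainAssignment({"p1": {"D1"}, "p2": {"D2"}}))
        assert len(net) == 0

    def test_common_domain_makes_triangle(self):
        net = build_domain(DomainAssignment({"a": {"D1"}, "b": {"D1"}, "c": {"D1", "D2"}}))
        assert len(net) == 3
        for u, v, s in net.edges():
            assert s >= 1

    def test_scores_equal_intersection_sizes_random(self, rng):
        domains = [f"D{i}" for i in range(8)]
        assign = DomainAssignment()
        entries = {}
        for i in range(15):
            picked = {d for d in domains if rng.random() < 0.4} or {domains[0]}
            entries[f"p{i:02d}"] = picked
            for d in picked:
                assign.add(f"p{i:02d}", d)
        net = build_domain(assign)
        for u, v, s in net.edges():
            assert s == len(entries[u] & entries[v])
        for p, q in [("p00", "p01"), ("p03", "p09")]:
            if not net.has_edge(p, q):
                assert not (entries[p] & entries[q])


class TestInterolog:
    def donor(self):
        net = EvidenceNetwork(source_id="humannet")
        net.add_edge("H1", "H2", 0.9)
        return net

    def test_one_to_one_transfer(self):
        omap = OrthologMap("human", {("H1", "b1"), ("H2", "b2")})
        net = build_interolog(self.donor(), omap)
        assert len(net) == 1 and net.score("b1", "b2") == 0.9

    def test_unmapped_endpoint_skipped(self):
        omap = OrthologMap("human", {("H1", "b1")})
        assert len(build_interolog(self.donor(), omap)) == 0

    def test_many_to_many_enumerates_all_pairs(self, rng):
        # brute-force oracle over ortholog pair combinations
        donor = EvidenceNetwork(source_id="d")
        for _ in range(30):
            i, j = rng.choice(10, size=2, replace=False)
            donor.add_edge(f"H{i}", f"H{j}", float(rng.uniform(0, 1)))
        omap = OrthologMap("human")
        for i in range(10):
            for t in rng.choice(12, size=int(rng.integers(0, 3)), replace=False):
                omap.add_pair(f"H{i}", f"b{t}")
        mapping = omap.donor_to_targets()
        expected = {}
        for a_d, b_d, s in donor.edges():
            for a in mapping.get(a_d, set()):
                for b in mapping.get(b_d, set()):
                    if a != b:
                        key = tuple(sorted((a, b)))
                        expected[key] = max(expected.get(key, -1), s)
        net = build_interolog(donor, omap)
        assert {(u, v): s for u, v, s in net.edges()} == expected

    def test_paralog_expansion(self):
        omap = OrthologMap("human", {("H1", "b1"), ("H1", "b1x"), ("H2", "b2")})
        net = build_interolog(self.donor(), omap)
        assert net.score("b1", "b2") == 0.9 and net.score("b1x", "b2") == 0.9


class TestTransferAnnotations:
    def test_fills_only_unannotated(self):
        ann = {"b2": {"GO:1"}}
        donor = ({"H1": {"GO:8150"}, "H2": {"GO:2"}},
                 OrthologMap("human", {("H1", "b1"), ("H2", "b2")}))
        out = transfer_annotations(ann, [donor])
        assert out["b1"] == {"GO:8150"}
        assert out["b2"] == {"GO:1"}  # annotated gene untouched

    def test_merge_flag_unions(self):
        ann = {"b2": {"GO:1"}}
        donor = ({"H2": {"GO:2"}}, OrthologMap("human", {("H2", "b2")}))
        out = transfer_annotations(ann, [donor], merge_annotated=True)
        assert out["b2"] == {"GO:1", "GO:2"}

    def test_gene_without_ortholog_stays_absent(self):
        out = transfer_annotations({}, [({"H1": {"GO:1"}}, OrthologMap("h", {("H1", "b1")}))])
        assert "b9" not in out

    def test_never_shrinks_term_sets(self, rng):
        genes = [f"b{i}" for i in range(20)]
        ann = {g: {f"GO:{int(t)}" for t in rng.integers(0, 9, size=rng.integers(1, 4))}
               for g in genes if rng.random() < 0.5}
        omap = OrthologMap("h")
        donor_ann = {}
        for i in range(15):
            omap.add_pair(f"H{i}", genes[int(rng.integers(0, 20))])
            donor_ann[f"H{i}"] = {f"GO:d{int(rng.integers(0, 5))}"}
        out = transfer_annotations(ann, [(donor_ann, omap)])
        for g, terms in ann.items():
            assert out[g] == terms
        for g in out:
            assert out[g] >= ann.get(g, set())
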