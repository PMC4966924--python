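import numpy as np
import pytest

import protasr as pa
from protasr.ancestral import (AncestralError, AncestralPosterior,
                               indel_change_count, leaf_posterior,
                               ml_sequence, place_indels, sample_sequences,
                               support_summary, map_to_extant)
from protasr.likelihood import TreeLikelihood

from oracles import enumeration_posterior, min_indel_changes, random_instance


def _fit(aln, tree, model):
    return TreeLikelihood(aln, tree, model).fit(optimize=())


def _make_posterior(probs, present=None, node_id=9):
    probs = np.asarray(probs, dtype=float)
    if present is None:
        present = np.ones(len(probs), dtype=bool)
    return AncestralPosterior(
        node_id=node_id, clade=frozenset({"A", "B"}), probs=probs,
        rate_weights=np.ones((len(probs), 1)),
        indel_present=np.asarray(present, dtype=bool))


def _vec(**kw):
    v = np.zeros(20)
    for aa, p in kw.items():
        v[pa.AMINO_ACIDS.index(aa)] = p
    return v


class TestMarginalPosteriors:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(12):
            aln, tree, model = random_instance(rng, n_taxa=4)
            rooted = tree.rooted_on_edge(tree.edges()[0].node_id)
            rec = _fit(aln, rooted, model).ancestral_posteriors()
            for node in rooted.base.postorder():
                if node.is_leaf:
                    continue
                oracle = enumeration_posterior(aln, rooted, model, node)
                got = rec[node.node_id].probs
                assert np.abs(got - oracle).max() < 1e-10
                assert np.abs(got.sum(axis=1) - 1).max() < 1e-9

    def test_equilibrium_limit_long_branches(self):
        aln = pa.Alignment(list("ABCD"), ["MKLV", "AWCD", "PQRS", "GHIE"])
        tree = pa.read_newick(
            "((A:1e6,B:1e6):1e6,C:1e6,D:1e6);").rooted_on_edge(1)
        m = pa.build_model("LG")
        rec = _fit(aln, tree, m).ancestral_posteriors()
        for nid in rec.node_ids():
            assert np.abs(rec[nid].probs - m.pi[None, :]).max() < 1e-6

    def test_consensus_limit_short_branches(self):
        aln = pa.Alignment(list("ABCD"), ["K", "K", "K", "K"])
        tree = pa.read_newick(
            "((A:0.01,B:0.01):0.01,C:0.01,D:0.01);").rooted_on_edge(1)
        rec = _fit(aln, tree, pa.build_model("LG")).ancestral_posteriors()
        k = pa.AMINO_ACIDS.index("K")
        for nid in rec.node_ids():
            assert rec[nid].probs[0, k] > 0.99

    def test_unrooted_without_outgroup_rejected(self, six_taxon_unrooted):
        sim = pa.simulate_evolution(pa.SimulationSpec(
            tree=six_taxon_unrooted, seq_length=30, model="LG", seed=0))
        res = _fit(sim.alignment, six_taxon_unrooted, pa.build_model("LG"))
        with pytest.raises(AncestralError, match="outgroup"):
            res.ancestral_posteriors()

    def test_outgroup_roots_automatically(self, six_taxon_unrooted):
        sim = pa.simulate_evolution(pa.SimulationSpec(
            tree=six_taxon_unrooted, seq_length=30, model="LG", seed=0))
        res = _fit(sim.alignment, six_taxon_unrooted, pa.build_model("LG"))
        rec = res.ancestral_posteriors(outgroup={"A", "B"})
        assert rec.tree.rooted
        assert len(rec.node_ids()) == 5  # 6-leaf rooted: 5 internal nodes


class TestMlSequence:
    def test_argmax_and_support(self):
        post = _make_posterior([_vec(A=0.7, G=0.3)] * 3)
        seq = ml_sequence(post)
        assert seq.residues == "AAA"
        assert np.allclose(seq.support, 0.7)
        assert not seq.ties.any()

    def test_exact_tie_alphabetical_flagged(self):
        post = _make_posterior([_vec(A=0.5, C=0.5)])
        seq = ml_sequence(post)
        assert seq.residues == "A"
        assert seq.ties[0]

    def test_indel_absent_emits_gap(self):
        post = _make_posterior([_vec(K=1.0), _vec(K=1.0)],
                               present=[True, False])
        seq = ml_sequence(post)
        assert seq.residues == "K-"
        assert np.isnan(seq.support[1])


class TestSampling:
    def test_point_mass_equals_ml(self):
        post = _make_posterior([_vec(W=1.0)] * 5)
        samples = sample_sequences(post, 3, seed=1)
        assert all(s.residues == "WWWWW" for s in samples)

    def test_same_seed_reproducible(self):
        post = _make_posterior([_vec(A=0.6, G=0.4)] * 10)
        a = [s.residues for s in sample_sequences(post, 5, seed=42)]
        b = [s.residues for s in sample_sequences(post, 5, seed=42)]
        assert a == b

    def test_frequencies_match_posterior(self):
        post = _make_posterior([_vec(A=0.8, G=0.2)])
        samples = sample_sequences(post, 10000, seed=7)
        freq_g = np.mean([s.residues == "G" for s in samples])
        assert abs(freq_g - 0.2) < 0.012  # 3 sigma binomial


class TestPlaceIndels:
    def test_all_gapped_column_absent_everywhere(self, six_taxon_rooted):
        aln = pa.Alignment(list("ABCDEF"), ["-K"] * 6)
        states = place_indels(aln, six_taxon_rooted)
        for nid, st in states.items():
            assert not st[0] and st[1]

    def test_single_gap_keeps_ancestors_present(self, six_taxon_rooted):
        rows = ["K", "K", "K", "K", "K", "-"]
        aln = pa.Alignment(list("ABCDEF"), rows)
        states = place_indels(aln, six_taxon_rooted)
        internal_ids = {n.node_id for n in six_taxon_rooted.base.postorder()
                        if not n.is_leaf}
        for nid in internal_ids:
            assert states[nid][0]

    def test_change_count_is_minimal(self, six_taxon_rooted):
        rng = np.random.default_rng(17)
        taxa = list("ABCDEF")
        for _ in range(40):
            pattern = rng.random(6) < 0.5
            if not pattern.any():
                pattern[0] = True
            aln = pa.Alignment(taxa, ["K" if p else "-" for p in pattern])
            states = place_indels(aln, six_taxon_rooted)
            got = indel_change_count(six_taxon_rooted, states)[0]
            oracle = min_indel_changes(
                six_taxon_rooted, dict(zip(taxa, pattern)))
            assert got == oracle

    def test_deterministic(self, six_taxon_rooted):
        aln = pa.Alignment(list("ABCDEF"),
                           ["K-", "KK", "-K", "K-", "--", "KK"])
        a = place_indels(aln, six_taxon_rooted)
        b = place_indels(aln, six_taxon_rooted)
        for nid in a:
            assert (a[nid] == b[nid]).all()


class TestSupportSummary:
    def test_certain_columns_fill_top_bin(self):
        post = _make_posterior([_vec(A=1.0)] * 7)
        s = support_summary(post)
        assert s.histogram.tolist() == [0] * 9 + [7]

    def test_counts_sum_to_non_indel_columns(self):
        probs = [_vec(A=0.55, G=0.45), _vec(K=0.91, R=0.09), _vec(W=1.0)]
        post = _make_posterior(probs, present=[True, False, True])
        s = support_summary(post)
        assert s.histogram.sum() == 2

    def test_traces_ordered(self):
        rng = np.random.default_rng(5)
        raw = rng.dirichlet(np.ones(20), size=30)
        post = _make_posterior(raw)
        s = support_summary(post)
        assert (s.best >= s.second).all() and (s.second >= s.third).all()


class TestMapToExtant:
    def test_identity_numbering_when_ungapped(self):
        post = _make_posterior([_vec(K=1.0)] * 4)
        anc = ml_sequence(post)
        aln = pa.Alignment(["hum", "oth"], ["KKKK", "KKKK"])
        table = map_to_extant(anc, post, "hum", aln)
        assert table.anc_site.tolist() == [1, 2, 3, 4]
        assert table.extant_site.tolist() == [1, 2, 3, 4]

    def test_gap_rows_have_no_index(self):
        post = _make_posterior([_vec(K=1.0)] * 5)
        anc = ml_sequence(post)
        aln = pa.Alignment(["hum", "oth"], ["KK-KK", "KKKKK"])
        table = map_to_extant(anc, post, "hum", aln)
        assert table.extant_state.tolist() == ["K", "K", "-", "K", "K"]
        assert table.extant_site.fillna(0).tolist() == [1, 2, 0, 3, 4]

    def test_offsets_match_hand_enumeration(self):
        # ancestor gapped at columns 2,3; extant gapped at column 5
        post = _make_posterior([_vec(R=1.0)] * 6,
                               present=[1, 0, 0, 1, 1, 1])
        anc = ml_sequence(post)
        aln = pa.Alignment(["hum", "oth"], ["RRRR-R", "RRRRRR"])
        table = map_to_extant(anc, post, "hum", aln)
        assert table.anc_site.fillna(0).tolist() == [1, 0, 0, 2, 3, 4]
        assert table.extant_site.fillna(0).tolist() == [1, 2, 3, 4, 0, 5]
        assert table.anc_state.tolist() == ["R", "-", "-", "R", "R", "R"]

    def test_unknown_taxon_rejected(self):
        post = _make_posterior([_vec(K=1.0)])
        anc = ml_sequence(post)
        aln = pa.Alignment(["x", "y"], ["K", "K"])
        with pytest.raises(AncestralError):
            map_to_extant(anc, post, "nope", aln)


class TestRecoveryProperties:
    def test_root_recovery_and_support_correlation(self, six_taxon_rooted):
        # simulate, refit, reconstruct; accuracy should be high and the
        # ML-residue posterior should rank correct sites above wrong ones
        sim = pa.simulate_evolution(pa.SimulationSpec(
            tree=six_taxon_rooted, seq_length=400, model="LG", seed=21,
            deletion_rate=0.01))
        res = TreeLikelihood(sim.alignment, sim.tree,
                             pa.build_model("LG")).fit()
        rec = res.ancestral_posteriors()
        root_id = sim.tree.base.node_id
        truth = sim.ancestors[root_id]
        seq = rec.ml_sequences()[root_id]
        correct, supports = [], []
        for i, (a, b) in enumerate(zip(seq.residues, truth)):
            if b == "-" or a == "-":
                continue
            correct.append(a == b)
            supports.append(seq.support[i])
        assert np.mean(correct) >= 0.85
        from scipy.stats import spearmanr
        rho, _ = spearmanr(supports, np.array(correct, dtype=float))
        assert rho > 0


class TestLeafPosterior:
    def test_point_mass_and_gaps(self):
        aln = pa.Alignment(["x", "y"], ["K-X", "KKK"])
        post = leaf_posterior(aln, "x", node_id=1)
        assert post.probs[0, pa.AMINO_ACIDS.index("K")] == 1.0
        assert not post.indel_present[1]
        assert post.indel_present[2]  # X is present but uninformative
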