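import numpy as np
import pytest

import protasr as pa
from protasr.ancestral import leaf_posterior, ml_sequence
from protasr.likelihood import TreeLikelihood
from protasr.robustness import (RobustnessError, RobustnessGrid,
                                branch_path_mutations, diff_ancestors,
                                map_node, robustness_report,
                                root_by_outgroup)


class TestRootByOutgroup:
    def test_root_bisects_central_edge(self):
        t = pa.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_by_outgroup(t, {"A", "B"})
        assert rooted.rooted
        clades = set(rooted.clades().values())
        assert frozenset({"C", "D"}) in clades
        # the split edge (length 2 after unrooting) is bisected
        lens = sorted(n.length for n in rooted.base.children)
        assert lens == [1.0, 1.0]

    def test_single_taxon_outgroup_on_pendant_edge(self):
        t = pa.read_newick("((A:1,B:1):1,C:1,D:1);")
        rooted = root_by_outgroup(t, {"A"})
        og, rest = sorted(rooted.base.children,
                          key=lambda n: len(n.leaves()))
        assert og.name == "A" and og.length == pytest.approx(0.5)

    def test_non_monophyletic_outgroup_reports_split(self):
        t = pa.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(RobustnessError, match="not monophyletic"):
            root_by_outgroup(t, {"A", "C"})

    def test_whole_taxa_outgroup_rejected(self):
        t = pa.read_newick("((A:1,B:1):1,C:1,D:1);")
        with pytest.raises(RobustnessError):
            root_by_outgroup(t, {"A", "B", "C", "D"})
        with pytest.raises(RobustnessError):
            root_by_outgroup(t, set())

    def test_unrooting_recovers_topology(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            t = pa.random_topology([f"t{i}" for i in range(6)], r)
            leaf = t.leaf_names[int(r.integers(6))]
            rooted = root_by_outgroup(t, {leaf})
            assert pa.same_topology(rooted.unrooted(), t)


class TestMapNode:
    def test_identical_topologies_all_exist(self):
        t1 = root_by_outgroup(
            pa.read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);"), {"E"})
        t2 = root_by_outgroup(
            pa.read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);"), {"E"})
        for clade in t1.clades().values():
            matches = map_node(clade, {"x": t2})
            assert matches["x"] is not None

    def test_discordant_grouping_absent(self):
        # one tree groups (human,mouse,chicken); the other groups
        # (chicken,frog) so that ancestor does not exist there
        t1 = root_by_outgroup(pa.read_newick(
            "(((human:1,mouse:1):1,chicken:1):1,frog:1,fish:1);"), {"fish"})
        t2 = root_by_outgroup(pa.read_newick(
            "((human:1,mouse:1):1,(chicken:1,frog:1):1,fish:1);"), {"fish"})
        target = frozenset({"human", "mouse", "chicken"})
        assert target in t1.clades().values()
        matches = map_node(target, {"t2": t2})
        assert matches["t2"] is None

    def test_leaf_always_matches(self):
        t2 = root_by_outgroup(
            pa.read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);"), {"E"})
        assert map_node({"C"}, {"x": t2})["x"] == t2.node_by_name("C").node_id

    def test_agrees_with_brute_force_clade_check(self):
        rng = np.random.default_rng(23)
        taxa = [f"t{i}" for i in range(6)]
        for _ in range(20):
            a = root_by_outgroup(pa.random_topology(taxa, rng), {taxa[0]})
            b = root_by_outgroup(pa.random_topology(taxa, rng), {taxa[0]})
            b_clades = set(b.clades().values())
            for clade in a.clades().values():
                got = map_node(clade, {"b": b})["b"]
                assert (got is not None) == (clade in b_clades)


class TestRobustnessReport:
    def _grid(self):
        t1 = root_by_outgroup(pa.read_newick(
            "(((A:1,B:1):1,C:1):1,D:1,E:1);"), {"E"})
        t2 = root_by_outgroup(pa.read_newick(
            "((A:1,B:1):1,(C:1,D:1):1,E:1);"), {"E"})
        return RobustnessGrid(trees={("muscle", "LG"): t1,
                                     ("muscle", "JTT"): t2})

    def test_identical_trees_fraction_one(self):
        t = root_by_outgroup(pa.read_newick(
            "((A:1,B:1):1,(C:1,D:1):1,E:1);"), {"E"})
        grid = RobustnessGrid(trees={("m", "LG"): t, ("m", "JTT"): t.copy()})
        report = robustness_report(grid)
        assert (report.existence_fraction == 1.0).all()

    def test_symmetry_of_correspondence(self):
        report = robustness_report(self._grid())
        cor = report.attrs["correspondences"]
        by_cell = {}
        for c in cor:
            by_cell.setdefault(c.source_cell, {})[c.node_id] = c
        for c in cor:
            for cell, match in c.matches.items():
                if cell == c.source_cell or match is None:
                    continue
                if match in by_cell[cell]:  # internal-node match
                    back = by_cell[cell][match].matches[c.source_cell]
                    assert back == c.node_id

    def test_pair_count_matches_all_pairs_oracle(self):
        grid = self._grid()
        report = robustness_report(grid)
        cells = grid.cells()
        oracle = 0
        for ca in cells:
            for cb in cells:
                ca_clades = set(grid.trees[ca].clades().values())
                cb_clades = set(grid.trees[cb].clades().values())
                oracle += len(ca_clades & cb_clades)
        got = sum(
            1 for c in report.attrs["correspondences"]
            for m in c.matches.values() if m is not None)
        assert got == oracle

    def test_single_cell_rejected(self):
        t = root_by_outgroup(pa.read_newick(
            "((A:1,B:1):1,(C:1,D:1):1,E:1);"), {"E"})
        with pytest.raises(RobustnessError):
            robustness_report(RobustnessGrid(trees={("m", "LG"): t}))


def _post(node_id, *cols):
    probs = np.zeros((len(cols), 20))
    present = np.ones(len(cols), dtype=bool)
    for i, c in enumerate(cols):
        if c is None:
            present[i] = False
            probs[i] = 1 / 20
        else:
            aa, p = c
            probs[i, pa.AMINO_ACIDS.index(aa)] = p
            rest = (1 - p) / 19
            probs[i] += rest
            probs[i, pa.AMINO_ACIDS.index(aa)] = p
    from protasr.ancestral import AncestralPosterior
    return AncestralPosterior(node_id=node_id, clade=frozenset(),
                              probs=probs,
                              rate_weights=np.ones((len(cols), 1)),
                              indel_present=present)


class TestDiffAncestors:
    def test_identical_ancestors_empty(self):
        a = _post(1, ("K", 0.95), ("W", 0.9))
        assert len(diff_ancestors(a, a)) == 0

    def test_confident_substitution(self):
        a = _post(1, ("K", 0.95))
        b = _post(2, ("R", 0.91))
        diff = diff_ancestors(a, b, confident_threshold=0.8)
        row = diff.table.iloc[0]
        assert (row["from_state"], row["to_state"]) == ("K", "R")
        assert row["class"] == "confident"

    def test_low_support_is_ambiguous(self):
        a = _post(1, ("K", 0.95))
        b = _post(2, ("R", 0.55))
        assert diff_ancestors(a, b).table.iloc[0]["class"] == "ambiguous"

    def test_indel_class(self):
        a = _post(1, ("K", 0.95))
        b = _post(2, None)
        assert diff_ancestors(a, b).table.iloc[0]["class"] == "indel"

    def test_symmetry_with_roles_swapped(self):
        a = _post(1, ("K", 0.95), ("A", 0.7), ("W", 0.99))
        b = _post(2, ("R", 0.91), ("A", 0.7), ("C", 0.5))
        ab, ba = diff_ancestors(a, b), diff_ancestors(b, a)
        assert ab.table.column.tolist() == ba.table.column.tolist()
        assert ab.table.from_state.tolist() == ba.table.to_state.tolist()

    def test_confident_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        cols_a = [(pa.AMINO_ACIDS[rng.integers(20)],
                   float(rng.uniform(0.4, 1.0))) for _ in range(40)]
        cols_b = [(pa.AMINO_ACIDS[rng.integers(20)],
                   float(rng.uniform(0.4, 1.0))) for _ in range(40)]
        a, b = _post(1, *cols_a), _post(2, *cols_b)
        counts = []
        for thr in (0.5, 0.7, 0.9, 0.99):
            d = diff_ancestors(a, b, confident_threshold=thr)
            counts.append((d.table["class"] == "confident").sum())
        assert all(x >= y for x, y in zip(counts, counts[1:]))

    def test_different_alignment_lengths_rejected(self):
        with pytest.raises(RobustnessError, match="residue map"):
            diff_ancestors(_post(1, ("K", 0.9)),
                           _post(2, ("K", 0.9), ("R", 0.9)))


class TestBranchPathMutations:
    def _recon(self, seed=0):
        t = pa.read_newick(
            "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,(E:0.1,F:0.1):0.1);")
        rooted = root_by_outgroup(t, {"A", "B"})
        sim = pa.simulate_evolution(pa.SimulationSpec(
            tree=rooted, seq_length=150, model="LG", seed=seed))
        res = TreeLikelihood(sim.alignment, sim.tree,
                             pa.build_model("LG")).fit(optimize=())
        return res.ancestral_posteriors(), sim

    def test_same_node_empty_path(self):
        recon, _ = self._recon()
        nid = recon.node_ids()[0]
        assert branch_path_mutations(recon, nid, nid) == []

    def test_single_branch_equals_pairwise_diff(self):
        recon, _ = self._recon()
        root = recon.tree.base
        child = next(c for c in root.children if not c.is_leaf)
        diffs = branch_path_mutations(recon, root.node_id, child.node_id)
        assert len(diffs) == 1
        direct = diff_ancestors(recon[root.node_id], recon[child.node_id])
        assert diffs[0].table.equals(direct.table)

    def test_root_to_leaf_confident_muts_cover_differences(self):
        recon, sim = self._recon(seed=4)
        tree = recon.tree
        leaf = tree.node_by_name("C")
        root_id = tree.base.node_id
        diffs = branch_path_mutations(recon, root_id, leaf.node_id,
                                      confident_threshold=0.8)
        path_cols = set()
        for d in diffs:
            path_cols |= set(d.table.column.tolist())
        # columns where a confidently reconstructed root differs from
        # the leaf must appear somewhere along the path
        root_seq = ml_sequence(recon[root_id])
        leaf_row = sim.alignment.row("C")
        for col in range(1, sim.alignment.ncols + 1):
            a = root_seq.residues[col - 1]
            b = leaf_row[col - 1]
            s = root_seq.support[col - 1]
            if a != "-" and b != "-" and a != b and s >= 0.95:
                assert col in path_cols
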