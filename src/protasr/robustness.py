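"""Outgroup rooting, ancestral-node robustness across a method/model
grid, and mutational-trajectory diffs between ancestors.

An ancestral node is identified by its descendant leaf set after
outgroup rooting. Because ML trees inferred from different alignments
or models can disagree in topology, a node from one tree may simply
not exist on another: the correspondence machinery here looks the
clade up in every other tree of the grid and reports where it is
found, giving an existence fraction per ancestor.

Trajectory diffs list the columns where two ancestors' ML residues (or
indel states) differ, classifying each as "confident" (both endpoint
posteriors at or above a threshold), "ambiguous", or "indel" — the set
of candidate function-changing substitutions along a branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestral import AncestralPosterior, AncestralReconstruction, ml_sequence
from .tree import PhyloTree, TreeError


class RobustnessError(ValueError):
    pass


def root_by_outgroup(tree: PhyloTree, outgroup) -> PhyloTree:
    """Root an unrooted tree on the edge separating the outgroup.

    The root bisects that edge (equal halves; for reversible models the
    likelihood does not depend on the split). The outgroup must be a
    nonempty proper subset of the leaves and monophyletic in the
    unrooted tree.
    """
    outgroup = set(outgroup)
    leaves = set(tree.leaf_names)
    if not outgroup:
        raise RobustnessError("outgroup is empty")
    if not outgroup < leaves:
        extra = outgroup - leaves
        if extra:
            raise RobustnessError(
                f"outgroup taxa not in tree: {sorted(extra)}")
        raise RobustnessError(
            "outgroup cannot contain every taxon in the tree")
    work = tree.unrooted() if tree.rooted else tree.copy()
    for node in work.base.postorder():
        if node.parent is None:
            continue
        side = {l.name for l in node.leaves()}
        if side == outgroup or side == leaves - outgroup:
            return work.rooted_on_edge(node.node_id, fraction=0.5)
    # not monophyletic: report the smallest split containing the outgroup
    best = leaves
    for node in work.base.postorder():
        if node.parent is None:
            continue
        side = {l.name for l in node.leaves()}
        for s in (side, leaves - side):
            if outgroup <= s and len(s) < len(best):
                best = s
    raise RobustnessError(
        f"outgroup {sorted(outgroup)} is not monophyletic; the smallest "
        f"containing split is {sorted(best)}")


@dataclass
class NodeCorrespondence:
    """Where one ancestral node exists across the grid."""

    source_cell: tuple  # (alignment name, model spec)
    node_id: int
    leaf_set: frozenset
    matches: dict  # cell -> matched node id, or None for "absent"
    existence_fraction: float


def map_node(leaf_set, target_trees: dict,
             source_taxa=None) -> dict:
    """Look one clade up in each rooted target tree.

    ``target_trees`` maps a cell label to a rooted :class:`PhyloTree`;
    the return maps each label to the matching internal node id or
    None. When ``source_taxa`` is given (trees over different taxon
    sets, e.g. after masking), both the query clade and the target
    clades are first restricted to the taxa the two trees share. A
    single-leaf set matches the leaf itself.
    """
    leaf_set = frozenset(leaf_set)
    out = {}
    for label, t in target_trees.items():
        ttaxa = set(t.leaf_names)
        universe = ttaxa if source_taxa is None else set(source_taxa) & ttaxa
        shared = leaf_set & universe
        if not shared:
            out[label] = None
            continue
        if len(shared) == 1:
            out[label] = t.node_by_name(next(iter(shared))).node_id
            continue
        match = None
        for nid, clade in sorted(t.clades().items()):
            if clade & universe == shared:
                match = nid
                break
        out[label] = match
    return out


@dataclass
class RobustnessGrid:
    """Fitted (alignment method x model) grid of rooted trees."""

    trees: dict  # (alignment name, model spec) -> rooted PhyloTree
    ancestors: dict = field(default_factory=dict)  # cell -> AncestralReconstruction

    def cells(self) -> list:
        return list(self.trees)


def robustness_report(grid: RobustnessGrid) -> pd.DataFrame:
    """Cross-map every internal node of every grid cell onto all cells.

    One row per (source cell, internal node): its leaf set, the match
    (node id or "absent") in every cell, and the fraction of cells
    where the ancestor exists. The mapping is symmetric: if u in T1
    maps to v in T2 then v maps back to u.
    """
    cells = grid.cells()
    if len(cells) < 2:
        raise RobustnessError("need at least 2 grid cells")
    rows = []
    correspondences = []
    for cell in cells:
        tree = grid.trees[cell]
        for nid, clade in sorted(tree.clades().items()):
            matches = map_node(clade, {c: grid.trees[c] for c in cells},
                               source_taxa=tree.leaf_names)
            frac = sum(m is not None for m in matches.values()) / len(cells)
            correspondences.append(NodeCorrespondence(
                source_cell=cell, node_id=nid, leaf_set=clade,
                matches=matches, existence_fraction=frac))
            row = {
                "alignment": cell[0],
                "model": cell[1],
                "node_id": nid,
                "leaf_set": ",".join(sorted(clade)),
                "existence_fraction": frac,
            }
            for c in cells:
                m = matches[c]
                row[f"in {c[0]}|{c[1]}"] = "absent" if m is None else f"Node{m}"
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["correspondences"] = correspondences
    return df


@dataclass
class TrajectoryDiff:
    """Columns at which two ancestors differ."""

    from_node: int
    to_node: int
    table: pd.DataFrame  # column, from/to residues + posteriors, class

    def __len__(self) -> int:
        return len(self.table)


def diff_ancestors(a: AncestralPosterior, b: AncestralPosterior,
                   confident_threshold: float = 0.8) -> TrajectoryDiff:
    """List the columns where two ancestors' ML states differ.

    Both posteriors must live on the same alignment coordinate system
    (same number of columns). A differing column is classed "indel"
    when the presence states differ, "confident" when both endpoint
    posteriors are at or above the threshold, else "ambiguous".
    """
    if a.probs.shape != b.probs.shape:
        raise RobustnessError(
            "ancestors come from different alignments "
            f"({a.probs.shape[0]} vs {b.probs.shape[0]} columns); map "
            "columns across alignments with a residue map first")
    seq_a = ml_sequence(a)
    seq_b = ml_sequence(b)
    rows = []
    for col in range(1, a.ncols + 1):
        ca, cb = seq_a.residues[col - 1], seq_b.residues[col - 1]
        pa, pb = a.indel_present[col - 1], b.indel_present[col - 1]
        if pa != pb:
            cls = "indel"
        elif ca != cb:
            sa = seq_a.support[col - 1]
            sb = seq_b.support[col - 1]
            cls = ("confident"
                   if sa >= confident_threshold and sb >= confident_threshold
                   else "ambiguous")
        else:
            continue
        rows.append({
            "column": col,
            "from_state": ca,
            "from_support": float(seq_a.support[col - 1])
            if pa else np.nan,
            "to_state": cb,
            "to_support": float(seq_b.support[col - 1]) if pb else np.nan,
            "class": cls,
        })
    table = pd.DataFrame(
        rows, columns=["column", "from_state", "from_support",
                       "to_state", "to_support", "class"])
    return TrajectoryDiff(from_node=a.node_id, to_node=b.node_id,
                          table=table)


def branch_path_mutations(recon: AncestralReconstruction,
                          from_node: int, to_node: int,
                          confident_threshold: float = 0.8
                          ) -> list[TrajectoryDiff]:
    """Per-branch diffs along the path between two nodes of one tree.

    Node ids may denote internal nodes or leaves (leaves contribute a
    point-mass posterior). The path runs through the MRCA; the diffs
    are returned in path order, one per branch.
    """
    from .ancestral import leaf_posterior

    tree = recon.tree
    if not tree.rooted:
        raise TreeError("trajectory paths require the rooted tree")

    def node_path(nid):
        node = tree.node_by_id(nid)
        path = [node]
        while node.parent is not None:
            node = node.parent
            path.append(node)
        return path

    if from_node == to_node:
        return []
    up_a = node_path(from_node)
    up_b = node_path(to_node)
    ids_a = [n.node_id for n in up_a]
    ids_b = [n.node_id for n in up_b]
    mrca = next(nid for nid in ids_a if nid in set(ids_b))
    path = (ids_a[:ids_a.index(mrca) + 1]
            + list(reversed(ids_b[:ids_b.index(mrca)])))

    def posterior_of(nid):
        if nid in recon.posteriors:
            return recon.posteriors[nid]
        node = tree.node_by_id(nid)
        return leaf_posterior(recon.alignment, node.name, nid)

    diffs = []
    for x, y in zip(path, path[1:]):
        diffs.append(diff_ancestors(posterior_of(x), posterior_of(y),
                                    confident_threshold=confident_threshold))
    return diffs
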