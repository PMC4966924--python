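"""Sequence evolution simulator with recorded ancestral truth.

The simulator is the package's test-bed: it draws a root protein
sequence from the model's equilibrium frequencies, evolves it down a
tree by sampling from the transition matrices branch by branch (with a
continuous per-site gamma rate when the model has +G), and applies a
simple per-branch column-deletion process so that Fitch indel
placement has something to reconstruct. Every internal node's true
sequence is retained, so tree inference, model selection and ancestral
reconstruction can all be scored against the truth.

Deliberate simplifications: deletions only (no insertions, so the
alignment coordinate system is the root's), independent sites, and a
single substitution process across sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AMINO_ACIDS, GAP, Alignment
from .models import SubstitutionModel, parse_model_spec
from .tree import DEFAULT_BRANCH_LENGTH, PhyloTree, TreeNode, random_topology


@dataclass
class SimulationSpec:
    """Everything a simulation run needs; fully determined by the seed."""

    n_taxa: int = 6
    seq_length: int = 500
    model: str = "LG"
    seed: int = 0
    tree: PhyloTree | None = None  # rooted; drawn at random when None
    birth_rate: float = 1.0  # Yule speciation rate for random trees
    branch_length: float | None = None  # fixed length overriding Yule draws
    deletion_rate: float = 0.0  # per-branch, per-column deletion probability


@dataclass
class SimulationResult:
    alignment: Alignment
    tree: PhyloTree  # rooted, true branch lengths
    ancestors: dict[int, str]  # node id -> gapped true sequence
    site_rates: np.ndarray
    spec: SimulationSpec = None

    def true_root_sequence(self) -> str:
        return self.ancestors[self.tree.base.node_id]


def random_yule_tree(n_taxa: int, birth_rate: float, rng,
                     names: list[str] | None = None) -> PhyloTree:
    """A rooted Yule (pure-birth) tree with exponential waiting times."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    names = names or [f"t{i + 1}" for i in range(n_taxa)]
    root = TreeNode()
    tips = []
    for _ in range(2):
        c = root.add_child(TreeNode(None, 0.0))
        tips.append(c)
    while len(tips) < n_taxa:
        dt = rng.exponential(1.0 / (birth_rate * len(tips)))
        for t in tips:
            t.length += dt
        k = rng.integers(len(tips))
        parent = tips.pop(k)
        for _ in range(2):
            c = parent.add_child(TreeNode(None, 0.0))
            tips.append(c)
    dt = rng.exponential(1.0 / (birth_rate * len(tips)))
    for i, t in enumerate(tips):
        t.length += dt
        t.name = names[i]
    return PhyloTree(root)


def _rooted(tree: PhyloTree) -> PhyloTree:
    if tree.rooted:
        return tree.copy()
    # arbitrary rooting; fine for simulation under a reversible model
    first_leaf = tree.base.leaves()[0]
    return tree.rooted_on_edge(first_leaf.node_id, fraction=0.5)


def simulate_evolution(spec: SimulationSpec) -> SimulationResult:
    """Simulate an alignment (and its true ancestors) under a model."""
    rng = np.random.default_rng(spec.seed)
    model = parse_model_spec(spec.model) if isinstance(spec.model, str) \
        else spec.model
    if spec.tree is not None:
        tree = _rooted(spec.tree)
    else:
        tree = random_yule_tree(spec.n_taxa, spec.birth_rate, rng)
        if spec.branch_length is not None:
            for n in tree.base.postorder():
                if n.parent is not None:
                    n.length = spec.branch_length
    L = spec.seq_length
    if model.alpha is not None:
        site_rates = rng.gamma(model.alpha, 1.0 / model.alpha, size=L)
    else:
        site_rates = np.ones(L)
    aa = np.array(list(AMINO_ACIDS))
    root_states = rng.choice(20, size=L, p=model.pi)
    states = {tree.base.node_id: root_states}
    present = {tree.base.node_id: np.ones(L, dtype=bool)}
    for node in tree.base.preorder():
        if node.parent is None:
            continue
        parent_states = states[node.parent.node_id]
        t = node.length or 0.0
        # per-site transition rows via the cached eigendecomposition
        expf = np.exp(model._eigval[None, :] * t * site_rates[:, None])
        rows = np.einsum("lk,lk,kj->lj", model._left[parent_states],
                         expf, model._right)
        rows = np.clip(rows, 0.0, None)
        rows /= rows.sum(axis=1, keepdims=True)
        u = rng.random(L)
        cum = np.cumsum(rows, axis=1)
        cum[:, -1] = 1.0
        states[node.node_id] = (u[:, None] > cum).sum(axis=1)
        keep = present[node.parent.node_id].copy()
        if spec.deletion_rate > 0:
            hit = rng.random(L) < spec.deletion_rate
            keep &= ~hit
        present[node.node_id] = keep
    seqs = {}
    for node in tree.base.postorder():
        nid = node.node_id
        chars = aa[states[nid]].copy()
        chars[~present[nid]] = GAP
        seqs[nid] = "".join(chars)
    taxa = tree.leaf_names
    rows = [seqs[tree.node_by_name(t).node_id] for t in taxa]
    aln = Alignment(taxa, rows, name="simulated")
    return SimulationResult(alignment=aln, tree=tree, ancestors=seqs,
                            site_rates=site_rates, spec=spec)


def perturb_gaps(aln: Alignment, rng, n_moves: int = 10,
                 name: str | None = None) -> Alignment:
    """Slide gaps within rows to mimic a different aligner's choices.

    Each move swaps a gap with an adjacent residue in one row, which
    preserves every degapped sequence and the column count — exactly
    the kind of disagreement alternative alignment programs produce.
    """
    rows = [list(r) for r in aln.rows]
    gapped_rows = [i for i, r in enumerate(rows) if GAP in r]
    if gapped_rows:
        for _ in range(n_moves):
            i = gapped_rows[rng.integers(len(gapped_rows))]
            row = rows[i]
            gaps = [j for j, ch in enumerate(row) if ch == GAP]
            j = gaps[rng.integers(len(gaps))]
            direction = 1 if rng.random() < 0.5 else -1
            k = j + direction
            if 0 <= k < len(row) and row[k] != GAP:
                row[j], row[k] = row[k], row[j]
    return Alignment(aln.taxa, ["".join(r) for r in rows],
                     name=name or f"{aln.name}-perturbed")
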