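"""Empirical-Bayes marginal ancestral sequence reconstruction.

For every internal node of a rooted, ML-fitted tree the posterior
distribution over the 20 amino acids is computed at each alignment
column by combining the inside (below-node) and outside (above-node)
partial likelihoods at the ML parameter estimates — the marginal
(per-node) empirical-Bayes reconstruction. Under a +G model the
posterior mixes rate categories with per-column empirical-Bayes
category weights.

Gap handling is separate: ancestral presence/absence of each column is
placed by Fitch parsimony on the binary gap character, with ambiguity
after the up-pass resolved by preferring the parent's state on the
down-pass (an ambiguous root becomes "present"). Columns absent at a
node carry no residue claim and render as ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, Alignment, GAP
from .likelihood import TreeLikelihood, TreeLikelihoodResults
from .tree import PhyloTree, TreeError


class AncestralError(ValueError):
    pass


@dataclass
class AncestralPosterior:
    """Per-column amino-acid posterior for one ancestral node."""

    node_id: int
    clade: frozenset
    probs: np.ndarray  # (ncols, 20), rows sum to 1
    rate_weights: np.ndarray  # (ncols, ncat) empirical-Bayes category weights
    indel_present: np.ndarray  # (ncols,) bool

    @property
    def ncols(self) -> int:
        return self.probs.shape[0]


@dataclass
class AncestralSequence:
    """A concrete ancestral sequence extracted from a posterior."""

    node_id: int
    kind: str  # "ML" or "sample<j>|seed<s>"
    residues: str  # length ncols, '-' at absent columns
    support: np.ndarray  # posterior of the chosen residue (nan at '-')
    ties: np.ndarray  # bool, True where the argmax was tied


@dataclass
class SupportSummary:
    """Fig-style per-node support: histogram plus best/2nd/3rd traces."""

    node_id: int
    bin_edges: np.ndarray  # 11 edges, [0, 0.1, ..., 1.0]
    histogram: np.ndarray  # 10 counts over non-indel columns
    best: np.ndarray  # (ncols,) P of best residue, nan at indels
    second: np.ndarray
    third: np.ndarray


class AncestralReconstruction:
    """Marginal posteriors for every internal node of a rooted tree."""

    def __init__(self, tree: PhyloTree, alignment: Alignment,
                 posteriors: dict[int, AncestralPosterior]):
        self.tree = tree
        self.alignment = alignment
        self.posteriors = posteriors

    def __getitem__(self, node_id: int) -> AncestralPosterior:
        return self.posteriors[node_id]

    def node_ids(self) -> list[int]:
        return sorted(self.posteriors)

    def ml_sequences(self) -> dict[int, AncestralSequence]:
        return {nid: ml_sequence(p) for nid, p in self.posteriors.items()}

    def posterior_table(self, node_id: int) -> pd.DataFrame:
        """Tidy per-column table: column, indel state, 20 probabilities."""
        p = self.posteriors[node_id]
        df = pd.DataFrame(p.probs, columns=list(AMINO_ACIDS))
        df.insert(0, "column", np.arange(1, p.ncols + 1))
        df.insert(1, "indel",
                  np.where(p.indel_present, "present", "absent"))
        return df


def marginal_posteriors(result: TreeLikelihoodResults,
                        outgroup=None,
                        rooted_tree: PhyloTree | None = None
                        ) -> AncestralReconstruction:
    """Empirical-Bayes marginal reconstruction at every internal node.

    ``result`` must be a fitted likelihood result. An unrooted fitted
    tree is first rooted: explicitly via ``rooted_tree`` (same
    topology) or by the given outgroup; reconstruction on an unrooted
    tree is refused because ancestral nodes are only defined on a
    rooted phylogeny.
    """
    tree = result.tree
    if not tree.rooted:
        if rooted_tree is not None:
            tree = rooted_tree
        elif outgroup is not None:
            from .robustness import root_by_outgroup
            tree = root_by_outgroup(tree, outgroup)
        else:
            raise AncestralError(
                "tree is unrooted: supply an outgroup (or a rooted tree) "
                "to place the root before reconstructing ancestors")
    aln = result.alignment
    model = result.subst_model
    tl = TreeLikelihood(aln, tree, model)
    P = tl._pmats(tree, model)
    D, Dlogs = tl._down(tree, P)
    Out, Ologs, _, _ = tl._outside(tree, P, D, Dlogs, model)
    indels = place_indels(aln, tree)
    ncat = model.rate_categories.ncat
    npat = tl.n_patterns
    clades = tree.clades()
    posteriors = {}
    for node in tree.base.postorder():
        if node.is_leaf:
            continue
        joint = np.asarray(Out[id(node)]) * np.asarray(D[id(node)])
        joint = np.broadcast_to(joint, (ncat, npat, 20))
        denom = joint.sum(axis=(0, 2))  # per pattern
        denom = np.where(denom > 0, denom, 1.0)
        probs_pat = joint.sum(axis=0) / denom[:, None]
        w_pat = joint.sum(axis=2) / denom[None, :]
        probs = probs_pat[tl.pattern_index]
        weights = w_pat.T[tl.pattern_index]
        posteriors[node.node_id] = AncestralPosterior(
            node_id=node.node_id,
            clade=clades[node.node_id],
            probs=probs,
            rate_weights=weights,
            indel_present=indels[node.node_id],
        )
    return AncestralReconstruction(tree, aln, posteriors)


def ml_sequence(post: AncestralPosterior) -> AncestralSequence:
    """Most-probable residue at every present column.

    Ties break to the alphabetically first amino acid (the amino-acid
    axis is alphabetical, so argmax does this) and are flagged.
    """
    idx = np.argmax(post.probs, axis=1)
    best = post.probs[np.arange(post.ncols), idx]
    ties = (post.probs == best[:, None]).sum(axis=1) > 1
    chars = np.array(list(AMINO_ACIDS))[idx]
    chars[~post.indel_present] = GAP
    support = best.copy()
    support[~post.indel_present] = np.nan
    return AncestralSequence(
        node_id=post.node_id, kind="ML",
        residues="".join(chars), support=support, ties=ties)


def sample_sequences(post: AncestralPosterior, n: int,
                     seed: int) -> list[AncestralSequence]:
    """Bayesian-sampled sequences: per-column independent posterior draws."""
    if n < 1:
        raise AncestralError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(post.probs, axis=1)
    cum[:, -1] = 1.0
    out = []
    for j in range(n):
        u = rng.random(post.ncols)
        idx = (u[:, None] > cum).sum(axis=1)
        chars = np.array(list(AMINO_ACIDS))[idx]
        chars[~post.indel_present] = GAP
        support = post.probs[np.arange(post.ncols), idx]
        support[~post.indel_present] = np.nan
        out.append(AncestralSequence(
            node_id=post.node_id, kind=f"sample{j}|seed{seed}",
            residues="".join(chars), support=support,
            ties=np.zeros(post.ncols, dtype=bool)))
    return out


def place_indels(aln: Alignment, tree: PhyloTree) -> dict[int, np.ndarray]:
    """Fitch parsimony presence/absence of every column at every node.

    Up-pass: a node's state set is the intersection of its children's
    sets when nonempty, else the union. Down-pass: the root takes
    "present" when ambiguous; every other node takes its parent's state
    when admissible. The labeling attains the parsimony minimum.
    Returns, for every node id (leaves included), a boolean
    present-mask over columns.
    """
    if not tree.rooted:
        raise TreeError("indel placement requires a rooted tree")
    ncols = aln.ncols
    # bitmask per column: bit0 = absent possible, bit1 = present possible
    masks: dict[int, np.ndarray] = {}
    for node in tree.base.postorder():
        if node.is_leaf:
            row = np.frombuffer(aln.row(node.name).encode(), dtype=np.uint8)
            present = row != ord(GAP)
            masks[id(node)] = np.where(present, 2, 1).astype(np.uint8)
        else:
            child_masks = [masks[id(c)] for c in node.children]
            inter = child_masks[0]
            union = child_masks[0]
            for m in child_masks[1:]:
                inter = inter & m
                union = union | m
            masks[id(node)] = np.where(inter != 0, inter, union)
    states: dict[int, np.ndarray] = {}
    for node in tree.base.preorder():
        m = masks[id(node)]
        if node.parent is None:
            st = (m & 2) != 0  # ambiguous root -> present
        else:
            pstate = states[node.parent.node_id]
            want = np.where(pstate, 2, 1).astype(np.uint8)
            ok = (m & want) != 0
            st = np.where(ok, pstate, (m & 2) != 0)
        states[node.node_id] = st.astype(bool)
    return states


def indel_change_count(tree: PhyloTree,
                       states: dict[int, np.ndarray]) -> np.ndarray:
    """Per-column number of presence-state changes along edges."""
    ncols = next(iter(states.values())).shape[0]
    changes = np.zeros(ncols, dtype=int)
    for node in tree.base.postorder():
        if node.parent is not None:
            changes += (states[node.node_id]
                        != states[node.parent.node_id]).astype(int)
    return changes


def support_summary(post: AncestralPosterior) -> SupportSummary:
    """Histogram of ML-residue posteriors plus best/2nd/3rd traces."""
    top3 = -np.sort(-post.probs, axis=1)[:, :3]
    best, second, third = top3[:, 0].copy(), top3[:, 1].copy(), top3[:, 2].copy()
    for arr in (best, second, third):
        arr[~post.indel_present] = np.nan
    edges = np.linspace(0.0, 1.0, 11)
    hist, _ = np.histogram(best[post.indel_present], bins=edges)
    return SupportSummary(
        node_id=post.node_id, bin_edges=edges, histogram=hist,
        best=best, second=second, third=third)


def map_to_extant(anc: AncestralSequence, post: AncestralPosterior,
                  extant_taxon: str, aln: Alignment) -> pd.DataFrame:
    """Site table aligning an ancestor with one extant sequence.

    One row per alignment column: the 1-based alignment column, the
    ancestor's own (non-gap) site index and ML residue, the extant
    sequence's site index and residue, and the full posterior at that
    column. Gapped positions show ``-`` and no site index.
    """
    if extant_taxon not in aln.taxa:
        raise AncestralError(f"unknown taxon {extant_taxon!r}")
    ext_row = aln.row(extant_taxon)
    rows = []
    anc_i = 0
    ext_i = 0
    for col in range(1, aln.ncols + 1):
        a_ch = anc.residues[col - 1]
        e_ch = ext_row[col - 1]
        a_site = None
        e_site = None
        if a_ch != GAP:
            anc_i += 1
            a_site = anc_i
        if e_ch != GAP:
            ext_i += 1
            e_site = ext_i
        dist = {aa: float(p) for aa, p in
                zip(AMINO_ACIDS, post.probs[col - 1]) if p > 1e-12}
        rows.append({
            "column": col,
            "anc_site": a_site, "anc_state": a_ch,
            "extant_site": e_site, "extant_state": e_ch,
            "posterior": dict(sorted(dist.items(),
                                     key=lambda kv: -kv[1])),
        })
    df = pd.DataFrame(rows)
    for c in ("anc_site", "extant_site"):
        df[c] = df[c].astype("Int64")  # nullable: gaps have no index
    return df


def leaf_posterior(aln: Alignment, taxon: str,
                   node_id: int) -> AncestralPosterior:
    """Degenerate point-mass posterior for an extant sequence, so leaves
    can participate in ancestor-vs-descendant diffs."""
    row = aln.row(taxon)
    probs = np.zeros((aln.ncols, 20))
    present = np.zeros(aln.ncols, dtype=bool)
    for i, ch in enumerate(row):
        if ch == GAP:
            probs[i] = 1.0 / 20.0
        elif ch in AMINO_ACIDS:
            probs[i, AMINO_ACIDS.index(ch)] = 1.0
            present[i] = True
        else:  # ambiguous X: uniform, but present
            probs[i] = 1.0 / 20.0
            present[i] = True
    return AncestralPosterior(
        node_id=node_id, clade=frozenset({taxon}), probs=probs,
        rate_weights=np.ones((aln.ncols, 1)), indel_present=present)
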