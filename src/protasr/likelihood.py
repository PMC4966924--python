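"""Felsenstein-pruning likelihood engine and model fitting.

The central objects follow the model/results idiom: a
:class:`TreeLikelihood` binds an alignment, a tree and a substitution
model, its :meth:`~TreeLikelihood.fit` optimizes branch lengths and the
gamma shape by coordinate ascent, and the returned
:class:`TreeLikelihoodResults` carries the fitted tree, log-likelihoods
and diagnostics, plus entry points to ancestral reconstruction and
branch support.

Site patterns are compressed before any computation; per-node partial
likelihoods are rescaled per pattern so deep trees cannot underflow.
Gaps and the ambiguity code 'X' are missing data (all-ones leaf
partials), so an all-gap column has likelihood 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .alignment import AA_INDEX, Alignment
from .models import SubstitutionModel, parse_model_spec
from .tree import (PhyloTree, TreeError, canonical_topology,
                   enumerate_topologies, nni_neighbors)

BL_BOUNDS = (1e-8, 20.0)
ALPHA_BOUNDS = (0.02, 100.0)
MAX_EXHAUSTIVE_TAXA = 9


class LikelihoodError(ValueError):
    pass


def _encode_alignment(aln: Alignment, leaf_names: list[str]):
    """Integer-encode and pattern-compress the alignment columns."""
    missing = set(leaf_names) - set(aln.taxa)
    if missing:
        raise LikelihoodError(
            f"tree leaves absent from alignment: {sorted(missing)}")
    data = np.empty((len(leaf_names), aln.ncols), dtype=np.int8)
    for i, taxon in enumerate(leaf_names):
        row = aln.row(taxon)
        data[i] = [AA_INDEX.get(ch, -1) for ch in row]
    patterns, inverse, counts = np.unique(
        data, axis=1, return_inverse=True, return_counts=True)
    return patterns, inverse.ravel(), counts.astype(float)


class TreeLikelihood:
    """Phylogenetic likelihood model for one alignment/tree/model triple.

    Parameters
    ----------
    alignment : Alignment
    tree : PhyloTree
        Rooted or unrooted; for reversible models the likelihood does
        not depend on root placement.
    model : SubstitutionModel
    """

    def __init__(self, alignment: Alignment, tree: PhyloTree,
                 model: SubstitutionModel):
        self.alignment = alignment
        self.tree = tree
        self.model = model
        self.patterns, self.pattern_index, self.pattern_counts = \
            _encode_alignment(alignment, tree.leaf_names)
        self.n_patterns = self.patterns.shape[1]
        # per-leaf partial likelihood, shape (1, npat, 20)
        self._leaf_partial = {}
        for i, taxon in enumerate(tree.leaf_names):
            arr = np.zeros((1, self.n_patterns, 20))
            codes = self.patterns[i]
            obs = codes >= 0
            arr[0, obs, codes[obs]] = 1.0
            arr[0, ~obs, :] = 1.0
            self._leaf_partial[taxon] = arr

    # -- core passes ---------------------------------------------------

    def _pmats(self, tree: PhyloTree, model: SubstitutionModel):
        P = {}
        for node in tree.base.postorder():
            if node.parent is None:
                continue
            t = node.length if node.length is not None else 0.0
            P[id(node)] = model.transition_matrices(t)
        return P

    def _down(self, tree: PhyloTree, P):
        """Post-order (inside) partials, per-pattern rescaled."""
        D, logs = {}, {}
        npat = self.n_patterns
        for node in tree.base.postorder():
            if node.is_leaf:
                D[id(node)] = self._leaf_partial[node.name]
                logs[id(node)] = np.zeros(npat)
            else:
                acc = None
                ls = np.zeros(npat)
                for c in node.children:
                    M = np.matmul(D[id(c)], P[id(c)].transpose(0, 2, 1))
                    acc = M if acc is None else acc * M
                    ls += logs[id(c)]
                m = acc.max(axis=(0, 2))
                safe = np.where(m > 0, m, 1.0)
                acc = acc / safe[None, :, None]
                ls = ls + np.log(safe)
                D[id(node)] = acc
                logs[id(node)] = ls
        return D, logs

    def _outside(self, tree: PhyloTree, P, D, Dlogs, model: SubstitutionModel):
        """Pre-order (outside) partials and per-edge "rest of tree" terms.

        ``Out[v][c,p,i]`` is proportional to the probability of all data
        outside the subtree of ``v`` jointly with state ``i`` at ``v``
        (the base gets the equilibrium frequencies). ``U[c]`` is the
        outside term for the edge above node ``c``, i.e. the likelihood
        contribution of everything except c's subtree, indexed by the
        state at c's parent.
        """
        npat = self.n_patterns
        ncat = model.rate_categories.ncat
        Out, Ologs, U, Ulogs = {}, {}, {}, {}
        base = tree.base
        Out[id(base)] = np.broadcast_to(
            model.pi[None, None, :], (1, npat, 20))
        Ologs[id(base)] = np.zeros(npat)
        for v in base.preorder():
            if v.is_leaf:
                continue
            Ms = {id(c): np.matmul(D[id(c)], P[id(c)].transpose(0, 2, 1))
                  for c in v.children}
            for c in v.children:
                acc = np.array(np.broadcast_to(
                    Out[id(v)], (ncat, npat, 20)), copy=True)
                ls = Ologs[id(v)].copy()
                for s in v.children:
                    if s is c:
                        continue
                    acc = acc * Ms[id(s)]
                    ls = ls + Dlogs[id(s)]
                U[id(c)] = acc
                Ulogs[id(c)] = ls
                out_c = np.matmul(acc, P[id(c)])
                m = out_c.max(axis=(0, 2))
                safe = np.where(m > 0, m, 1.0)
                Out[id(c)] = out_c / safe[None, :, None]
                Ologs[id(c)] = ls + np.log(safe)
        return Out, Ologs, U, Ulogs

    def _pattern_loglik(self, tree: PhyloTree, model: SubstitutionModel):
        P = self._pmats(tree, model)
        D, logs = self._down(tree, P)
        acc = D[id(tree.base)]
        site = np.einsum("cpi,i->cp", acc, model.pi).mean(axis=0)
        with np.errstate(divide="ignore"):
            return np.log(site) + logs[id(tree.base)]

    def loglike(self, tree: PhyloTree | None = None,
                model: SubstitutionModel | None = None) -> float:
        """Total log-likelihood at the given (or bound) tree and model."""
        patl = self._pattern_loglik(tree or self.tree, model or self.model)
        return float(np.dot(self.pattern_counts, patl))

    def site_log_likelihoods(self, tree: PhyloTree | None = None,
                             model: SubstitutionModel | None = None
                             ) -> np.ndarray:
        """Per-column log-likelihood, in alignment column order."""
        patl = self._pattern_loglik(tree or self.tree, model or self.model)
        return patl[self.pattern_index]

    # -- fitting -------------------------------------------------------

    def _edge_loglik_fn(self, tree, model, edge):
        """1-D branch-length objective for one edge, others fixed."""
        P = self._pmats(tree, model)
        D, Dlogs = self._down(tree, P)
        _, _, U, Ulogs = self._outside(tree, P, D, Dlogs, model)
        u, ul = U[id(edge)], Ulogs[id(edge)]
        d, dl = D[id(edge)], Dlogs[id(edge)]
        const = ul + dl

        def fn(t: float) -> float:
            Pt = model.transition_matrices(t)
            tmp = np.matmul(d, Pt.transpose(0, 2, 1))
            site = (u * tmp).sum(axis=2).mean(axis=0)
            with np.errstate(divide="ignore"):
                return float(np.dot(self.pattern_counts,
                                    np.log(site) + const))

        return fn

    def fit(self, optimize=("branch_lengths", "alpha"), tol: float = 1e-6,
            max_sweeps: int = 50) -> "TreeLikelihoodResults":
        """Coordinate-ascent fit of branch lengths and gamma shape.

        Each sweep optimizes every branch length by bounded 1-D search
        (bounds [1e-8, 20]) and then, for +G models, the shape alpha
        (bounds [0.02, 100]). Converged when a full sweep improves lnL
        by less than ``tol``; the likelihood never decreases because a
        proposed update is kept only if it improves it.
        """
        tree = self.tree.copy()
        model = self.model
        lnL = self.loglike(tree, model)
        history = [lnL]
        converged = False
        n_sweeps = 0
        for sweep in range(max_sweeps):
            n_sweeps = sweep + 1
            if "branch_lengths" in optimize:
                for edge in tree.edges():
                    fn = self._edge_loglik_fn(tree, model, edge)
                    cur = fn(edge.length)
                    res = minimize_scalar(
                        lambda t: -fn(t), bounds=BL_BOUNDS,
                        method="bounded", options={"xatol": 1e-8})
                    if -res.fun > cur:
                        edge.length = float(res.x)
            if "alpha" in optimize and model.alpha is not None:
                def neg_alpha(a):
                    return -self.loglike(tree, model.with_alpha(a))
                cur = self.loglike(tree, model)
                res = minimize_scalar(neg_alpha, bounds=ALPHA_BOUNDS,
                                      method="bounded",
                                      options={"xatol": 1e-4})
                if -res.fun > cur:
                    model = model.with_alpha(float(res.x))
            new = self.loglike(tree, model)
            history.append(new)
            if new - history[-2] < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"fit did not converge in {max_sweeps} sweeps "
                f"(last improvement {history[-1] - history[-2]:.3g})",
                stacklevel=2)
        site_lnl = self.site_log_likelihoods(tree, model)
        return TreeLikelihoodResults(
            model_frame=self, tree=tree, subst_model=model,
            lnL=float(np.sum(site_lnl)),
            site_lnL=site_lnl, converged=converged,
            n_sweeps=n_sweeps, history=history)


@dataclass
class TreeLikelihoodResults:
    """Fitted phylogenetic likelihood: estimates, diagnostics, summaries."""

    model_frame: TreeLikelihood
    tree: PhyloTree
    subst_model: SubstitutionModel
    lnL: float
    site_lnL: np.ndarray
    converged: bool
    n_sweeps: int
    history: list = field(default_factory=list)

    @property
    def alignment(self) -> Alignment:
        return self.model_frame.alignment

    @property
    def n_parameters(self) -> int:
        """Free parameters: branch lengths plus model parameters."""
        return len(self.tree.edges()) + self.subst_model.n_free_parameters

    @property
    def aic(self) -> float:
        return 2.0 * self.n_parameters - 2.0 * self.lnL

    def branch_lengths(self) -> dict[int, float]:
        return {n.node_id: n.length for n in self.tree.edges()}

    def summary(self) -> str:
        lines = [
            "Tree likelihood results",
            "=" * 54,
            f"alignment:      {self.alignment.name} "
            f"({len(self.alignment.taxa)} taxa x {self.alignment.ncols} cols)",
            f"model:          {self.subst_model.spec}",
            f"log-likelihood: {self.lnL:.6f}",
            f"AIC:            {self.aic:.6f}  (k = {self.n_parameters})",
            f"converged:      {self.converged} ({self.n_sweeps} sweeps)",
            f"tree length:    {self.tree.total_branch_length():.6f}",
            "-" * 54,
            "branch lengths (edge above node):",
        ]
        for n in self.tree.edges():
            label = n.name if n.is_leaf else f"Node{n.node_id}"
            lines.append(f"  {label:<20s} {n.length:.6f}")
        return "\n".join(lines)

    # results-level entry points into downstream stages ----------------

    def ancestral_posteriors(self, outgroup=None, rooted_tree=None):
        """Empirical-Bayes marginal ancestral posteriors (see
        :func:`protasr.ancestral.marginal_posteriors`)."""
        from .ancestral import marginal_posteriors
        return marginal_posteriors(self, outgroup=outgroup,
                                   rooted_tree=rooted_tree)

    def branch_support(self, exact: bool = True):
        """aLRT/aLR branch support (see :func:`alrt_branch_support`)."""
        return alrt_branch_support(self, exact=exact)


# ----------------------------------------------------------------------
# model selection


def aic_select(alignment: Alignment, model_specs: list[str],
               tree: PhyloTree | None = None,
               constraint: PhyloTree | None = None,
               max_sweeps: int = 50) -> pd.DataFrame:
    """Fit each candidate model and rank by AIC.

    With ``tree`` given, each model is fitted on that fixed topology;
    otherwise an exhaustive ML search is run per model. Returns a table
    with one row per model (lnL, parameter count k, AIC = 2k - 2 lnL)
    and a ``best`` flag; ties break toward fewer parameters, then model
    name order. The fitted results are attached in ``df.attrs["results"]``.
    """
    if not model_specs:
        raise LikelihoodError("need at least one candidate model")
    rows = []
    results = {}
    for spec in model_specs:
        model = parse_model_spec(spec, alignment=alignment)
        if tree is not None:
            tl = TreeLikelihood(alignment, tree, model)
            res = tl.fit(max_sweeps=max_sweeps)
        else:
            res = exhaustive_ml_search(alignment, model,
                                       constraint=constraint,
                                       max_sweeps=max_sweeps)
        results[spec] = res
        rows.append({
            "alignment": alignment.name,
            "model": spec,
            "lnL": res.lnL,
            "k": res.n_parameters,
            "AIC": res.aic,
        })
    df = pd.DataFrame(rows)
    order = df.sort_values(["AIC", "k", "model"],
                           kind="mergesort").index
    df["best"] = False
    df.loc[order[0], "best"] = True
    df.attrs["results"] = results
    return df


def _compatible(candidate: PhyloTree, constraint: PhyloTree) -> bool:
    shared = set(candidate.leaf_names) & set(constraint.leaf_names)
    want = constraint.bipartitions(restrict=shared)
    have = candidate.bipartitions(restrict=shared)
    return want <= have


def exhaustive_ml_search(alignment: Alignment, model: SubstitutionModel,
                         constraint: PhyloTree | None = None,
                         max_taxa: int = MAX_EXHAUSTIVE_TAXA,
                         taxa: list[str] | None = None,
                         max_sweeps: int = 50) -> TreeLikelihoodResults:
    """ML tree by exhaustive enumeration of unrooted topologies.

    Every unrooted binary topology on the alignment's taxa (optionally
    filtered to those displaying all constraint-tree bipartitions) is
    fitted by :meth:`TreeLikelihood.fit`; the best lnL wins, with ties
    broken by canonical topology string. Refuses more than ``max_taxa``
    taxa — supply a tree and use fixed-topology fitting instead.

    For +G models the gamma shape is estimated on the first candidate
    topology and held fixed while the remaining topologies are scored
    (branch lengths still optimized per topology); the winning topology
    is then refitted with alpha free. The shape parameter varies little
    across topologies of the same data, so this two-phase scheme ranks
    topologies identically to the full refit at a fraction of the cost.
    """
    taxa = list(taxa) if taxa is not None else list(alignment.taxa)
    if len(taxa) > max_taxa:
        raise LikelihoodError(
            f"{len(taxa)} taxa exceed the exhaustive-search cap of "
            f"{max_taxa}; provide a tree to fit instead")
    if len(taxa) < 3:
        raise LikelihoodError("need at least 3 taxa for a tree search")
    best = None
    best_key = None
    n_evaluated = 0
    search_model = model
    for topo in enumerate_topologies(taxa):
        if constraint is not None and not _compatible(topo, constraint):
            continue
        n_evaluated += 1
        if model.alpha is not None and n_evaluated == 1:
            first = TreeLikelihood(alignment, topo, model).fit(
                max_sweeps=max_sweeps)
            search_model = first.subst_model
            res = first
        else:
            res = TreeLikelihood(alignment, topo, search_model).fit(
                optimize=("branch_lengths",), max_sweeps=max_sweeps)
        key = (-res.lnL, canonical_topology(res.tree))
        if best is None or key < best_key:
            best, best_key = res, key
    if best is None:
        raise LikelihoodError("no topology is compatible with the constraint")
    if model.alpha is not None and n_evaluated > 1:
        best = TreeLikelihood(alignment, best.tree,
                              best.subst_model).fit(max_sweeps=max_sweeps)
    best.n_topologies_evaluated = n_evaluated
    return best


# ----------------------------------------------------------------------
# branch support


def alr_transform(alrt: float) -> float:
    """aLR = exp(aLRT / 2): how many times more likely the ML tree is
    than the best alternative lacking the branch."""
    if alrt < 0:
        raise LikelihoodError(f"aLRT statistic must be >= 0, got {alrt}")
    if alrt / 2.0 > 700:  # beyond double range
        return math.inf
    return math.exp(alrt / 2.0)


@dataclass
class BranchSupportEntry:
    node_id: int
    leaf_set: frozenset
    alrt: float
    alr: float
    best_nni_topology: str


def alrt_branch_support(result: TreeLikelihoodResults,
                        exact: bool = True) -> list[BranchSupportEntry]:
    """aLRT/aLR support for every internal branch of a fitted tree.

    For each internal edge the two NNI rearrangements are refitted
    (all branch lengths when ``exact``, only the focal branch
    otherwise) and ``aLRT = 2 (lnL_ML - lnL_bestNNI)``, clipped at 0 so
    the aLR = exp(aLRT/2) >= 1 interpretation stays coherent. Supports
    are also written onto the result's tree nodes as aLR values.
    """
    tree = result.tree
    work = tree if not tree.rooted else tree.unrooted()
    out = []
    for edge in work.internal_edges():
        leafset = frozenset(l.name for l in edge.leaves())
        best_alt = None
        best_topo = ""
        for alt in nni_neighbors(work, edge.node_id):
            tl = TreeLikelihood(result.alignment, alt, result.subst_model)
            if exact:
                res = tl.fit(optimize=("branch_lengths",))
                lnl = res.lnL
            else:
                fn = tl._edge_loglik_fn(alt, result.subst_model,
                                        _find_edge(alt, leafset))
                r = minimize_scalar(lambda t: -fn(t), bounds=BL_BOUNDS,
                                    method="bounded",
                                    options={"xatol": 1e-8})
                lnl = -r.fun
            if best_alt is None or lnl > best_alt:
                best_alt = lnl
                best_topo = canonical_topology(alt)
        alrt = max(0.0, 2.0 * (result.lnL - best_alt))
        entry = BranchSupportEntry(
            node_id=edge.node_id, leaf_set=leafset,
            alrt=alrt, alr=alr_transform(alrt),
            best_nni_topology=best_topo)
        out.append(entry)
        # annotate the (possibly rooted) result tree in place
        for n in tree.base.postorder():
            if n.parent is not None and not n.is_leaf:
                names = frozenset(l.name for l in n.leaves())
                if names == leafset or \
                        names == frozenset(tree.leaf_names) - leafset:
                    n.support = entry.alr
    return out


def _find_edge(tree: PhyloTree, leafset: frozenset):
    """Edge of ``tree`` whose child-side leaves equal ``leafset`` (either
    orientation)."""
    allset = frozenset(tree.leaf_names)
    for n in tree.edges():
        names = frozenset(l.name for l in n.leaves())
        if names == leafset or names == allset - leafset:
            return n
    raise TreeError("edge not found for leaf set")
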