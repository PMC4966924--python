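"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning/outside machinery:
likelihoods and posteriors are computed by explicit summation over all
internal-state assignments, indel parsimony by enumerating all internal
labelings, and gamma category rates by adaptive quadrature.
"""

import itertools

import numpy as np
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from protasr.alignment import AA_INDEX


def _joint_tensor(aln, tree, model, col, rate):
    """Joint probability tensor over all internal-node states for one
    column at one rate, by direct multiplication of edge factors."""
    nodes = list(tree.base.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    k = len(internals)
    axis = {id(n): i for i, n in enumerate(internals)}
    shape = [20] * k

    def along(vec, ax):
        s = [1] * k
        s[ax] = 20
        return vec.reshape(s)

    joint = np.ones(shape)
    joint = joint * along(model.pi, axis[id(tree.base)])
    for n in nodes:
        if n.parent is None:
            continue
        P = model.transition_matrix(n.length or 0.0, rate)
        pax = axis[id(n.parent)]
        if n.is_leaf:
            ch = aln.row(n.name)[col - 1]
            code = AA_INDEX.get(ch)
            if code is None:  # gap or X: missing data, factor 1
                continue
            joint = joint * along(P[:, code], pax)
        else:
            nax = axis[id(n)]
            s = [1] * k
            s[pax] = 20
            s[nax] = 20
            if pax < nax:
                joint = joint * P.reshape(s)
            else:
                joint = joint * P.T.reshape(s)
    return joint, axis


def enumeration_site_loglik(aln, tree, model):
    """Per-column log-likelihood by summation over internal assignments."""
    rates = model.rate_categories.rates
    out = np.zeros(aln.ncols)
    for col in range(1, aln.ncols + 1):
        tot = 0.0
        for r in rates:
            joint, _ = _joint_tensor(aln, tree, model, col, r)
            tot += joint.sum() / len(rates)
        out[col - 1] = np.log(tot)
    return out


def enumeration_posterior(aln, tree, model, node):
    """Marginal posterior over states at one internal node, per column."""
    rates = model.rate_categories.rates
    out = np.zeros((aln.ncols, 20))
    for col in range(1, aln.ncols + 1):
        acc = np.zeros(20)
        for r in rates:
            joint, axis = _joint_tensor(aln, tree, model, col, r)
            other = tuple(i for i in range(joint.ndim)
                          if i != axis[id(node)])
            acc += joint.sum(axis=other) / len(rates)
        out[col - 1] = acc / acc.sum()
    return out


def min_indel_changes(tree, leaf_present):
    """Minimum presence-state changes over all internal labelings.

    ``leaf_present`` maps leaf name -> bool for one column.
    """
    nodes = list(tree.base.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    best = None
    for assign in itertools.product([False, True], repeat=len(internals)):
        st = {id(n): s for n, s in zip(internals, assign)}
        for n in nodes:
            if n.is_leaf:
                st[id(n)] = leaf_present[n.name]
        changes = sum(1 for n in nodes if n.parent is not None
                      and st[id(n)] != st[id(n.parent)])
        best = changes if best is None else min(best, changes)
    return best


def quadrature_gamma_rates(alpha, ncat):
    """Mean-of-band discrete gamma rates by adaptive quadrature."""
    cuts = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha,
                          scale=1.0 / alpha)
    bounds = np.concatenate(([0.0], cuts, [np.inf]))
    rates = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        val, _ = integrate.quad(
            lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1.0 / alpha),
            lo, hi)
        rates.append(val * ncat)
    rates = np.array(rates)
    return rates / rates.mean()


def random_instance(rng, n_taxa=None, with_gamma=None, ncols=5,
                    gap_prob=0.1):
    """A random small alignment + unrooted tree + model for oracle tests."""
    import protasr as pa

    n_taxa = n_taxa or int(rng.integers(3, 6))
    taxa = [f"t{i}" for i in range(n_taxa)]
    tree = pa.random_topology(taxa, rng)
    for n in tree.base.postorder():
        if n.parent is not None:
            n.length = float(rng.uniform(0.02, 1.0))
    name = ["JTT", "LG", "WAG"][int(rng.integers(3))]
    if with_gamma is None:
        with_gamma = bool(rng.integers(2))
    model = pa.build_model(
        name, alpha=float(rng.uniform(0.3, 2.0)) if with_gamma else None,
        ncat=3)
    rows = []
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in taxa:
        row = "".join(
            "-" if rng.random() < gap_prob else aas[rng.integers(20)]
            for _ in range(ncols))
        rows.append(row)
    aln = pa.Alignment(taxa, rows, name="rand")
    return aln, tree, model
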