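"""Amino-acid substitution models.

A model couples a symmetric exchangeability matrix ``S`` with
equilibrium frequencies ``pi`` to form the reversible rate matrix
``Q[i,j] = S[i,j] * pi[j]`` (off-diagonal), normalized so that
``-sum_i pi_i Q_ii = 1``: branch lengths are then expected
substitutions per site. Among-site rate variation uses the discrete
gamma approximation: ``ncat`` equal-probability categories whose rates
are the category means of a Gamma(alpha, alpha) distribution,
renormalized to mean exactly 1.

Transition probabilities ``P(t) = expm(Q t)`` are computed through the
symmetric eigendecomposition of ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``,
which is exact for reversible models and numerically stable.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from . import _ratedata
from .alignment import AMINO_ACIDS, Alignment, empirical_frequencies

_NAMES = {"JTT", "LG", "WAG"}

# reorder the published (PAML-order) constants into this package's
# alphabetical amino-acid order
_PAML_TO_LOCAL = [_ratedata.PAML_ORDER.index(aa) for aa in AMINO_ACIDS]


def _lower_to_full(lower: list[float]) -> np.ndarray:
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = lower[k]
            k += 1
    assert k == len(lower) == 190
    return S


def _reorder(S_paml: np.ndarray, pi_paml: np.ndarray):
    idx = np.array(_PAML_TO_LOCAL)
    return S_paml[np.ix_(idx, idx)], pi_paml[idx]


_EXCHANGE = {}
for _name in _NAMES:
    _S, _pi = _reorder(
        _lower_to_full(getattr(_ratedata, f"{_name}_EXCH_LOWER")),
        np.asarray(getattr(_ratedata, f"{_name}_FREQS")),
    )
    _EXCHANGE[_name] = (_S, _pi / _pi.sum())


class ModelError(ValueError):
    """Raised for invalid substitution-model construction."""


@dataclass
class RateCategories:
    """Discrete-gamma rate categories with equal probabilities."""

    rates: np.ndarray
    probabilities: np.ndarray

    @property
    def ncat(self) -> int:
        return len(self.rates)


def discrete_gamma_rates(alpha: float, ncat: int) -> RateCategories:
    """Equal-probability discrete gamma categories (category means).

    Category ``i`` covers the quantile band ``(i/ncat, (i+1)/ncat)`` of
    Gamma(alpha, rate=alpha); its rate is the conditional mean within
    the band, and the rates are rescaled so the mean is exactly 1.
    """
    if alpha <= 0:
        raise ModelError("gamma shape alpha must be > 0")
    if ncat < 1:
        raise ModelError("ncat must be >= 1")
    if ncat == 1:
        return RateCategories(np.array([1.0]), np.array([1.0]))
    probs = np.arange(1, ncat) / ncat
    cut = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate(([0.0], cut, [np.inf]))
    # E[X; a<X<b] for Gamma(alpha, rate=alpha) = I(alpha+1, alpha*b) - I(alpha+1, alpha*a)
    # (mean of the distribution is 1)
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(alpha + 1.0, alpha * bounds[1:]))
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = (upper - lower) * ncat
    rates = rates / (rates.mean())  # exact mean 1
    return RateCategories(rates, np.full(ncat, 1.0 / ncat))


class SubstitutionModel:
    """A reversible amino-acid substitution model, optionally with +G rates.

    Attributes
    ----------
    name : str
        Base matrix name ("JTT", "LG" or "WAG").
    S : (20, 20) ndarray
        Symmetric exchangeabilities.
    pi : (20,) ndarray
        Equilibrium frequencies (sum 1).
    Q : (20, 20) ndarray
        Normalized rate matrix.
    alpha : float or None
        Gamma shape; None for a uniform-rate model.
    ncat : int
        Number of discrete rate categories (1 when alpha is None).
    """

    def __init__(self, name: str, S: np.ndarray, pi: np.ndarray,
                 alpha: float | None = None, ncat: int = 1,
                 frequencies_mode: str = "model"):
        if alpha is not None and alpha <= 0:
            raise ModelError("alpha must be > 0")
        if ncat < 1:
            raise ModelError("ncat must be >= 1")
        if alpha is None:
            ncat = 1
        self.name = name
        self.S = np.asarray(S, dtype=float)
        pi = np.asarray(pi, dtype=float)
        self.pi = pi / pi.sum()
        self.alpha = alpha
        self.ncat = ncat
        self.frequencies_mode = frequencies_mode
        self.Q = self._build_q()
        self._decompose()
        if self.alpha is None or self.ncat == 1:
            self._rate_cats = RateCategories(np.array([1.0]), np.array([1.0]))
        else:
            self._rate_cats = discrete_gamma_rates(self.alpha, self.ncat)

    def _build_q(self) -> np.ndarray:
        Q = self.S * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(self.pi, np.diag(Q))
        if mu <= 0:
            raise ModelError("degenerate rate matrix (zero total rate)")
        return Q / mu

    def _decompose(self) -> None:
        sq = np.sqrt(self.pi)
        B = (self.Q / sq[None, :]) * sq[:, None]
        B = 0.5 * (B + B.T)  # enforce exact symmetry
        eigval, eigvec = np.linalg.eigh(B)
        self._eigval = eigval
        self._left = eigvec / sq[:, None]  # diag(1/sq) @ U
        self._right = eigvec.T * sq[None, :]  # U.T @ diag(sq)

    @property
    def rate_categories(self) -> RateCategories:
        return self._rate_cats

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t * rate) = expm(Q * t * rate), a row-stochastic matrix."""
        if t < 0:
            raise ModelError(f"branch length must be >= 0, got {t}")
        P = (self._left * np.exp(self._eigval * t * rate)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t * r) over all rate categories, shape (ncat, 20, 20)."""
        if t < 0:
            raise ModelError(f"branch length must be >= 0, got {t}")
        rates = self._rate_cats.rates
        expf = np.exp(self._eigval[None, :] * (t * rates)[:, None])
        P = np.einsum("ik,ck,kj->cij", self._left, expf, self._right,
                      optimize=True)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def with_alpha(self, alpha: float | None) -> "SubstitutionModel":
        """Copy of this model with a different gamma shape."""
        return SubstitutionModel(self.name, self.S, self.pi, alpha=alpha,
                                 ncat=self.ncat if alpha is not None else self.ncat,
                                 frequencies_mode=self.frequencies_mode)

    @property
    def spec(self) -> str:
        """Model spec string, e.g. ``"LG+G{alpha=0.7}"``."""
        if self.alpha is None:
            base = self.name
        else:
            base = f"{self.name}+G{self.ncat if self.ncat != 4 else ''}"
            base += f"{{alpha={self.alpha:.6g}}}"
        if self.frequencies_mode == "empirical":
            base += "+F"
        return base

    @property
    def n_free_parameters(self) -> int:
        """Model parameters beyond branch lengths (alpha; frequencies)."""
        k = 0
        if self.alpha is not None:
            k += 1
        if self.frequencies_mode == "empirical":
            k += 19
        return k

    def __repr__(self) -> str:
        return f"SubstitutionModel({self.spec})"


def build_model(name: str, frequencies_mode: str = "model",
                alignment: Alignment | None = None,
                alpha: float | None = None, ncat: int = 4) -> SubstitutionModel:
    """Construct a substitution model by name.

    Parameters
    ----------
    name : {"JTT", "LG", "WAG"}
    frequencies_mode : {"model", "empirical"}
        "model" uses the matrix's published frequencies; "empirical"
        estimates them from ``alignment`` (with a +0.25 pseudocount per
        amino acid, warning when a residue is absent).
    alpha : float, optional
        Gamma shape for +G rate heterogeneity; None means uniform rates.
    ncat : int
        Discrete gamma categories (ignored when alpha is None).
    """
    key = name.upper()
    if key not in _EXCHANGE:
        raise ModelError(f"unknown model {name!r}; choose from {sorted(_NAMES)}")
    S, pi = _EXCHANGE[key]
    if frequencies_mode == "empirical":
        if alignment is None:
            raise ModelError("empirical frequencies require an alignment")
        raw = np.zeros(20)
        for row in alignment.rows:
            for ch in row:
                if ch in AMINO_ACIDS:
                    raw[AMINO_ACIDS.index(ch)] += 1
        if (raw == 0).any():
            warnings.warn(
                "some amino acids unobserved; +0.25 pseudocount applied",
                stacklevel=2,
            )
        pi = empirical_frequencies(alignment)
    elif frequencies_mode != "model":
        raise ModelError(f"unknown frequencies_mode {frequencies_mode!r}")
    return SubstitutionModel(key, S, pi.copy(), alpha=alpha,
                             ncat=ncat if alpha is not None else 1,
                             frequencies_mode=frequencies_mode)


_SPEC_RE = re.compile(
    r"^(?P<name>[A-Za-z]+)"
    r"(?:\+G(?P<ncat>\d+)?(?:\{alpha=(?P<alpha>[0-9.eE+-]+)\})?)?"
    r"(?P<emp>\+F)?$"
)


def parse_model_spec(spec: str, alignment: Alignment | None = None,
                     default_alpha: float = 1.0,
                     default_ncat: int = 4) -> SubstitutionModel:
    """Parse a model spec string like ``"LG"``, ``"JTT+G"``, ``"WAG+G4"``
    or ``"LG+G{alpha=0.7}"`` (``+F`` appends empirical frequencies)."""
    m = _SPEC_RE.match(spec.strip())
    if m is None:
        raise ModelError(f"cannot parse model spec {spec!r}")
    has_gamma = "+G" in spec.upper().replace("+F", "")
    ncat = int(m.group("ncat")) if m.group("ncat") else default_ncat
    alpha = float(m.group("alpha")) if m.group("alpha") else (
        default_alpha if has_gamma else None)
    mode = "empirical" if m.group("emp") else "model"
    return build_model(m.group("name"), frequencies_mode=mode,
                       alignment=alignment, alpha=alpha, ncat=ncat)
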