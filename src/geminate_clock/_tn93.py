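"""Tamura–Nei (TN93) substitution model machinery.

The TN93 model distinguishes the two transition types (A<->G among
purines, C<->T among pyrimidines) from transversions and allows unequal
stationary base frequencies. We parameterize with the two
transition/transversion rate ratios ``kappa1`` (A<->G) and ``kappa2``
(C<->T) relative to a unit transversion rate, and normalize the rate
matrix to one expected substitution per site per unit branch length.

Transition probabilities are computed from the eigendecomposition of
the (reversible) rate matrix, which vectorizes cleanly over branch
lengths and gamma rate categories.

State order everywhere: A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: integer code for anything that is not an unambiguous base
MISSING = 4

_ENCODE = np.full(128, MISSING, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i


def encode(residues: str) -> np.ndarray:
    """Residue string -> int8 codes (A,C,G,T -> 0..3, everything else 4)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


@dataclass(frozen=True)
class TN93Params:
    """Shared substitution parameters: base frequencies and rate ratios."""

    pi: tuple[float, float, float, float]  # A, C, G, T
    kappa1: float  # A<->G transition / transversion rate ratio
    kappa2: float  # C<->T transition / transversion rate ratio
    gamma_shape: float | None = None  # None => rate homogeneity

    def __post_init__(self):
        pi = np.asarray(self.pi, float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError(f"invalid base frequencies {self.pi}")
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("rate ratios must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")


def rate_matrix(params: TN93Params) -> np.ndarray:
    """Normalized TN93 rate matrix (expected 1 substitution/site/unit t)."""
    pi = np.asarray(params.pi, float)
    rel = np.ones((4, 4))
    rel[0, 2] = rel[2, 0] = params.kappa1  # A<->G
    rel[1, 3] = rel[3, 1] = params.kappa2  # C<->T
    q = rel * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -np.dot(pi, np.diag(q))
    return q / mu


class TN93Model:
    """Eigendecomposed TN93 model; fast P(t) for arrays of branch lengths."""

    def __init__(self, params: TN93Params):
        self.params = params
        self.pi = np.asarray(params.pi, float)
        self.q = rate_matrix(params)
        # reversible Q: symmetrize with sqrt(pi) similarity, use eigh
        sqrt_pi = np.sqrt(self.pi)
        sym = sqrt_pi[:, None] * self.q / sqrt_pi[None, :]
        sym = 0.5 * (sym + sym.T)
        w, v = np.linalg.eigh(sym)
        # P(t) = D^{-1/2} V e^{wt} V^T D^{1/2}  with D = diag(pi)
        self._eigval = w
        self._u = v / sqrt_pi[:, None]
        self._uinv = (v * sqrt_pi[:, None]).T

    def transition_probs(self, t) -> np.ndarray:
        """P(t) for scalar or array ``t``; returns (..., 4, 4)."""
        t = np.asarray(t, float)
        expwt = np.exp(np.multiply.outer(t, self._eigval))  # (..., 4)
        p = np.einsum("ik,...k,kj->...ij", self._u, expwt, self._uinv)
        return np.clip(p, 0.0, None)


def empirical_frequencies(codes: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Pooled base frequencies over all unambiguous sites of all sequences."""
    counts = np.bincount(codes[codes < 4].ravel(), minlength=4).astype(float)
    counts += pseudocount
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous bases; cannot estimate frequencies")
    return counts / total


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability categories of Gamma(alpha, 1/alpha).

    The standard discretization for among-site rate heterogeneity: category
    boundaries at quantiles i/k, category rate = conditional mean, so the
    overall mean rate is exactly 1.
    """
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([alpha * bounds, [np.inf]])
    lower = np.concatenate([[0.0], alpha * bounds])
    mass = gammainc(alpha + 1.0, np.where(np.isinf(upper), 1e300, upper)) - gammainc(
        alpha + 1.0, lower
    )
    return k * mass
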