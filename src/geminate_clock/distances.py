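"""Pairwise genetic distances with pairwise deletion.

Three estimators are provided:

``p``
    Uncorrected proportion of differing sites.
``tn93``
    Closed-form Tamura–Nei (1993) distance per pair, using that pair's
    pooled base frequencies.
``mcl``
    Composite-likelihood TN93 distances: the two transition/transversion
    rate ratios are shared across all pairs and estimated by maximizing
    the sum of pairwise log-likelihoods (base frequencies are the pooled
    empirical frequencies); each pairwise distance is then the ML branch
    length under those shared parameters. This mirrors the
    maximum-composite-likelihood approach of distance software such as
    MEGA.

All estimators use pairwise deletion: for each pair independently,
alignment columns where either sequence has a gap or an ambiguous base
are excluded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._tn93 import TN93Model, TN93Params, empirical_frequencies, encode
from .alignment import Alignment, GroupPartition
from .errors import DistanceError, OptimizationError, PartitionError, SaturationError

__all__ = [
    "DistanceMatrix",
    "DivergenceSummary",
    "pairwise_valid_sites",
    "p_distance",
    "tn93_distance",
    "tn93_distances",
    "p_distances",
    "mcl_distances",
    "summarize_divergence",
]

_MAX_BRANCH = 12.0  # ML distances at this bound are treated as saturated


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix (substitutions/site)."""

    ids: tuple[str, ...]
    d: np.ndarray
    model: str  # "p", "tn93" or "mcl"

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        d = np.asarray(self.d, float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise DistanceError(f"matrix shape {d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(d)):
            raise DistanceError("non-finite distances")
        if np.any(d < 0):
            raise DistanceError("negative distances")
        if not np.allclose(d, d.T, atol=1e-12):
            raise DistanceError("matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise DistanceError("non-zero diagonal")
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        d.flags.writeable = False
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.ids)

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.d[np.ix_(idx, idx)], self.model)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids)).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, model: str = "mcl") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise DistanceError(f"{path}: row and column IDs differ")
        return cls(tuple(str(i) for i in df.index), df.to_numpy(float), model)


# ---------------------------------------------------------------------------
# per-pair primitives


def _check_equal_length(a: str, b: str) -> None:
    if len(a) != len(b):
        raise DistanceError(f"sequence lengths differ: {len(a)} vs {len(b)}")


def pairwise_valid_sites(a: str, b: str) -> frozenset[int]:
    """1-based column indices where both residues are unambiguous bases."""
    _check_equal_length(a, b)
    ca, cb = encode(a), encode(b)
    return frozenset((np.nonzero((ca < 4) & (cb < 4))[0] + 1).tolist())


def _pair_counts(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """4x4 site-pattern count matrix after pairwise deletion."""
    mask = (ca < 4) & (cb < 4)
    if not mask.any():
        return np.zeros((4, 4))
    idx = ca[mask].astype(np.int64) * 4 + cb[mask]
    return np.bincount(idx, minlength=16).reshape(4, 4).astype(float)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among pairwise-valid sites."""
    _check_equal_length(a, b)
    f = _pair_counts(encode(a), encode(b))
    n = f.sum()
    if n == 0:
        raise DistanceError("no shared unambiguous sites; p-distance undefined")
    return float((n - np.trace(f)) / n)


def _tn93_from_counts(f: np.ndarray, id_a: str = "a", id_b: str = "b") -> float:
    """Closed-form TN93 distance from a 4x4 pair count matrix.

    Uses the pair's pooled base frequencies. Raises SaturationError when
    any logarithm argument is non-positive.
    """
    n = f.sum()
    if n == 0:
        raise DistanceError("no shared unambiguous sites; TN93 distance undefined")
    # pooled frequencies across both members of the pair
    counts = f.sum(axis=1) + f.sum(axis=0)
    pi = counts / counts.sum()
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    p1 = (f[0, 2] + f[2, 0]) / n  # A<->G transitions
    p2 = (f[1, 3] + f[3, 1]) / n  # C<->T transitions
    q = (n - np.trace(f)) / n - p1 - p2  # transversions

    d = 0.0
    # purine-transition term
    if pa * pg > 0 and pr > 0:
        arg1 = 1.0 - pr * p1 / (2.0 * pa * pg) - q / (2.0 * pr)
        if arg1 <= 0:
            raise SaturationError(id_a, id_b, "purine transition term")
        d -= (2.0 * pa * pg / pr) * math.log(arg1)
    elif p1 > 0:
        raise SaturationError(id_a, id_b, "A/G transitions with zero purine product")
    # pyrimidine-transition term
    if pt * pc > 0 and py > 0:
        arg2 = 1.0 - py * p2 / (2.0 * pt * pc) - q / (2.0 * py)
        if arg2 <= 0:
            raise SaturationError(id_a, id_b, "pyrimidine transition term")
        d -= (2.0 * pt * pc / py) * math.log(arg2)
    elif p2 > 0:
        raise SaturationError(id_a, id_b, "C/T transitions with zero pyrimidine product")
    # transversion term
    if pr * py > 0:
        arg3 = 1.0 - q / (2.0 * pr * py)
        if arg3 <= 0:
            raise SaturationError(id_a, id_b, "transversion term")
        coef = pr * py
        if pr > 0:
            coef -= pa * pg * py / pr
        if py > 0:
            coef -= pt * pc * pr / py
        d -= 2.0 * coef * math.log(arg3)
    elif q > 0:
        raise SaturationError(id_a, id_b, "transversions with zero purine*pyrimidine")
    return max(d, 0.0)


def tn93_distance(a: str, b: str) -> float:
    """Closed-form Tamura–Nei distance for one pair (pairwise deletion)."""
    _check_equal_length(a, b)
    return _tn93_from_counts(_pair_counts(encode(a), encode(b)))


# ---------------------------------------------------------------------------
# alignment-level matrices


def _encoded(aln: Alignment) -> np.ndarray:
    return np.stack([encode(r.residues) for r in aln.records])


def _all_pair_counts(codes: np.ndarray) -> tuple[list[tuple[int, int]], np.ndarray]:
    n = codes.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    f = np.empty((len(pairs), 4, 4))
    for k, (i, j) in enumerate(pairs):
        f[k] = _pair_counts(codes[i], codes[j])
    return pairs, f


def p_distances(aln: Alignment) -> DistanceMatrix:
    """Matrix of uncorrected p-distances."""
    codes = _encoded(aln)
    pairs, f = _all_pair_counts(codes)
    n_sites = f.sum(axis=(1, 2))
    if np.any(n_sites == 0):
        k = int(np.argmax(n_sites == 0))
        i, j = pairs[k]
        raise DistanceError(
            f"no shared unambiguous sites for pair ({aln.ids[i]}, {aln.ids[j]})"
        )
    diffs = n_sites - np.trace(f, axis1=1, axis2=2)
    return _matrix_from_pairs(aln.ids, pairs, diffs / n_sites, "p")


def tn93_distances(aln: Alignment) -> DistanceMatrix:
    """Matrix of per-pair closed-form TN93 distances."""
    codes = _encoded(aln)
    pairs, f = _all_pair_counts(codes)
    vals = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        vals[k] = _tn93_from_counts(f[k], aln.ids[i], aln.ids[j])
    return _matrix_from_pairs(aln.ids, pairs, vals, "tn93")


def _matrix_from_pairs(ids, pairs, vals, model) -> DistanceMatrix:
    n = len(ids)
    d = np.zeros((n, n))
    for (i, j), v in zip(pairs, vals):
        d[i, j] = d[j, i] = v
    return DistanceMatrix(tuple(ids), d, model)


def _pair_logliks(model: TN93Model, f: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Composite log-likelihood of each pair at its branch length ``t``."""
    p = model.transition_probs(t)  # (m, 4, 4)
    joint = model.pi[None, :, None] * p
    with np.errstate(divide="ignore"):
        logj = np.log(joint)
    logj[joint <= 0] = -1e30  # only multiplied by zero counts at t>0
    return np.einsum("mxy,mxy->m", f, logj)


def _profile_distances(model: TN93Model, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized golden-section maximization of each pair's likelihood."""
    m = f.shape[0]
    lo = np.zeros(m)
    hi = np.full(m, _MAX_BRANCH)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1 = _pair_logliks(model, f, x1)
    f2 = _pair_logliks(model, f, x2)
    for _ in range(60):
        right = f1 < f2  # maximum lies in [x1, hi]
        lo = np.where(right, x1, lo)
        hi = np.where(right, hi, x2)
        x_keep = np.where(right, x2, x1)  # interior point that survives
        f_keep = np.where(right, f2, f1)
        x1_new = hi - invphi * (hi - lo)
        x2_new = lo + invphi * (hi - lo)
        x_eval = np.where(right, x2_new, x1_new)
        f_eval = _pair_logliks(model, f, x_eval)
        x1 = np.where(right, x_keep, x_eval)
        f1 = np.where(right, f_keep, f_eval)
        x2 = np.where(right, x_eval, x_keep)
        f2 = np.where(right, f_eval, f_keep)
    t_hat = 0.5 * (lo + hi)
    # identical pairs sit at the t=0 boundary
    ll = _pair_logliks(model, f, t_hat)
    ll0 = _pair_logliks(model, f, np.full(m, 1e-12))
    at_zero = ll0 >= ll
    t_hat = np.where(at_zero, 0.0, t_hat)
    ll = np.where(at_zero, ll0, ll)
    return t_hat, ll


def mcl_distances(aln: Alignment, *, return_params: bool = False):
    """Composite-likelihood TN93 distance matrix with shared parameters.

    The two transition/transversion ratios are shared across pairs and
    chosen to maximize the summed pairwise log-likelihoods; base
    frequencies are pooled empirical frequencies (not optimized).
    """
    if len(aln) < 2:
        raise DistanceError("need at least two sequences")
    codes = _encoded(aln)
    pi = empirical_frequencies(codes, pseudocount=1.0)
    pairs, f = _all_pair_counts(codes)
    n_sites = f.sum(axis=(1, 2))
    if np.any(n_sites == 0):
        k = int(np.argmax(n_sites == 0))
        i, j = pairs[k]
        raise DistanceError(
            f"no shared unambiguous sites for pair ({aln.ids[i]}, {aln.ids[j]})"
        )

    off_diag = n_sites - np.trace(f, axis1=1, axis2=2)
    if off_diag.sum() == 0:  # no variation anywhere
        zeros = np.zeros((len(aln), len(aln)))
        dm = DistanceMatrix(tuple(aln.ids), zeros, "mcl")
        if return_params:
            return dm, TN93Params(tuple(pi), 1.0, 1.0)
        return dm

    def neg_profile(logk: np.ndarray) -> float:
        k1, k2 = np.exp(np.clip(logk, -6, 8))
        model = TN93Model(TN93Params(tuple(pi), float(k1), float(k2)))
        _, ll = _profile_distances(model, f)
        return -float(ll.sum())

    res = minimize(
        neg_profile,
        x0=np.log([4.0, 4.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 300},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter, still usable
        raise OptimizationError(f"composite-likelihood fit failed: {res.message}")
    k1, k2 = np.exp(np.clip(res.x, -6, 8))
    params = TN93Params(tuple(pi), float(k1), float(k2))
    model = TN93Model(params)
    t_hat, _ = _profile_distances(model, f)
    sat = t_hat >= _MAX_BRANCH * 0.99
    if np.any(sat):
        k = int(np.argmax(sat))
        i, j = pairs[k]
        raise SaturationError(aln.ids[i], aln.ids[j], "ML distance at upper bound")
    dm = _matrix_from_pairs(aln.ids, pairs, t_hat, "mcl")
    if return_params:
        return dm, params
    return dm


# ---------------------------------------------------------------------------
# divergence summaries


@dataclass(frozen=True)
class DivergenceSummary:
    """(mean, min, max) of pairwise distances within and between groups.

    ``overall_within_species`` pools *all* pairs in the matrix — the
    convention used when a nominal species spans both groups, so basin
    comparisons contribute to the "intraspecific" range.
    """

    within: Mapping[str, tuple[float, float, float] | None]
    between: Mapping[tuple[str, str], tuple[float, float, float]]
    overall_within_species: tuple[float, float, float] | None

    def min_between(self, g1: str, g2: str) -> float:
        key = (g1, g2) if (g1, g2) in self.between else (g2, g1)
        return self.between[key][1]


def _stats(vals: list[float]) -> tuple[float, float, float] | None:
    if not vals:
        return None
    arr = np.asarray(vals)
    return (float(arr.mean()), float(arr.min()), float(arr.max()))


def summarize_divergence(dm: DistanceMatrix, part: GroupPartition) -> DivergenceSummary:
    """Within/between-group divergence statistics over unordered pairs."""
    unlabeled = [s for s in dm.ids if s not in part]
    if unlabeled:
        raise PartitionError(f"samples missing group labels: {unlabeled}")
    groups = [g for g in part.groups if any(part.group(s) == g for s in dm.ids)]
    within: dict[str, tuple[float, float, float] | None] = {}
    between: dict[tuple[str, str], tuple[float, float, float]] = {}
    all_vals: list[float] = []
    by_group: dict[str, list[int]] = {g: [] for g in groups}
    for idx, s in enumerate(dm.ids):
        by_group[part.group(s)].append(idx)
    for i, j in itertools.combinations(range(len(dm.ids)), 2):
        all_vals.append(float(dm.d[i, j]))
    for g in groups:
        vals = [float(dm.d[i, j]) for i, j in itertools.combinations(by_group[g], 2)]
        within[g] = _stats(vals)
    for g1, g2 in itertools.combinations(groups, 2):
        vals = [float(dm.d[i, j]) for i in by_group[g1] for j in by_group[g2]]
        if vals:
            between[(g1, g2)] = _stats(vals)
    return DivergenceSummary(within, between, _stats(all_vals))
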