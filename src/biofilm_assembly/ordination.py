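"""Distance-matrix PERMANOVA and principal coordinate analysis.

PERMANOVA partitions the squared dissimilarities of a distance matrix among
``a`` groups via the distance-based identity (no coordinate embedding):

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    F = (SS_between / (a - 1)) / (SS_within / (N - a)),  R^2 = SS_between/SS_total

with a permutation p-value using the +1 convention
``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``; when the number of distinct
label arrangements is small enough they are enumerated exhaustively and
``p = #{F_perm >= F_obs} / n_distinct`` (the identity arrangement included).

PCoA (classical metric MDS) double-centers the squared distances,
``B = -1/2 * J D^2 J``, and eigendecomposes ``B``; coordinates are
eigenvectors scaled by the square roots of the non-negative eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.base import BaseEstimator

from .io import DistanceMatrix


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None
    ss_total: float
    ss_within: float
    ss_between: float


def _as_square(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return d.values
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("expected a square distance matrix")
    return d


def _ss_within_batch(d2: np.ndarray, onehot: np.ndarray, group_sizes: np.ndarray) -> np.ndarray:
    """SS_within for a batch of label arrangements.

    ``onehot`` has shape (n_perm, N, a); within-group sums of d^2 come out of
    one einsum: for each arrangement and group, z^T D2 z = 2 * sum_{i<j in g} d2.
    """
    q = np.einsum("pig,ij,pjg->pg", onehot, d2, onehot)
    return (q / (2.0 * group_sizes[None, :])).sum(axis=1)


def _multiset_permutations(labels: np.ndarray):
    """All distinct arrangements of a label multiset (recursive enumeration)."""
    values, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    out = []
    arrangement = np.empty(n, dtype=labels.dtype)

    def rec(pos, remaining):
        if pos == n:
            out.append(arrangement.copy())
            return
        for v in range(len(values)):
            if remaining[v] > 0:
                remaining[v] -= 1
                arrangement[pos] = values[v]
                rec(pos + 1, remaining)
                remaining[v] += 1

    rec(0, counts.copy())
    return np.array(out)


def n_distinct_arrangements(labels) -> int:
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    n = int(counts.sum())
    total = 1
    for c in counts:
        total *= comb(n, c)
        n -= c
    return total


def permanova(
    d,
    groups,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    Permutations are unrestricted label shuffles; when the number of distinct
    arrangements is <= ``n_perm`` they are enumerated exhaustively instead.
    """
    dm = _as_square(d)
    labels = np.asarray(list(groups))
    N = dm.shape[0]
    if len(labels) != N:
        raise ValueError("group labels do not match the distance matrix")
    values, counts = np.unique(labels, return_counts=True)
    a = len(values)
    if a < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        small = values[counts < 2]
        raise ValueError(f"groups with a single sample: {list(small)}")

    d2 = dm**2
    ss_total = d2[np.triu_indices(N, k=1)].sum() / N

    def onehot_of(lbls: np.ndarray) -> np.ndarray:
        z = np.zeros((len(lbls), N, a))
        for g, v in enumerate(values):
            z[:, :, g] = lbls == v
        return z

    obs_sw = float(_ss_within_batch(d2, onehot_of(labels[None, :]), counts)[0])
    ss_between = ss_total - obs_sw
    if obs_sw <= 0 and ss_between <= 0:
        raise ValueError("degenerate distance matrix: zero within and between SS")
    df_b, df_w = a - 1, N - a

    def f_of(sw: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return ((ss_total - sw) / df_b) / (sw / df_w)

    f_obs = float(f_of(np.array([obs_sw]))[0])

    n_distinct = n_distinct_arrangements(labels)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        perms = _multiset_permutations(labels)
        sw = _ss_within_batch(d2, onehot_of(perms), counts)
        f_perm = f_of(sw)
        p = float((f_perm >= f_obs - 1e-12).sum() / n_distinct)
        n_used = n_distinct
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
        sw = _ss_within_batch(d2, onehot_of(perms), counts)
        f_perm = f_of(sw)
        p = float((1 + (f_perm >= f_obs - 1e-12).sum()) / (1 + n_perm))
        n_used = n_perm

    return PermanovaResult(
        pseudo_F=f_obs,
        r_squared=float(ss_between / ss_total),
        p_value=p,
        n_permutations=n_used,
        exhaustive=exhaustive,
        seed=seed,
        ss_total=float(ss_total),
        ss_within=float(obs_sw),
        ss_between=float(ss_between),
    )


# ---------------------------------------------------------------------- PCoA

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes, centered
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues
    negative_eigenvalues: np.ndarray


class PCoA(BaseEstimator):
    """Principal coordinate analysis (classical metric MDS).

    Negative eigenvalues (from non-Euclidean dissimilarities) are reported
    and their axes dropped.  ``fit`` accepts a square distance matrix or a
    :class:`~biofilm_assembly.io.DistanceMatrix`.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        dm = _as_square(X)
        ids = X.sample_ids if isinstance(X, DistanceMatrix) else list(range(dm.shape[0]))
        n = dm.shape[0]
        if self.n_components > n - 1:
            raise ValueError("n_components must be <= n_samples - 1")
        d2 = dm**2
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        B = -0.5 * J @ d2 @ J
        evals, evecs = eigh((B + B.T) / 2.0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        tol = max(1e-12, 1e-10 * max(abs(evals[0]), 1.0))
        pos = evals > tol
        if not pos.any():
            import warnings

            warnings.warn("all-zero distance matrix: returning a single zero axis")
            coords = np.zeros((n, 1))
            self.coordinates_ = pd.DataFrame(coords, index=ids, columns=["PC1"])
            self.eigenvalues_ = evals
            self.proportion_explained_ = np.array([0.0])
            self.negative_eigenvalues_ = evals[evals < -tol]
            return self
        k = min(self.n_components, int(pos.sum()))
        lam = evals[:k]
        coords = evecs[:, :k] * np.sqrt(lam)[None, :]
        coords -= coords.mean(axis=0)  # numerically recenter
        self.coordinates_ = pd.DataFrame(
            coords, index=ids, columns=[f"PC{i + 1}" for i in range(k)]
        )
        self.eigenvalues_ = evals
        self.proportion_explained_ = lam / evals[pos].sum()
        self.negative_eigenvalues_ = evals[evals < -tol]
        return self

    def transform(self, X=None):
        return self.coordinates_.to_numpy()

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()

    def result(self) -> PCoAResult:
        return PCoAResult(
            coordinates=self.coordinates_,
            eigenvalues=self.eigenvalues_,
            proportion_explained=self.proportion_explained_,
            negative_eigenvalues=self.negative_eigenvalues_,
        )


def pcoa(d, n_axes: int = 2) -> PCoAResult:
    """Functional wrapper over :class:`PCoA`."""
    return PCoA(n_components=n_axes).fit(d).result()
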