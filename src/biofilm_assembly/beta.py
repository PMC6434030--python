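"""Sørensen beta diversity and its turnover / nestedness partition.

For one sample pair with ``a`` shared taxa and ``b``, ``c`` taxa unique to
either sample (presence/absence after rarefaction):

    beta_sor = (b + c) / (2a + b + c)                 total dissimilarity
    beta_sim = min(b, c) / (a + min(b, c))            turnover (replacement)
    beta_sne = beta_sor - beta_sim                    nestedness-resultant

so that ``beta_sim + beta_sne == beta_sor`` exactly.  The beta ratio
``beta_sne / beta_sor`` is the dominance statistic: below 0.5 beta diversity
is dominated by turnover, above 0.5 by nestedness.  Summaries are produced
separately for within-group-1, within-group-2 and between-group pair sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import CommunityTable, DistanceMatrix, PairwiseComposition


def pair_composition(x, y) -> PairwiseComposition:
    """Incidence components (a, b, c) of two count/presence vectors."""
    x = np.asarray(x) > 0
    y = np.asarray(y) > 0
    if x.shape != y.shape:
        raise ValueError("presence vectors must cover the same taxon set")
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    return PairwiseComposition(a, b, c)  # raises if both samples empty


def baselga_partition(pc: PairwiseComposition) -> tuple[float, float, float]:
    """(beta_sor, beta_sim, beta_sne) of one pair; identical samples give zeros."""
    a, b, c = pc.a, pc.b, pc.c
    bmin = min(b, c)
    sor = (b + c) / (2 * a + b + c)
    sim = bmin / (a + bmin) if (a + bmin) > 0 else 0.0
    return sor, sim, sor - sim


def _pairwise_matrices(incidence: np.ndarray):
    """Vectorized beta_sor / beta_sim / beta_sne over all sample pairs."""
    B = incidence.astype(np.int64)
    A = B @ B.T  # shared taxa a
    r = B.sum(axis=1)
    b = r[:, None] - A
    c = r[None, :] - A
    with np.errstate(divide="ignore", invalid="ignore"):
        sor = (b + c) / (2 * A + b + c)
        bmin = np.minimum(b, c)
        sim = np.where(A + bmin > 0, bmin / (A + bmin), 0.0)
    np.fill_diagonal(sor, 0.0)
    np.fill_diagonal(sim, 0.0)
    sne = sor - sim
    return sor, sim, sne


class SorensenPartition(BaseEstimator):
    """Estimator computing the pairwise Sørensen matrices of a count table.

    After :meth:`fit`, the attributes ``sor_``, ``sim_`` and ``sne_`` hold the
    full symmetric dissimilarity matrices (total, turnover, nestedness).
    :meth:`transform` returns ``sor_`` for pipeline composition.
    """

    def fit(self, X, y=None):
        if isinstance(X, CommunityTable):
            X = X.counts
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("need >= 2 samples for pairwise dissimilarity")
        if ((X.to_numpy() > 0).sum(axis=1) == 0).any():
            raise ValueError("empty sample in presence matrix")
        self.sample_ids_ = list(X.index)
        self.sor_, self.sim_, self.sne_ = _pairwise_matrices(X.to_numpy() > 0)
        return self

    def transform(self, X=None):
        return self.sor_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()


@dataclass
class PartitionResult:
    """Three dissimilarity matrices plus pair-set summaries.

    ``summaries`` has one row per pair set (within each group, between) with
    mean beta_sor/beta_sim/beta_sne, the beta ratio computed from the
    pair-set means (authoritative) and the mean of pairwise ratios
    (reported for comparison; unstable when beta_sor is near 0).
    """

    sor: DistanceMatrix
    sim: DistanceMatrix
    sne: DistanceMatrix
    summaries: pd.DataFrame


def _pair_set_masks(groups: pd.Series) -> dict[str, np.ndarray]:
    labels = groups.to_numpy()
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    masks: dict[str, np.ndarray] = {}
    seen: list[str] = []
    for g in labels:
        if g not in seen:
            seen.append(g)
    for g in seen:
        masks[f"within_{g}"] = same & (labels[iu[0]] == g)
    masks["between"] = ~same
    return masks


def partition_table(table: CommunityTable) -> PartitionResult:
    """Full pairwise partition plus within/between pair-set summaries."""
    sor, sim, sne = _pairwise_matrices(table.incidence())
    ids = table.sample_ids
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    rows = []
    for name, mask in _pair_set_masks(table.groups).items():
        if mask.sum() == 0:
            rows.append(
                {"pair_set": name, "n_pairs": 0, "mean_sor": np.nan,
                 "mean_sim": np.nan, "mean_sne": np.nan,
                 "beta_ratio": np.nan, "mean_pairwise_ratio": np.nan}
            )
            continue
        s, t, u = sor[iu][mask], sim[iu][mask], sne[iu][mask]
        mean_sor = float(s.mean())
        ratio = float(u.mean() / mean_sor) if mean_sor > 0 else np.nan
        nz = s > 0
        mean_pw = float((u[nz] / s[nz]).mean()) if nz.any() else np.nan
        rows.append(
            {"pair_set": name, "n_pairs": int(mask.sum()), "mean_sor": mean_sor,
             "mean_sim": float(t.mean()), "mean_sne": float(u.mean()),
             "beta_ratio": ratio, "mean_pairwise_ratio": mean_pw}
        )
    return PartitionResult(
        sor=DistanceMatrix(ids, sor, "sorensen"),
        sim=DistanceMatrix(ids, sim, "simpson_turnover"),
        sne=DistanceMatrix(ids, sne, "nestedness_component"),
        summaries=pd.DataFrame(rows).set_index("pair_set"),
    )
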