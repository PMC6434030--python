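"""Rarefaction and Hill-number alpha diversity.

Alpha diversity is reported as the first two Hill numbers — richness ``0D``
(taxa with count > 0) and ``1D`` (the exponential of Shannon entropy, i.e.
the effective number of equally-abundant taxa) — plus evenness ``1D/0D``.
Counts are subsampled to even depth (rarefied, without replacement) first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CommunityTable


@dataclass
class AlphaResult:
    """Per-sample Hill diversity at a common rarefaction depth."""

    table: pd.DataFrame  # columns: richness_0d, diversity_1d, evenness
    rarefaction_depth: int
    seed: int | None


def _as_counts(X) -> tuple[np.ndarray, pd.Index | None, pd.Index | None]:
    if isinstance(X, CommunityTable):
        X = X.counts
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(), X.index, X.columns
    arr = np.asarray(X)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D samples x taxa count array")
    return arr, None, None


class Rarefier(BaseEstimator, TransformerMixin):
    """Subsample every sample to a common depth without replacement.

    Parameters
    ----------
    depth : int or "min"
        Target reads per sample; ``"min"`` uses the smallest sample total of
        the data seen by :meth:`fit`.
    random_state : int
        Seed of the subsampling; a required, logged parameter so results are
        reproducible (a single draw is taken, not an average over repeats).
    """

    def __init__(self, depth="min", random_state: int = 0):
        self.depth = depth
        self.random_state = random_state

    def fit(self, X, y=None):
        counts, _, _ = _as_counts(X)
        totals = counts.sum(axis=1)
        if self.depth == "min":
            self.depth_ = int(totals.min())
        else:
            self.depth_ = int(self.depth)
        if self.depth_ < 1:
            raise ValueError("rarefaction depth must be >= 1")
        return self

    def transform(self, X):
        counts, index, columns = _as_counts(X)
        if not hasattr(self, "depth_"):
            raise RuntimeError("Rarefier is not fitted")
        totals = counts.sum(axis=1)
        if (totals < self.depth_).any():
            i = int(np.argmin(totals))
            name = index[i] if index is not None else i
            raise ValueError(
                f"sample {name!r} has only {totals[i]} reads "
                f"(< depth {self.depth_})"
            )
        rng = np.random.default_rng(self.random_state)
        out = np.empty_like(counts)
        for i in range(counts.shape[0]):
            # multivariate hypergeometric == subsampling without replacement
            out[i] = rng.multivariate_hypergeometric(counts[i], self.depth_)
        if index is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out


class HillDiversity(BaseEstimator, TransformerMixin):
    """Per-sample Hill numbers: richness ``0D``, ``1D = exp(Shannon)``, evenness."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        counts, index, _ = _as_counts(X)
        totals = counts.sum(axis=1)
        if (totals < 1).any():
            raise ValueError("every sample must have total count >= 1")
        d0 = (counts > 0).sum(axis=1).astype(float)
        p = counts / totals[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        d1 = np.exp(-plogp.sum(axis=1))
        res = pd.DataFrame(
            {"richness_0d": d0, "diversity_1d": d1, "evenness": d1 / d0},
            index=index if index is not None else range(counts.shape[0]),
        )
        return res


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Rarefy a :class:`CommunityTable` to ``depth`` reads per sample."""
    r = Rarefier(depth=depth, random_state=seed).fit(table.counts)
    # rarefaction can zero out rare taxa; keep them as columns are dropped
    return CommunityTable(r.transform(table.counts), table.groups, quiet=True)


def hill_numbers(table: CommunityTable) -> pd.DataFrame:
    """Hill numbers per sample of an (already rarefied) table."""
    return HillDiversity().transform(table.counts)


def alpha_diversity(
    table: CommunityTable, depth: int | str = "min", seed: int = 0
) -> AlphaResult:
    """Rarefy to even depth (default: the minimum sample total) and compute
    Hill-number diversity per sample."""
    r = Rarefier(depth=depth, random_state=seed).fit(table.counts)
    rarefied = r.transform(table.counts)
    res = HillDiversity().transform(rarefied)
    res.insert(0, "group", table.groups.values)
    return AlphaResult(table=res, rarefaction_depth=r.depth_, seed=seed)
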