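"""Null models for deterministic vs stochastic community assembly.

Two complementary null models are provided:

* **Quasiswap / SES** — incidence matrices are randomized preserving every
  sample's richness (row sums) and every taxon's incidence (column sums);
  the standardized effect size of the pairwise Sørensen dissimilarity,
  ``SES = (obs - null mean) / null sd``, flags pairs more (or less)
  dissimilar than expected by chance; ``|SES| > 2`` (about a 95% interval)
  is the deterministic-assembly criterion.  Within-group analyses restrict
  the regional pool to taxa present in that group before randomizing.

* **Raup–Crick Bray–Curtis (RC_bray)** — abundance-based: null samples are
  reassembled preserving each sample's observed richness and total reads,
  drawing taxa without replacement weighted by their occurrence frequency
  and filling abundances multinomially weighted by regional relative
  abundance; ``RC = 2 * (n_below + 0.5 * n_equal) / n_reps - 1`` lies in
  [-1, 1] and ``|RC| > 0.95`` flags deviation from the stochastic
  expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._swap import null_replicate, seed_numba
from .io import CommunityTable

DEFAULT_REPS = 999
SES_THRESHOLD = 2.0
RC_THRESHOLD = 0.95
BURNIN_FACTOR = 10  # burn-in swap attempts = 10 x matrix fill


def derive_seed(seed: int, salt: str) -> int:
    """Stable sub-seed below 2**31 from a master seed and a stage label."""
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, abs(hash_stable(salt))])
    return int(ss.generate_state(1)[0] % (2**31))


def hash_stable(text: str) -> int:
    """Deterministic (process-independent) 32-bit hash of a string."""
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y) of two count vectors."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    den = int(x.sum() + y.sum())
    if den == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / den)


# ----------------------------------------------------------------- quasiswap

@dataclass
class NullEnsemble:
    """Quasiswap null ensemble: per-pair Sørensen null samples (and marginals)."""

    n_reps: int
    seed: int
    row_sums: np.ndarray
    col_sums: np.ndarray
    sor_null: np.ndarray  # (n_reps, n_pairs) in upper-triangle order
    burnin_factor: int
    matrices: list[np.ndarray] | None = None


def _pair_sor(incidence: np.ndarray, iu) -> np.ndarray:
    """Condensed pairwise Sørensen of a binary matrix; row sums enter the
    denominator so quasiswap nulls vary only through shared-taxon counts."""
    B = incidence.astype(np.int64)
    shared = B @ B.T
    r = B.sum(axis=1)
    denom = r[iu[0]] + r[iu[1]]
    return 1.0 - 2.0 * shared[iu] / denom


def quasiswap(
    incidence,
    n_reps: int = DEFAULT_REPS,
    seed: int = 0,
    return_matrices: bool = False,
    max_iter: int = 10_000_000,
) -> NullEnsemble:
    """Generate ``n_reps`` marginal-preserving binary null matrices.

    Every replicate has exactly the observed row sums (sample richness) and
    column sums (taxon incidence).
    """
    inc = (np.asarray(incidence) > 0).astype(np.int64)
    if inc.ndim != 2:
        raise ValueError("incidence must be a 2-D matrix")
    row_sums = inc.sum(axis=1)
    col_sums = inc.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError("incidence matrix has an all-zero row or column")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = inc.shape[0]
    iu = np.triu_indices(n, k=1)
    sor_null = np.empty((n_reps, len(iu[0])))
    mats = [] if return_matrices else None
    seed_numba(seed & 0x7FFFFFFF)
    for rep in range(n_reps):
        m, status = null_replicate(row_sums, col_sums, BURNIN_FACTOR, max_iter)
        if status < 0:
            raise RuntimeError(
                f"quasiswap failed to binarize replicate {rep} within "
                f"{max_iter} moves (fill={row_sums.sum()}, shape={inc.shape})"
            )
        assert (m.sum(axis=1) == row_sums).all() and (m.sum(axis=0) == col_sums).all()
        sor_null[rep] = _pair_sor(m, iu)
        if mats is not None:
            mats.append(m.astype(np.int8))
    return NullEnsemble(
        n_reps=n_reps,
        seed=seed,
        row_sums=row_sums,
        col_sums=col_sums,
        sor_null=sor_null,
        burnin_factor=BURNIN_FACTOR,
        matrices=mats,
    )


# ----------------------------------------------------------------------- SES

@dataclass
class SESResult:
    """Per-pair standardized effect sizes of Sørensen dissimilarity.

    ``pairs`` columns: sample_i, sample_j, pair_set, obs_sor, null_mean,
    null_sd, ses, deterministic (|SES| > 2; NaN SES where null sd = 0).
    """

    pairs: pd.DataFrame
    set_means: dict[str, float]
    n_reps: int
    seed: int
    n_undefined: int = 0

    def fraction_within(self, pair_set: str | None = None, bound: float = SES_THRESHOLD):
        """Fraction of (defined) pairwise SES values with |SES| < bound."""
        df = self.pairs if pair_set is None else self.pairs[self.pairs.pair_set == pair_set]
        ses = df.ses.dropna()
        if not len(ses):
            return np.nan
        return float((ses.abs() < bound).mean())


def _ses_from_ensemble(obs: np.ndarray, null: np.ndarray):
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(sd > 0, (obs - mean) / sd, np.nan)
    return mean, sd, ses


def ses_beta_sor(
    table: CommunityTable,
    n_reps: int = DEFAULT_REPS,
    seed: int = 0,
    pool: str = "restricted",
) -> SESResult:
    """SES of pairwise Sørensen dissimilarity against the quasiswap null.

    Between-group pairs are always evaluated against randomizations of the
    full table.  With ``pool="restricted"`` (default, mirroring the study's
    within-group analyses) each group's within-group pairs are evaluated
    against randomizations of that group's sub-table, using only the taxa
    present in the group as the regional pool; ``pool="global"`` evaluates
    every pair against the full-table null.
    """
    if pool not in ("restricted", "global"):
        raise ValueError("pool must be 'restricted' or 'global'")
    inc = table.incidence()
    n = table.n_samples
    iu = np.triu_indices(n, k=1)
    obs = _pair_sor(inc, iu)
    labels = table.groups.to_numpy()
    ids = np.asarray(table.sample_ids)
    pair_set = np.where(
        labels[iu[0]] == labels[iu[1]],
        np.char.add("within_", labels[iu[0]].astype(str)),
        "between",
    )

    ens = quasiswap(inc, n_reps=n_reps, seed=derive_seed(seed, "ses_global"))
    mean, sd, ses = _ses_from_ensemble(obs, ens.sor_null)

    if pool == "restricted":
        for g in table.group_labels():
            sub = table.subset_group(g)
            if sub.n_samples < 2:
                continue
            sub_iu = np.triu_indices(sub.n_samples, k=1)
            sub_obs = _pair_sor(sub.incidence(), sub_iu)
            sub_ens = quasiswap(
                sub.incidence(), n_reps=n_reps, seed=derive_seed(seed, f"ses_{g}")
            )
            m_g, s_g, ses_g = _ses_from_ensemble(sub_obs, sub_ens.sor_null)
            # map the sub-table's pairs back into the full pair list
            sub_ids = np.asarray(sub.sample_ids)
            full_index = {}
            for k in range(len(iu[0])):
                full_index[(ids[iu[0][k]], ids[iu[1][k]])] = k
            for k in range(len(sub_iu[0])):
                a, b = sub_ids[sub_iu[0][k]], sub_ids[sub_iu[1][k]]
                key = (a, b) if (a, b) in full_index else (b, a)
                idx = full_index[key]
                mean[idx], sd[idx], ses[idx] = m_g[k], s_g[k], ses_g[k]
                obs[idx] = sub_obs[k]

    pairs = pd.DataFrame(
        {
            "sample_i": ids[iu[0]],
            "sample_j": ids[iu[1]],
            "pair_set": pair_set,
            "obs_sor": obs,
            "null_mean": mean,
            "null_sd": sd,
            "ses": ses,
        }
    )
    pairs["deterministic"] = pairs.ses.abs() > SES_THRESHOLD
    set_means = {
        ps: float(sub.ses.dropna().mean()) for ps, sub in pairs.groupby("pair_set")
    }
    return SESResult(
        pairs=pairs,
        set_means=set_means,
        n_reps=n_reps,
        seed=seed,
        n_undefined=int(pairs.ses.isna().sum()),
    )


class QuasiswapSES(BaseEstimator):
    """Estimator interface over :func:`ses_beta_sor`.

    ``fit(X, y)`` takes a samples x taxa count frame and group labels; the
    fitted attributes are ``pairs_`` (per-pair SES table) and ``set_means_``.
    """

    def __init__(self, n_reps: int = DEFAULT_REPS, random_state: int = 0,
                 pool: str = "restricted"):
        self.n_reps = n_reps
        self.random_state = random_state
        self.pool = pool

    def fit(self, X, y):
        if isinstance(X, CommunityTable):
            table = X
        else:
            X = pd.DataFrame(X)
            table = CommunityTable(X, pd.Series(np.asarray(y), index=X.index))
        res = ses_beta_sor(table, self.n_reps, self.random_state, self.pool)
        self.pairs_ = res.pairs
        self.set_means_ = res.set_means
        self.result_ = res
        return self


# ------------------------------------------------------------------- RC_bray

@dataclass
class RCResult:
    """Raup–Crick (Bray–Curtis) metric for between-group sample pairs."""

    pairs: pd.DataFrame  # sample_i, sample_j, obs_bc, n_below, n_equal, n_above, rc, deviant
    mean_rc: float
    n_reps: int
    seed: int
    weighting: str


def _assemble_null_chunk(
    counts: np.ndarray,
    rng: np.random.Generator,
    n_chunk: int,
    richness: np.ndarray,
    totals: np.ndarray,
    log_w_draw: np.ndarray,
    rel_ab: np.ndarray,
) -> np.ndarray:
    """Null count tables (n_chunk, n_samples, n_taxa): richness- and
    total-preserving, occurrence/abundance weighted."""
    n, T = counts.shape
    out = np.zeros((n_chunk, n, T), dtype=np.int64)
    for s in range(n):
        r, ntot = int(richness[s]), int(totals[s])
        # Gumbel top-k == weighted sampling without replacement
        keys = log_w_draw[None, :] + rng.gumbel(size=(n_chunk, T))
        idx = np.argpartition(-keys, r - 1, axis=1)[:, :r]
        chosen = np.zeros((n_chunk, T), dtype=bool)
        np.put_along_axis(chosen, idx, True, axis=1)
        pv = np.where(chosen, rel_ab[None, :], 0.0)
        pv /= pv.sum(axis=1, keepdims=True)
        out[:, s, :] = chosen + rng.multinomial(ntot - r, pv)
    return out


def rc_bray(
    table: CommunityTable,
    n_reps: int = DEFAULT_REPS,
    seed: int = 0,
    weighting: str = "occurrence",
) -> RCResult:
    """RC_bray for all between-group pairs against richness/abundance nulls.

    Because null samples preserve each sample's total reads, Bray–Curtis
    values within one pair share a denominator, so null-vs-observed
    comparisons are exact integer comparisons of ``sum|x - y|``.
    """
    if weighting not in ("occurrence", "uniform"):
        raise ValueError("weighting must be 'occurrence' or 'uniform'")
    if len(table.group_labels()) < 2:
        raise ValueError("rc_bray needs >= 2 groups")
    counts = table.counts.to_numpy()
    n, T = counts.shape
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    assert (richness <= T).all()
    occ = (counts > 0).sum(axis=0).astype(float)
    w_draw = occ if weighting == "occurrence" else np.ones(T)
    log_w = np.log(w_draw)
    tot_ab = counts.sum(axis=0).astype(float)
    rel_ab = tot_ab / tot_ab.sum()

    labels = table.groups.to_numpy()
    ids = np.asarray(table.sample_ids)
    iu = np.triu_indices(n, k=1)
    between = labels[iu[0]] != labels[iu[1]]
    pi, pj = iu[0][between], iu[1][between]
    obs_num = np.abs(counts[pi] - counts[pj]).sum(axis=1)  # integer numerators
    den = totals[pi] + totals[pj]

    rng = np.random.default_rng(derive_seed(seed, f"rc_{weighting}"))
    n_below = np.zeros(len(pi), dtype=np.int64)
    n_equal = np.zeros(len(pi), dtype=np.int64)
    chunk = max(1, min(n_reps, int(2e7 // max(1, n * T))))
    done = 0
    while done < n_reps:
        c = min(chunk, n_reps - done)
        nulls = _assemble_null_chunk(counts, rng, c, richness, totals, log_w, rel_ab)
        null_num = np.abs(nulls[:, pi, :] - nulls[:, pj, :]).sum(axis=2)
        n_below += (null_num < obs_num[None, :]).sum(axis=0)
        n_equal += (null_num == obs_num[None, :]).sum(axis=0)
        done += c

    rc = 2.0 * ((n_below + 0.5 * n_equal) / n_reps) - 1.0
    pairs = pd.DataFrame(
        {
            "sample_i": ids[pi],
            "sample_j": ids[pj],
            "obs_bc": obs_num / den,
            "n_below": n_below,
            "n_equal": n_equal,
            "n_above": n_reps - n_below - n_equal,
            "rc": rc,
        }
    )
    pairs["deviant"] = pairs.rc.abs() > RC_THRESHOLD
    return RCResult(
        pairs=pairs,
        mean_rc=float(rc.mean()),
        n_reps=n_reps,
        seed=seed,
        weighting=weighting,
    )


class RaupCrick(BaseEstimator):
    """Estimator interface over :func:`rc_bray` (fitted attrs ``pairs_``, ``mean_rc_``)."""

    def __init__(self, n_reps: int = DEFAULT_REPS, random_state: int = 0,
                 weighting: str = "occurrence"):
        self.n_reps = n_reps
        self.random_state = random_state
        self.weighting = weighting

    def fit(self, X, y):
        if isinstance(X, CommunityTable):
            table = X
        else:
            X = pd.DataFrame(X)
            table = CommunityTable(X, pd.Series(np.asarray(y), index=X.index))
        res = rc_bray(table, self.n_reps, self.random_state, self.weighting)
        self.pairs_ = res.pairs
        self.mean_rc_ = res.mean_rc
        self.result_ = res
        return self
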