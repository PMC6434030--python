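"""Synthetic sample x taxon count tables with known assembly structure.

The generator emulates a two-group replicate design (by default ten thin- and
ten thick-biofilm carriers): each group has a regional taxon pool built from a
shared core, group-exclusive taxa (turnover control) and extra taxa added only
to group 2's pool while group 1's pool is a strict subset (nestedness
control).  Within a group, replicates differ only through occupancy drift
(each pool member occurs in a replicate with probability ``occupancy``) and
multinomial read sampling at uneven depths, so between-group differences are
deterministic and within-group variation is purely stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .io import CommunityTable

REGIMES = ("neutral", "turnover_dominated", "nestedness_dominated")


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic two-group community experiment.

    Attributes
    ----------
    n_per_group
        Replicate samples per group.
    core_taxa
        Taxa shared by both groups' regional pools.
    unique_taxa_g1, unique_taxa_g2
        Group-exclusive pool sizes (turnover control).
    nested_extra_g2
        Taxa added only to group 2's pool so that group 1's pool is a strict
        subset (nestedness control).
    occupancy
        Probability in (0, 1] that a pool member occurs in a given replicate
        (ecological-drift control).
    abundance_shape
        Log-normal sigma of taxon mean relative abundances.
    depth_range
        Inclusive (min, max) reads per sample; each sample's depth is uniform
        in this range and the counts are one multinomial draw.
    seed
        Base seed; identical seeds give bit-identical tables.
    """

    n_per_group: int = 10
    core_taxa: int = 100
    unique_taxa_g1: int = 0
    unique_taxa_g2: int = 0
    nested_extra_g2: int = 0
    occupancy: float = 0.9
    abundance_shape: float = 1.0
    depth_range: tuple[int, int] = (5000, 10000)
    seed: int = 0
    group_names: tuple[str, str] = ("Z50", "Z400")

    def __post_init__(self) -> None:
        pools = (self.core_taxa, self.unique_taxa_g1, self.unique_taxa_g2, self.nested_extra_g2)
        if min(pools) < 0:
            raise ValueError("pool sizes must be non-negative")
        if self.core_taxa + max(pools) < 1:
            raise ValueError("at least one taxon pool must be non-empty")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError("occupancy must be in (0, 1]")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range must satisfy 1 <= min <= max")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.abundance_shape < 0:
            raise ValueError("abundance_shape must be >= 0")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["depth_range"] = list(self.depth_range)
        d["group_names"] = list(self.group_names)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "depth_range" in d:
            d["depth_range"] = tuple(d["depth_range"])
        if "group_names" in d:
            d["group_names"] = tuple(d["group_names"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Pool membership per group and the expected assembly-regime label."""

    pools: dict[str, list[str]]
    regime: str


def regime_of(s: SyntheticScenario) -> str:
    """Deterministic regime label implied by the scenario's pool structure.

    ``neutral`` when both groups share one pool; otherwise the larger of the
    turnover (unique pools) and nestedness (extra pool) controls wins.
    """
    turnover = s.unique_taxa_g1 + s.unique_taxa_g2
    nested = s.nested_extra_g2
    if turnover == 0 and nested == 0:
        return "neutral"
    if turnover == 0:
        return "nestedness_dominated"
    if nested == 0:
        return "turnover_dominated"
    return "turnover_dominated" if turnover >= nested else "nestedness_dominated"


def _taxon_ids(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def generate(s: SyntheticScenario) -> tuple[CommunityTable, GroundTruth]:
    """Draw one synthetic community table plus its ground truth.

    Pool members are included in each replicate independently with
    probability ``occupancy``; included taxa receive log-normal mean relative
    abundances fixed across replicates (core taxa share one draw between the
    groups so a single-pool scenario is exactly neutral; group-exclusive taxa
    get their own draws); read counts are one multinomial draw at a
    uniform-random depth.
    """
    rng = np.random.default_rng(s.seed)
    g1, g2 = s.group_names

    core = _taxon_ids(s.core_taxa, "core")
    u1 = _taxon_ids(s.unique_taxa_g1, "uniq1_")
    u2 = _taxon_ids(s.unique_taxa_g2, "uniq2_")
    extra = _taxon_ids(s.nested_extra_g2, "extra2_")
    all_taxa = core + u1 + u2 + extra
    pools = {g1: core + u1, g2: core + u2 + extra}

    # mean relative abundances: one draw per taxon; shared across groups for
    # core taxa, group-specific for exclusive taxa (they occur in one group only)
    mean_ab = pd.Series(
        rng.lognormal(mean=0.0, sigma=s.abundance_shape, size=len(all_taxa)),
        index=all_taxa,
    )

    taxon_index = pd.Index(all_taxa)
    rows = []
    sample_ids = []
    groups = {}
    for gi, gname in enumerate((g1, g2)):
        pool = pools[gname]
        pool_means = mean_ab[pool].to_numpy()
        for rep in range(s.n_per_group):
            sid = f"{gname}_{rep + 1:02d}"
            counts = None
            for _attempt in range(100):
                present = rng.random(len(pool)) < s.occupancy
                if not present.any():
                    continue
                depth = int(rng.integers(s.depth_range[0], s.depth_range[1] + 1))
                p = pool_means * present
                p = p / p.sum()
                counts = rng.multinomial(depth, p)
                break
            if counts is None:
                raise RuntimeError(
                    f"could not draw a non-empty replicate for {sid} in 100 attempts"
                )
            row = np.zeros(len(all_taxa), dtype=np.int64)
            row[taxon_index.get_indexer(pool)] = counts
            rows.append(row)
            sample_ids.append(sid)
            groups[sid] = gname

    counts = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=all_taxa)
    table = CommunityTable(counts, groups, quiet=True)
    return table, GroundTruth(pools=pools, regime=regime_of(s))


# ------------------------------------------------------------------- presets

def neutral_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """Single shared pool, occupancy 0.8: no deterministic group structure."""
    kw = dict(core_taxa=100, occupancy=0.8, seed=seed)
    kw.update(overrides)
    return SyntheticScenario(**kw)


def turnover_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """Small core plus disjoint group-exclusive pools: replacement dominates."""
    kw = dict(core_taxa=20, unique_taxa_g1=40, unique_taxa_g2=40, seed=seed)
    kw.update(overrides)
    return SyntheticScenario(**kw)


def nestedness_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """Group 1's pool a strict subset of group 2's: species loss dominates."""
    kw = dict(core_taxa=50, nested_extra_g2=40, seed=seed)
    kw.update(overrides)
    return SyntheticScenario(**kw)


def study_like_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """A 20-sample, ~3,500-taxon sparse table with group-2 richness excess,
    mimicking the scale of a thin/thick carrier amplicon survey."""
    kw = dict(
        core_taxa=1200,
        unique_taxa_g1=600,
        unique_taxa_g2=1200,
        nested_extra_g2=500,
        occupancy=0.9,
        abundance_shape=1.5,
        depth_range=(30000, 60000),
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticScenario(**kw)


SCENARIO_PRESETS = {
    "neutral": neutral_scenario,
    "turnover": turnover_scenario,
    "nestedness": nestedness_scenario,
    "study_like": study_like_scenario,
}
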