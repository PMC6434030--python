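"""End-to-end assembly analysis: rarefy -> alpha -> beta partition ->
null models -> PERMANOVA/PCoA -> verdict, plus the synthetic-validation loop.

Every stage draws its seed deterministically from one master seed and the
stage name, so adding or toggling a stage never perturbs the other stages'
randomness, and a re-run with the same master seed reproduces the report
bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alpha import alpha_diversity
from .beta import partition_table
from .io import CommunityTable, read_community_table, write_distance_matrix
from .nullmodels import (
    RC_THRESHOLD,
    SES_THRESHOLD,
    derive_seed,
    rc_bray,
    ses_beta_sor,
)
from .ordination import PCoA, permanova
from .synthetic import SCENARIO_PRESETS, SyntheticScenario, generate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, seeds, replication settings and stage toggles of one run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    scenario: SyntheticScenario | None = None
    depth: int | str = "min"
    n_reps: int = 999
    n_perm: int = 999
    master_seed: int = 0
    output_dir: str = "assembly_out"
    run_alpha: bool = True
    run_beta: bool = True
    run_ses: bool = True
    run_rc: bool = True
    run_permanova: bool = True
    run_pcoa: bool = True
    rc_weighting: str = "occurrence"
    min_count: int = 0  # optional rare-taxon filter, off by default

    def load_table(self) -> CommunityTable:
        if self.scenario is not None:
            table, _ = generate(self.scenario)
        elif self.counts_path and self.metadata_path:
            table = read_community_table(self.counts_path, self.metadata_path)
        else:
            raise ValueError("provide counts_path+metadata_path or a scenario")
        if self.min_count > 0:
            table = table.min_count_filter(self.min_count)
        return table


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _verdict(partition, ses_res, rc_res) -> dict:
    """Assemble the decision block from the printed thresholds:
    |SES| > 2 and |RC| > 0.95 flag deterministic between-group assembly;
    beta_ratio < 0.5 means turnover dominates, > 0.5 nestedness."""
    out: dict = {"thresholds": {"ses": SES_THRESHOLD, "rc": RC_THRESHOLD,
                                "beta_ratio": 0.5}}
    if partition is not None:
        ratio = partition.summaries.loc["between", "beta_ratio"]
        if np.isfinite(ratio):
            out["between_beta_ratio"] = float(ratio)
            out["dominance"] = "turnover" if ratio < 0.5 else "nestedness"
        else:
            out["between_beta_ratio"] = None
            out["dominance"] = "undefined"
    signals = {}
    if ses_res is not None:
        m = ses_res.set_means.get("between", np.nan)
        signals["mean_between_ses"] = None if np.isnan(m) else float(m)
        for ps, v in ses_res.set_means.items():
            if ps.startswith("within_"):
                frac = ses_res.fraction_within(ps)
                signals[f"{ps}_frac_abs_ses_lt_2"] = None if np.isnan(frac) else frac
    if rc_res is not None:
        signals["mean_between_rc"] = rc_res.mean_rc
    out["signals"] = signals
    det = []
    if signals.get("mean_between_ses") is not None:
        det.append(abs(signals["mean_between_ses"]) > SES_THRESHOLD)
    if signals.get("mean_between_rc") is not None:
        det.append(abs(signals["mean_between_rc"]) > RC_THRESHOLD)
    if det:
        out["between"] = "deterministic" if any(det) else "stochastic"
    within = [
        v > 0.5
        for k, v in signals.items()
        if k.endswith("frac_abs_ses_lt_2") and v is not None
    ]
    if within:
        out["within"] = "stochastic" if all(within) else "deterministic"
    return out


def run_assembly_analysis(cfg: RunConfig) -> dict:
    """Run the configured stages and write the TSV/JSON report bundle.

    Returns a dict with the in-memory results and the verdict block.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cfg.load_table()
    results: dict = {"table": table}
    log: dict = {
        "master_seed": cfg.master_seed,
        "n_reps": cfg.n_reps,
        "n_perm": cfg.n_perm,
        "stage_seeds": {},
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
    }

    def stage_seed(name: str) -> int:
        s = derive_seed(cfg.master_seed, name)
        log["stage_seeds"][name] = s
        return s

    try:
        alpha_res = None
        if cfg.run_alpha:
            alpha_res = alpha_diversity(table, cfg.depth, stage_seed("alpha"))
            alpha_res.table.to_csv(outdir / "alpha.tsv", sep="\t")
            log["rarefaction_depth"] = alpha_res.rarefaction_depth
            results["alpha"] = alpha_res

        # beta/null stages run on a rarefied table (single shared draw)
        from .alpha import rarefy, Rarefier

        r = Rarefier(depth=cfg.depth, random_state=stage_seed("rarefy")).fit(table.counts)
        rarefied = CommunityTable(r.transform(table.counts), table.groups, quiet=True)
        log["analysis_rarefaction_depth"] = r.depth_

        partition = None
        if cfg.run_beta:
            partition = partition_table(rarefied)
            write_distance_matrix(partition.sor, outdir / "beta_sor.tsv")
            write_distance_matrix(partition.sim, outdir / "beta_sim.tsv")
            write_distance_matrix(partition.sne, outdir / "beta_sne.tsv")
            partition.summaries.to_csv(outdir / "beta_summary.tsv", sep="\t")
            results["beta"] = partition

        ses_res = None
        if cfg.run_ses:
            ses_res = ses_beta_sor(rarefied, cfg.n_reps, stage_seed("ses"))
            ses_res.pairs.to_csv(outdir / "ses_pairs.tsv", sep="\t", index=False)
            results["ses"] = ses_res

        rc_res = None
        if cfg.run_rc:
            rc_res = rc_bray(rarefied, cfg.n_reps, stage_seed("rc"), cfg.rc_weighting)
            rc_res.pairs.to_csv(outdir / "rc_pairs.tsv", sep="\t", index=False)
            results["rc"] = rc_res

        if cfg.run_permanova and partition is not None:
            rows = []
            for name, dm in (("sorensen", partition.sor),
                             ("simpson_turnover", partition.sim),
                             ("nestedness_component", partition.sne)):
                pr = permanova(dm, rarefied.groups, cfg.n_perm,
                               stage_seed(f"permanova_{name}"))
                rows.append({
                    "metric": name, "pseudo_F": pr.pseudo_F, "r_squared": pr.r_squared,
                    "p_value": pr.p_value, "n_permutations": pr.n_permutations,
                    "exhaustive": pr.exhaustive,
                })
            perm_table = pd.DataFrame(rows).set_index("metric")
            perm_table.to_csv(outdir / "permanova.tsv", sep="\t")
            results["permanova"] = perm_table

        if cfg.run_pcoa and partition is not None:
            p = PCoA(n_components=2).fit(partition.sor)
            p.coordinates_.to_csv(outdir / "pcoa.tsv", sep="\t")
            results["pcoa"] = p.result()

        verdict = _verdict(partition, ses_res, rc_res)
        results["verdict"] = verdict
        with open(outdir / "verdict.json", "w") as fh:
            json.dump({"verdict": verdict, "log": log}, fh, indent=2,
                      sort_keys=True, default=_json_default)
    except Exception:
        logger.exception("assembly analysis failed; partial outputs kept in %s", outdir)
        raise
    return results


# --------------------------------------------------------------- validation

VALIDATION_COLUMNS = [
    "scenario", "seed", "true_regime", "beta_ratio_between", "regime_recovered",
    "mean_between_ses", "frac_within_ses_lt2", "mean_between_rc",
]


def run_validation_suite(
    n_seeds: int = 20,
    scenarios=("neutral", "turnover", "nestedness"),
    n_reps: int = 999,
    master_seed: int = 0,
    run_nulls: bool = True,
) -> pd.DataFrame:
    """Generate -> analyze loop over scenarios x seeds with known ground truth.

    Tabulates beta-ratio regime recovery and, when ``run_nulls`` is on, the
    between-group SES / RC_bray signals and within-group SES coverage.
    """
    if n_seeds < 5:
        raise ValueError("n_seeds must be >= 5")
    rows = []
    for name in scenarios:
        preset = SCENARIO_PRESETS[name]
        for i in range(n_seeds):
            seed = derive_seed(master_seed, f"validate_{name}_{i}")
            scenario = preset(seed=seed)
            table, truth = generate(scenario)
            from .alpha import Rarefier

            r = Rarefier(depth="min", random_state=derive_seed(seed, "rarefy")).fit(
                table.counts
            )
            rarefied = CommunityTable(r.transform(table.counts), table.groups, quiet=True)
            part = partition_table(rarefied)
            ratio = part.summaries.loc["between", "beta_ratio"]
            recovered = None
            if truth.regime == "turnover_dominated":
                recovered = bool(ratio < 0.5)
            elif truth.regime == "nestedness_dominated":
                recovered = bool(ratio > 0.5)
            row = {
                "scenario": name,
                "seed": seed,
                "true_regime": truth.regime,
                "beta_ratio_between": float(ratio) if np.isfinite(ratio) else np.nan,
                "regime_recovered": recovered,
                "mean_between_ses": np.nan,
                "frac_within_ses_lt2": np.nan,
                "mean_between_rc": np.nan,
            }
            if run_nulls:
                ses = ses_beta_sor(rarefied, n_reps, derive_seed(seed, "ses"))
                within = ses.pairs[ses.pairs.pair_set.str.startswith("within_")]
                row["mean_between_ses"] = ses.set_means.get("between", np.nan)
                row["frac_within_ses_lt2"] = float(
                    (within.ses.dropna().abs() < SES_THRESHOLD).mean()
                )
                rc = rc_bray(rarefied, n_reps, derive_seed(seed, "rc"))
                row["mean_between_rc"] = rc.mean_rc
            rows.append(row)
    return pd.DataFrame(rows, columns=VALIDATION_COLUMNS)
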