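"""End-to-end orchestration: simulate/load -> screen -> d' -> psychometric
-> permutation inference -> reaction-time tables, as a pure dataflow over
delimited files with a JSON run manifest.

Every stage writes a long-format CSV mirroring the corresponding report
table shape (pairwise group tests, 2x2 interaction tests, RT difference
lists, within-group rank-consistency matrices). Identical configuration
yields byte-identical outputs: all randomness flows from the recorded
seeds and no timestamps enter the reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ParameterError
from .inclusion import apply_screen
from .psychometric import fit_all
from .resampling import (CELL_ORDER, lilliefors, permute_groups,
                         permute_interaction)
from .rt_analysis import (GROUP_PAIRS, condition_rank_matrix,
                          group_rt_differences, rt_condition_medians,
                          rt_dprime_rank_table, rt_medians)
from .sdt import dprime_frame
from .synthetic_data import CohortSpec, cohort_spec_from_dict, simulate_cohort
from .trial_model import GROUPS, read_trials, write_trials

logger = logging.getLogger("tojlab.pipeline")

ASYNCHRONY_CLASSES = ("67", "133", "200", "pooled")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    cohort: CohortSpec | None = None
    input_path: str | None = None
    trial_seed: int = 1
    resampling_seed: int = 2
    n_sims: int = 10_000
    lilliefors_reps: int = 10_000
    out_dir: str = "results"
    include_practice: bool = False
    run_mc: bool = True
    run_rt: bool = True

    def __post_init__(self):
        if self.cohort is None and self.input_path is None:
            self.cohort = CohortSpec()
        if self.cohort is not None and self.input_path is not None:
            raise ParameterError("give either a cohort spec or an input path")
        if self.n_sims < 1:
            raise ParameterError("n_sims must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = cohort_spec_from_dict(raw["cohort"])
        return cls(**raw)

    def describe(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "cohort"}
        if self.cohort is not None:
            cohort = dict(self.cohort.__dict__)
            cohort["interaction_profile"] = {
                f"{m}:{dd}": v for (m, dd), v in cohort["interaction_profile"].items()}
            d["cohort"] = cohort
        return d


def _test_seed(base: int, index: int) -> int:
    """Deterministic per-test seed derived from the resampling seed."""
    return int((base * 1_000_003 + index) % (2 ** 31))


def _dprime_wide(dp: pd.DataFrame, asynchrony_class: str) -> pd.DataFrame:
    """Per-participant wide cell matrix for one asynchrony class."""
    sub = dp[dp["asynchrony_class"] == asynchrony_class].copy()
    sub["condition"] = sub["motion_type"] + "_" + sub["initial_directions"]
    wide = sub.pivot_table(index=["participant_id", "group"],
                           columns="condition", values="dprime",
                           aggfunc="first").reset_index()
    wide.columns.name = None
    return wide


def pairwise_group_tests(dp: pd.DataFrame, n_sims: int, seed: int) -> pd.DataFrame:
    """Median-difference permutation tests for every group pair x condition
    x asynchrony class present in the d' table.

    Pairs with a missing group are skipped with a logged warning.
    """
    present = set(dp["group"])
    rows = []
    idx = 0
    for cls in ASYNCHRONY_CLASSES:
        wide = _dprime_wide(dp, cls)
        for cond in [f"{m}_{d}" for m, d in
                     (("radial", "same"), ("radial", "opposite"),
                      ("rotational", "same"), ("rotational", "opposite"))]:
            if cond not in wide.columns:
                continue
            for g1, g2 in GROUP_PAIRS:
                idx += 1
                if g1 not in present or g2 not in present:
                    logger.warning("skipping pairwise test %s vs %s (%s, %s): "
                                   "group absent", g1, g2, cond, cls)
                    continue
                d1 = wide.loc[wide["group"] == g1, cond]
                d2 = wide.loc[wide["group"] == g2, cond]
                res = permute_groups(d1, d2, n_sims=n_sims,
                                     seed=_test_seed(seed, idx))
                rows.append({
                    "test": "pairwise", "condition": cond,
                    "asynchrony_class": cls, "comparison": f"{g1} vs {g2}",
                    "observed_stat": res.observed_stat,
                    "p_value": res.p_value, "significant": res.significant,
                    "n_sims": res.n_sims, "seed": res.seed,
                })
    return pd.DataFrame(rows)


def interaction_tests(dp: pd.DataFrame, n_sims: int, seed: int) -> pd.DataFrame:
    """Within-participant 2x2 interaction tests per group (and combined)
    per asynchrony class — the interaction report shape."""
    rows = []
    idx = 10_000
    for cls in ASYNCHRONY_CLASSES:
        wide = _dprime_wide(dp, cls)
        scopes = [("all", wide)]
        scopes += [(g, wide[wide["group"] == g]) for g in GROUPS
                   if (wide["group"] == g).any()]
        for name, sub in scopes:
            if sub.empty or any(c not in sub.columns for c in CELL_ORDER):
                continue
            idx += 1
            res = permute_interaction(sub[list(CELL_ORDER)], n_sims=n_sims,
                                      seed=_test_seed(seed, idx))
            rows.append({
                "test": "interaction", "condition": "2x2",
                "asynchrony_class": cls, "comparison": name,
                "observed_stat": res.observed_stat,
                "p_value": res.p_value, "significant": res.significant,
                "n_sims": res.n_sims, "seed": res.seed,
            })
    return pd.DataFrame(rows)


def normality_screen(dp: pd.DataFrame, n_reps: int, seed: int) -> pd.DataFrame:
    """Lilliefors screen of the pooled d' values per group x condition."""
    rows = []
    idx = 20_000
    pooled = dp[dp["asynchrony_class"] == "pooled"]
    for (group, m, d), sub in pooled.groupby(
            ["group", "motion_type", "initial_directions"], observed=True):
        idx += 1
        vals = sub["dprime"].to_numpy()
        if vals.size < 4:
            continue
        stat, p = lilliefors(vals, n_reps=n_reps, seed=_test_seed(seed, idx))
        rows.append({"group": group, "condition": f"{m}_{d}",
                     "statistic": stat, "p_value": p, "n": int(vals.size),
                     "normal_at_05": bool(p >= 0.05)})
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written
    to ``out_dir/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if config.input_path is not None:
        logger.info("stage load: %s", config.input_path)
        trials = read_trials(config.input_path)
    else:
        logger.info("stage simulate: cohort seed %s, trial seed %s",
                    config.cohort.seed, config.trial_seed)
        trials = simulate_cohort(config.cohort, trial_seed=config.trial_seed,
                                 include_practice=config.include_practice)
        outputs["trials.csv"] = write_trials(trials, out / "trials.csv")
    logger.info("loaded %d trials from %d participants",
                len(trials.trials), trials.n_participants)

    included, report = apply_screen(trials)
    outputs["inclusion.csv"] = _write_csv(report.participants,
                                          out / "inclusion.csv")
    outputs["inclusion_groups.csv"] = _write_csv(report.groups,
                                                 out / "inclusion_groups.csv")
    logger.info("stage screen: %d of %d participants included",
                included.n_participants, trials.n_participants)

    dp = dprime_frame(included)
    outputs["dprime.csv"] = _write_csv(dp, out / "dprime.csv")
    logger.info("stage dprime: %d entries", len(dp))

    fits = fit_all(included)
    outputs["fits.csv"] = _write_csv(fits, out / "fits.csv")
    logger.info("stage psychometric: %d fits", len(fits))

    if config.run_mc:
        mc = pd.concat([
            pairwise_group_tests(dp, config.n_sims, config.resampling_seed),
            interaction_tests(dp, config.n_sims, config.resampling_seed),
        ], ignore_index=True)
        outputs["mc_results.csv"] = _write_csv(mc, out / "mc_results.csv")
        lf = normality_screen(dp, config.lilliefors_reps,
                              config.resampling_seed)
        outputs["lilliefors.csv"] = _write_csv(lf, out / "lilliefors.csv")
        logger.info("stage mc: %d tests, seed %s", len(mc),
                    config.resampling_seed)

    if config.run_rt:
        rt_dir = out / "rt_tables"
        rt_dir.mkdir(exist_ok=True)
        table = rt_medians(included)
        outputs["rt_tables/rt_medians.csv"] = _write_csv(
            table.group_medians, rt_dir / "rt_medians.csv")
        outputs["rt_tables/rt_differences.csv"] = _write_csv(
            group_rt_differences(table), rt_dir / "rt_differences.csv")
        dp_wide = _dprime_wide(dp, "pooled")
        outputs["rt_tables/dprime_rank_corr.csv"] = _write_csv(
            condition_rank_matrix(dp_wide), rt_dir / "dprime_rank_corr.csv")
        rt_wide = rt_condition_medians(included)
        outputs["rt_tables/rt_rank_corr.csv"] = _write_csv(
            condition_rank_matrix(rt_wide), rt_dir / "rt_rank_corr.csv")
        outputs["rt_tables/rt_vs_dprime.csv"] = _write_csv(
            rt_dprime_rank_table(rt_wide, dp_wide), rt_dir / "rt_vs_dprime.csv")
        logger.info("stage rt: tables written to %s", rt_dir)

    manifest = {
        "package": "tojlab",
        "version": __version__,
        "config": config.describe(),
        "provenance": {k: v for k, v in trials.provenance.items()},
        "n_participants_total": int(trials.n_participants),
        "n_participants_included": int(included.n_participants),
        "n_trials_analyzed": int(len(included.analysis_trials)),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
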