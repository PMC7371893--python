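"""Command-line interface, configuration I/O and the group-statistics report.

The statistics report is thin plumbing over scipy/statsmodels following the
study's decision tree: a KS-type normality check per group, then one-way
ANOVA (Welch variant under unequal variances) for normal measures or
Kruskal-Wallis / Mann-Whitney otherwise, with Bonferroni-adjusted pairwise
comparisons at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import click
import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .exceptions import ConfigError
from .fitting import (FITTED_PARAMS, FitGrid, STROOP_COLUMNS, compare_groups,
                      grid_fit)
from .genotype import MutationRecord, classify_dp140
from .iblt_core import ModelParams
from .neuropsych_scores import score_cohort
from .stroop_task import TaskConfig
from .synthetic_cohort import PROFILES, cohort_to_frame, gen_model_subjects, gen_scores

ALPHA = 0.05

__all__ = ["RunConfig", "stats_report", "load_config", "write_run_log", "cli"]


@dataclass
class RunConfig:
    """Resolved configuration of one run, echoed verbatim to the run log."""

    seed: int = 0
    params: Optional[ModelParams] = None
    grid: Optional[FitGrid] = None
    task: TaskConfig = field(default_factory=TaskConfig)
    groups: tuple = ("control", "dp140_neg")
    output: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "params": asdict(self.params) if self.params else None,
            "grid": asdict(self.grid) if self.grid else None,
            "task": asdict(self.task),
            "groups": list(self.groups),
            "output": self.output,
        }


def load_config(path) -> dict:
    """Read a JSON or YAML configuration file into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_run_log(path, config: RunConfig, extra: Optional[dict] = None) -> None:
    """Plain-text run log: package version, seed and the resolved config."""
    lines = [f"dmdibl {__version__}", f"seed: {config.seed}",
             "config: " + json.dumps(config.to_dict(), default=str)]
    for key, value in (extra or {}).items():
        lines.append(f"{key}: {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def _normality_ok(groups: Sequence[np.ndarray]) -> bool:
    from statsmodels.stats.diagnostic import lilliefors

    for g in groups:
        if np.std(g) == 0:
            return False
        _, p = lilliefors(g, dist="norm")
        if p <= ALPHA:
            return False
    return True


def _pairwise(groups: dict, parametric: bool, equal_var: bool) -> dict:
    pairs = list(itertools.combinations(groups, 2))
    out = {}
    for a, b in pairs:
        x, y = groups[a], groups[b]
        if parametric:
            _, p = sps.ttest_ind(x, y, equal_var=equal_var)
        else:
            _, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        out[f"p_adj_{a}_vs_{b}"] = min(1.0, float(p) * len(pairs))
    return out


def stats_report(cohort: pd.DataFrame, measures: Sequence[str],
                 group_col: str = "group") -> pd.DataFrame:
    """Per-measure group comparison table.

    Normal measures get one-way ANOVA (Welch variant when Levene rejects
    equal variances) with Bonferroni-adjusted pairwise t tests; non-normal
    measures get Kruskal-Wallis (or Mann-Whitney for two groups) with
    Bonferroni-adjusted pairwise Mann-Whitney tests. Groups with fewer than
    two observations drop the measure with a warning.
    """
    labels = list(pd.unique(cohort[group_col]))
    if len(labels) < 2:
        raise ConfigError("stats_report needs at least 2 groups")
    rows = []
    for measure in measures:
        groups = {}
        for lab in labels:
            vals = cohort.loc[cohort[group_col] == lab, measure].dropna().to_numpy()
            groups[lab] = vals
        if any(len(v) < 2 for v in groups.values()):
            warnings.warn(f"measure {measure!r} skipped: a group has < 2 "
                          "observations", stacklevel=2)
            continue
        arrays = list(groups.values())
        normal = _normality_ok(arrays)
        row = {"measure": measure, "normal": normal}
        for lab, vals in groups.items():
            row[f"mean_{lab}"] = float(np.mean(vals))
            row[f"sd_{lab}"] = float(np.std(vals, ddof=1))
        if normal:
            _, lev_p = sps.levene(*arrays)
            equal_var = lev_p > ALPHA
            if len(arrays) > 2:
                if equal_var:
                    stat, p = sps.f_oneway(*arrays)
                    row["test"] = "anova"
                else:
                    from statsmodels.stats.oneway import anova_oneway
                    res = anova_oneway(arrays, use_var="unequal")
                    stat, p = res.statistic, res.pvalue
                    row["test"] = "welch-anova"
            else:
                stat, p = sps.ttest_ind(*arrays, equal_var=equal_var)
                row["test"] = "t-test" if equal_var else "welch-t"
            row.update(_pairwise(groups, parametric=True, equal_var=equal_var))
        else:
            if len(arrays) > 2:
                stat, p = sps.kruskal(*arrays)
                row["test"] = "kruskal-wallis"
            else:
                stat, p = sps.mannwhitneyu(*arrays, alternative="two-sided")
                row["test"] = "mann-whitney"
            row.update(_pairwise(groups, parametric=False, equal_var=False))
        row["statistic"] = float(stat)
        row["p_value"] = round(float(p), 3)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- CLI ----

def _resolve_params(name: Optional[str], config_file) -> ModelParams:
    if config_file:
        raw = load_config(config_file)
        return ModelParams(**raw.get("params", raw))
    if name is None:
        raise click.UsageError("give --params {control,dmd} or --config FILE")
    try:
        return FITTED_PARAMS[name]
    except KeyError:
        raise click.UsageError(f"unknown parameter preset {name!r}")


@click.group()
@click.version_option(__version__)
def cli():
    """Instance-based learning model of the Stroop task for DMD cognition."""


@cli.command()
@click.option("--params", "preset", type=click.Choice(sorted(FITTED_PARAMS)),
              default=None, help="fitted parameter preset")
@click.option("--config", "config_file", type=click.Path(exists=True), default=None)
@click.option("--n", default=20, show_default=True, help="number of sessions")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def simulate(preset, config_file, n, seed, out):
    """Simulate model sessions and write per-session Stroop counts."""
    params = _resolve_params(preset, config_file)
    frame = gen_model_subjects(params, n, seed=seed, group=preset or "custom")
    frame.to_csv(out, index=False)
    write_run_log(str(out) + ".log", RunConfig(seed=seed, params=params,
                                               output=str(out)),
                  {"n_sessions": n})
    click.echo(f"wrote {len(frame)} sessions to {out}")


@cli.command()
@click.option("--human", "human_file", type=click.Path(exists=True), required=True,
              help="CSV with stroop_w/stroop_c/stroop_cw (per subject or one row of means)")
@click.option("--grid", "grid_file", type=click.Path(exists=True), default=None)
@click.option("--sessions-per-point", default=20, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def fit(human_file, grid_file, sessions_per_point, seed, out):
    """Grid-fit the model to human per-sheet Stroop counts."""
    human = pd.read_csv(human_file)
    grid = FitGrid(**{k + "_values": tuple(v) for k, v in
                      load_config(grid_file).items()}) if grid_file else FitGrid()
    result = grid_fit(human, grid=grid, sessions_per_point=sessions_per_point,
                      base_seed=seed)
    payload = {
        "params": asdict(result.params), "fitness": result.fitness,
        "msd": result.msd, "msd_subjects": result.msd_subjects,
        "model_counts": result.model_counts,
    }
    Path(out).write_text(json.dumps(payload, indent=2) + "\n")
    result.trace.to_csv(str(out) + ".trace.csv", index=False)
    write_run_log(str(out) + ".log",
                  RunConfig(seed=seed, grid=grid, output=str(out)),
                  {"fitness": result.fitness})
    click.echo(json.dumps(payload["params"]))


@cli.command()
@click.option("--group", type=click.Choice(sorted(FITTED_PARAMS)), required=True)
@click.option("--n", default=20, show_default=True, help="data sessions to simulate")
@click.option("--grid", "grid_file", type=click.Path(exists=True), default=None)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def recover(group, n, grid_file, seed, out):
    """Forward-simulate a cohort at a fitted preset, then refit it.

    The refit reuses the data-generation seed and matches the number of
    simulated sessions per grid point to the cohort size, so the search at
    the true point replays the generating simulation (common random
    numbers)."""
    truth = FITTED_PARAMS[group]
    data = gen_model_subjects(truth, n, seed=seed, group=group)
    grid = FitGrid(**{k + "_values": tuple(v) for k, v in
                      load_config(grid_file).items()}) if grid_file else FitGrid()
    result = grid_fit(data, grid=grid, sessions_per_point=n, base_seed=seed)
    payload = {"truth": asdict(truth), "recovered": asdict(result.params),
               "fitness": result.fitness, "msd": result.msd}
    Path(out).write_text(json.dumps(payload, indent=2) + "\n")
    write_run_log(str(out) + ".log",
                  RunConfig(seed=seed, params=truth, output=str(out)),
                  {"recovered": json.dumps(asdict(result.params))})
    click.echo(json.dumps(payload["recovered"]))


@cli.command()
@click.option("--cohort", "cohort_file", type=click.Path(exists=True), default=None,
              help="cohort CSV; omit to generate the default synthetic cohort")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def score(cohort_file, seed, out):
    """Batch-score a cohort into the derived neuropsychological indices."""
    if cohort_file:
        frame = pd.read_csv(cohort_file)
    else:
        rng = np.random.default_rng(seed)
        records = []
        for profile in PROFILES.values():
            records.extend(gen_scores(profile, rng))
        frame = cohort_to_frame(records)
    score_cohort(frame).to_csv(out, index=False)
    write_run_log(str(out) + ".log", RunConfig(seed=seed, output=str(out)))
    click.echo(f"scored {len(frame)} subjects -> {out}")


@cli.command()
@click.option("--mutations", "mut_file", type=click.Path(exists=True), required=True,
              help="CSV with columns id, kind, exon_start, exon_end")
@click.option("--out", type=click.Path(), default=None)
def classify(mut_file, out):
    """Classify mutation records into Dp140 isoform calls."""
    frame = pd.read_csv(mut_file)
    calls = []
    for _, row in frame.iterrows():
        record = MutationRecord(
            kind=row["kind"],
            exon_start=None if pd.isna(row.get("exon_start")) else int(row["exon_start"]),
            exon_end=None if pd.isna(row.get("exon_end")) else int(row["exon_end"]))
        call = classify_dp140(record)
        calls.append({"id": row.get("id", ""), "dp140": call.dp140,
                      "low_confidence": call.low_confidence,
                      "rationale": call.rationale})
    result = frame.assign(**pd.DataFrame(calls).drop(columns="id"))
    if out:
        result.to_csv(out, index=False)
    click.echo(result[["kind", "dp140"]].to_string(index=False))


@cli.command()
@click.option("--groups", default="control,dp140_pos,dp140_neg", show_default=True)
@click.option("--measures", default="stroop_w,stroop_c,stroop_cw,dsf,dsb",
              show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def report(groups, measures, seed, out):
    """Synthetic-cohort group comparison table (means, tests, adjusted p)."""
    rng = np.random.default_rng(seed)
    records = []
    for name in groups.split(","):
        records.extend(gen_scores(PROFILES[name], rng))
    frame = cohort_to_frame(records)
    table = stats_report(frame, measures.split(","))
    table.to_csv(out, index=False)
    write_run_log(str(out) + ".log", RunConfig(seed=seed, output=str(out)))
    click.echo(table.to_string(index=False))
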