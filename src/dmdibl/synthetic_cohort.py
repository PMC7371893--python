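"""Synthetic subject cohorts with the group structure the analysis assumes.

The study's human data are not deposited, so analyses here run on synthetic
subjects drawn from group profiles: per-measure means and SDs for the
control, Dp140-positive (proximal mutation) and Dp140-negative (distal
mutation) groups, as published for the Stroop, RAVLT, digit-span and IQ
measures. Marginals are independent truncated normals whose location is
re-solved so the *truncated* mean equals the profile mean (plain truncation
at the task ceiling would otherwise bias bounded measures such as RAVLT
trial 5 visibly downward).

RAVLT trials 2-4 and List B have no published means; they are derived from
published anchors: a linear trial-1 to trial-5 learning shape rescaled to
match the published learning capacity (sum of trials 1-5), and List B from
the published proactive-interference ratio times trial 1.

Per-word recall grids (5 trials x 15 list positions, binary) are generated
so that each row sums exactly to the trial score and the expected mass in
the primacy / middle / recency bins matches the requested serial-position
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConfigError
from .genotype import MutationRecord
from .iblt_core import ModelParams
from .stroop_task import TaskConfig, simulate_sessions

RAVLT_MAX = 15          # words per list
N_POSITIONS = 15
BIN_SIZE = 5            # primacy / middle / recency bins

#: measure -> (lower bound, upper bound); None = unbounded above.
MEASURE_BOUNDS = {
    "stroop_w": (0.0, "sheet"), "stroop_c": (0.0, "sheet"), "stroop_cw": (0.0, "sheet"),
    "ravlt_t1": (0.0, 15.0), "ravlt_t2": (0.0, 15.0), "ravlt_t3": (0.0, 15.0),
    "ravlt_t4": (0.0, 15.0), "ravlt_t5": (0.0, 15.0), "ravlt_listb": (0.0, 15.0),
    "ravlt_t6": (0.0, 15.0), "ravlt_t7": (0.0, 15.0),
    "dsf": (0.0, None), "dsb": (0.0, None), "iq": (0.0, None),
}

__all__ = [
    "GroupProfile",
    "SubjectRecord",
    "PROFILES",
    "gen_scores",
    "gen_recall_grid",
    "gen_model_subjects",
    "cohort_to_frame",
]


@dataclass(frozen=True)
class GroupProfile:
    """Per-group generator profile: measure -> (mean, SD), subject count and
    serial-position bin targets (trial-1 triple and 5-trial totals)."""

    name: str
    n: int
    measures: Mapping[str, tuple]
    serial_t1: tuple = (2.5, 2.5, 2.5)
    serial_total: tuple = (12.5, 12.5, 12.5)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("profile n must be >= 1")
        for name, (mean, sd) in self.measures.items():
            if sd < 0:
                raise ConfigError(f"negative SD for {name}")


@dataclass
class SubjectRecord:
    """One synthetic subject: group label, scores, optional recall grid and
    (for DMD groups) a mutation record."""

    subject_id: str
    group: str
    scores: dict
    grid: Optional[np.ndarray] = None
    mutation: Optional[MutationRecord] = None


# Published group profiles. Trials 2-4 and List B are derived (see module
# docstring); every other entry is a published group mean (SD).
PROFILES = {
    "control": GroupProfile(
        name="control", n=80,
        measures={
            "stroop_w": (60.09, 13.4), "stroop_c": (46.79, 13.9), "stroop_cw": (28.34, 9.8),
            "ravlt_t1": (7.48, 1.91), "ravlt_t2": (9.59, 1.99), "ravlt_t3": (10.90, 2.07),
            "ravlt_t4": (12.21, 2.14), "ravlt_t5": (12.71, 2.22),
            "ravlt_listb": (6.58, 1.91), "ravlt_t6": (11.64, 2.74), "ravlt_t7": (11.38, 2.89),
            "dsf": (5.52, 1.21), "dsb": (3.59, 1.26), "iq": (108.0, 11.16),
        },
        serial_t1=(2.70, 2.21, 2.58), serial_total=(19.09, 16.52, 17.44),
    ),
    "dp140_neg": GroupProfile(
        name="dp140_neg", n=53,
        measures={
            "stroop_w": (52.30, 20.07), "stroop_c": (38.46, 13.71), "stroop_cw": (24.49, 9.44),
            "ravlt_t1": (6.73, 2.48), "ravlt_t2": (8.74, 2.66), "ravlt_t3": (9.90, 2.83),
            "ravlt_t4": (11.07, 3.01), "ravlt_t5": (11.38, 3.18),
            "ravlt_listb": (5.65, 2.48), "ravlt_t6": (10.15, 3.74), "ravlt_t7": (9.81, 3.48),
            "dsf": (4.94, 1.21), "dsb": (2.66, 1.84), "iq": (89.0, 19.94),
        },
        serial_t1=(2.37, 2.21, 2.06), serial_total=(17.17, 15.25, 15.46),
    ),
    "dp140_pos": GroupProfile(
        name="dp140_pos", n=14,
        measures={
            "stroop_w": (48.00, 20.52), "stroop_c": (37.25, 15.33), "stroop_cw": (20.25, 7.35),
            "ravlt_t1": (6.00, 2.69), "ravlt_t2": (8.68, 2.81), "ravlt_t3": (10.00, 2.93),
            "ravlt_t4": (11.32, 3.05), "ravlt_t5": (11.29, 3.17),
            "ravlt_listb": (5.52, 2.69), "ravlt_t6": (9.79, 3.02), "ravlt_t7": (9.93, 2.92),
            "dsf": (4.73, 1.19), "dsb": (2.64, 1.29), "iq": (90.0, 10.75),
        },
        serial_t1=(2.50, 1.71, 1.64), serial_total=(17.79, 13.36, 15.29),
    ),
}


def _corrected_loc(target: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal N(loc, sd) on [lo, hi] whose truncated
    mean equals ``target``."""
    if not (lo < target < hi):
        raise ConfigError(f"mean {target} not inside bounds ({lo}, {hi})")
    # Bounds effectively non-binding: skip the solve.
    if target - lo > 8 * sd and hi - target > 8 * sd:
        return target

    def tmean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target

    span = 10 * sd
    return float(optimize.brentq(tmean, target - span, target + span, xtol=1e-10))


def _draw_measure(target: float, sd: float, lo: float, hi: Optional[float],
                  n: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(n, target)
    hi_val = np.inf if hi is None else hi
    loc = _corrected_loc(target, sd, lo, hi_val)
    a, b = (lo - loc) / sd, (hi_val - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def _sample_mutation(group: str, rng: np.random.Generator) -> Optional[MutationRecord]:
    if group == "dp140_neg":
        end = int(rng.integers(44, 56))
    elif group == "dp140_pos":
        end = int(rng.integers(2, 44))
    else:
        return None
    start = int(rng.integers(max(1, end - 10), end + 1))
    return MutationRecord(kind="deletion", exon_start=start, exon_end=end)


def gen_scores(profile: GroupProfile, rng: np.random.Generator,
               n: Optional[int] = None, with_grids: bool = False,
               sheet_length: int = 100) -> list:
    """Draw ``n`` subjects (default: the profile's group size).

    Each measure is an independent mean-corrected truncated normal within
    its task bounds. With ``with_grids=True``, RAVLT trial scores are
    unbiased-rounded to integers and a recall grid consistent with them is
    attached to every subject.
    """
    n = profile.n if n is None else n
    cols = {}
    for name, (mean, sd) in profile.measures.items():
        lo, hi = MEASURE_BOUNDS.get(name, (0.0, None))
        if hi == "sheet":
            hi = float(sheet_length)
        cols[name] = _draw_measure(mean, sd, lo, hi, n, rng)

    targets = {"t1": profile.serial_t1, "total": profile.serial_total}
    records = []
    for i in range(n):
        scores = {name: float(col[i]) for name, col in cols.items()}
        grid = None
        if with_grids:
            trial_keys = [f"ravlt_t{t}" for t in range(1, 6)]
            ints = [_unbiased_round(scores[kk], rng) for kk in trial_keys]
            for kk, v in zip(trial_keys, ints):
                scores[kk] = float(v)
            grid = gen_recall_grid(ints, targets, rng)
        records.append(SubjectRecord(
            subject_id=f"{profile.name}-{i:03d}", group=profile.name,
            scores=scores, grid=grid,
            mutation=_sample_mutation(profile.name, rng)))
    return records


def _unbiased_round(x: float, rng: np.random.Generator) -> int:
    lo = int(np.floor(x))
    val = lo + int(rng.random() < (x - lo))
    return int(np.clip(val, 0, RAVLT_MAX))


def _trial_targets(targets, trial: int) -> np.ndarray:
    """Bin-mass triple for one trial from t1 + totals targets (or a single
    triple applied to every trial)."""
    if isinstance(targets, Mapping):
        t1 = np.asarray(targets["t1"], dtype=float)
        total = np.asarray(targets["total"], dtype=float)
        triple = t1 if trial == 0 else (total - t1) / 4.0
    else:
        triple = np.asarray(targets, dtype=float)
    if triple.shape != (3,):
        raise ConfigError("serial-position targets must be a length-3 triple")
    if np.any(triple < 0) or np.any(triple > BIN_SIZE):
        raise ConfigError(
            f"infeasible serial-position targets {triple.tolist()} (bin max {BIN_SIZE})")
    return triple


def _capped_allocation(k: int, q: np.ndarray) -> np.ndarray:
    """Expected per-bin counts k*q, redistributing any excess above the bin
    capacity of 5 to the remaining bins."""
    a = k * q.astype(float)
    for _ in range(3):
        over = a > BIN_SIZE
        if not over.any():
            break
        excess = float(np.sum(a[over] - BIN_SIZE))
        a[over] = BIN_SIZE
        free = ~over
        if not free.any():
            break
        a[free] += excess * a[free] / np.sum(a[free]) if np.sum(a[free]) > 0 \
            else excess / np.sum(free)
    return a


def _systematic_round(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Round a nonnegative vector with integer sum k to integers with exact
    expectation: systematic sampling over the cumulative profile."""
    k = int(round(float(np.sum(a))))
    if k == 0:
        return np.zeros(len(a), dtype=int)
    edges = np.concatenate([[0.0], np.cumsum(a)])
    edges[-1] = float(k)  # guard float drift
    points = np.arange(k) + rng.random()
    return np.histogram(points, bins=edges)[0].astype(int)


def gen_recall_grid(trial_scores: Sequence[int], serial_position_targets,
                    rng: np.random.Generator) -> np.ndarray:
    """Binary 5 x 15 recall grid whose row sums equal the trial scores and
    whose expected primacy/middle/recency masses match the targets."""
    scores = [int(s) for s in trial_scores]
    if len(scores) != 5 or any(s < 0 or s > RAVLT_MAX for s in scores):
        raise ConfigError("need 5 trial scores in [0, 15]")
    grid = np.zeros((5, N_POSITIONS), dtype=int)
    for t, k in enumerate(scores):
        triple = _trial_targets(serial_position_targets, t)
        if k == 0:
            continue
        if k == N_POSITIONS:
            grid[t] = 1
            continue
        total = float(np.sum(triple))
        q = triple / total if total > 0 else np.full(3, 1 / 3)
        counts = _systematic_round(_capped_allocation(k, q), rng)
        for b, nb in enumerate(counts):
            if nb:
                pos = BIN_SIZE * b + rng.choice(BIN_SIZE, size=nb, replace=False)
                grid[t, pos] = 1
    return grid


def gen_model_subjects(params: ModelParams, n: int,
                       seed: Union[int, np.random.SeedSequence],
                       config: Optional[TaskConfig] = None,
                       group: str = "model",
                       noise_on: bool = True) -> pd.DataFrame:
    """Forward-simulate ``n`` model sessions and tabulate per-sheet counts
    and mean per-item latencies (one row per synthetic subject)."""
    cfg = config or TaskConfig()
    sessions = simulate_sessions(params, cfg, n, seed=seed, noise_on=noise_on)
    rows = []
    for i, res in enumerate(sessions):
        rows.append({
            "subject_id": f"{group}-{i:03d}", "group": group,
            "stroop_w": res.w, "stroop_c": res.c, "stroop_cw": res.cw,
            "rt_w": res.sheets["word"].mean_rt,
            "rt_c": res.sheets["color"].mean_rt,
            "rt_cw": res.sheets["color_word"].mean_rt,
        })
    columns = ["subject_id", "group", "stroop_w", "stroop_c", "stroop_cw",
               "rt_w", "rt_c", "rt_cw"]
    return pd.DataFrame(rows, columns=columns)


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten SubjectRecords to a tidy table (one row per subject)."""
    rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id, "group": rec.group}
        row.update(rec.scores)
        if rec.mutation is not None:
            row["mutation_kind"] = rec.mutation.kind
            row["exon_start"] = rec.mutation.exon_start
            row["exon_end"] = rec.mutation.exon_end
        rows.append(row)
    return pd.DataFrame(rows)
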