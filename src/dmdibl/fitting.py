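"""Grid ("hit and trial") parameter search and model-vs-human comparison.

The search enumerates a lattice over the four fitted scalars (F, f, d, s),
simulates a batch of sessions at every point with common random numbers,
and scores each point by the fitness function: the mean absolute difference
between model and human per-sheet word counts. Model mean-square deviation
(MSD) is reported both over sheet means and - when per-subject scores are
supplied - over subjects and sheets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _engine
from .exceptions import AlignmentError, ConfigError
from .iblt_core import ModelParams
from .stroop_task import SHEET_KINDS, TaskConfig, simulate_sessions

#: Fitted reference parameter sets for the two modelled groups
#: (control vs the Dp140-negative DMD group).
FITTED_PARAMS = {
    "control": ModelParams(F=1.0, f=0.003, d=5.0, s=2.0),
    "dmd": ModelParams(F=1.0, f=0.005, d=4.0, s=2.0),
}

#: Column names used for per-subject Stroop counts in score tables.
STROOP_COLUMNS = {"word": "stroop_w", "color": "stroop_c", "color_word": "stroop_cw"}

DEFAULT_BASE_SEED = 190871  # fixed base seed for common random numbers

__all__ = [
    "FITTED_PARAMS",
    "STROOP_COLUMNS",
    "FitGrid",
    "FitResult",
    "fitness",
    "msd",
    "grid_fit",
    "compare_groups",
]


@dataclass(frozen=True)
class FitGrid:
    """Inclusive parameter lattice. Defaults: d and s step 1 over [0, 10],
    f step 0.001 over [0, 0.01], F fixed at its default of 1."""

    F_values: tuple = (1.0,)
    f_values: tuple = tuple(np.round(np.arange(0.0, 0.0101, 0.001), 6))
    d_values: tuple = tuple(float(v) for v in range(11))
    s_values: tuple = tuple(float(v) for v in range(11))

    def __post_init__(self) -> None:
        for name, values, lo, hi in (
            ("F", self.F_values, 0.0, 1.0),
            ("f", self.f_values, 0.0, 1.0),
            ("d", self.d_values, 0.0, 10.0),
            ("s", self.s_values, 0.0, 10.0),
        ):
            if len(values) == 0:
                raise ConfigError(f"empty grid for {name}")
            arr = np.asarray(values, dtype=float)
            if arr.min() < lo or arr.max() > hi:
                raise ConfigError(
                    f"{name} grid outside its normal range [{lo}, {hi}]")

    def points(self):
        """Grid points in the tie-break order: lexicographic by (d, s, f, F)."""
        for d in self.d_values:
            for s in self.s_values:
                for f in self.f_values:
                    for F in self.F_values:
                        yield F, f, d, s

    def size(self) -> int:
        return (len(self.F_values) * len(self.f_values)
                * len(self.d_values) * len(self.s_values))


@dataclass
class FitResult:
    params: ModelParams
    fitness: float
    msd: float
    model_counts: dict
    msd_subjects: Optional[float] = None
    trace: Optional[pd.DataFrame] = None
    sessions_per_point: int = 0
    base_seed: int = 0


def _aligned(model, human):
    """Return (model, human) as aligned 1-D arrays over common sheet keys."""
    if isinstance(model, Mapping) != isinstance(human, Mapping):
        raise AlignmentError("model and human counts must both be mappings "
                             "or both be sequences")
    if isinstance(model, Mapping):
        if set(model) != set(human):
            raise AlignmentError(
                f"sheet mismatch: {sorted(model)} vs {sorted(human)}")
        keys = [k for k in SHEET_KINDS if k in model] or sorted(model)
        m = np.array([model[k] for k in keys], dtype=float)
        h = np.array([human[k] for k in keys], dtype=float)
    else:
        m = np.asarray(model, dtype=float)
        h = np.asarray(human, dtype=float)
        if m.shape != h.shape:
            raise AlignmentError(f"shape mismatch: {m.shape} vs {h.shape}")
    return m, h


def fitness(model_counts, human_counts) -> float:
    """Mean absolute difference between model and human per-sheet counts."""
    m, h = _aligned(model_counts, human_counts)
    return float(np.mean(np.abs(h - m)))


def msd(model_counts, human_counts) -> float:
    """Mean square deviation between model and human counts.

    ``human_counts`` may be a per-sheet mapping of means, or a 2-D array
    (subjects x sheets) in which case the mean runs over subjects as well.
    """
    if not isinstance(human_counts, Mapping):
        h = np.asarray(human_counts, dtype=float)
        if h.ndim == 2:
            m = np.asarray([model_counts[k] for k in SHEET_KINDS], dtype=float) \
                if isinstance(model_counts, Mapping) else np.asarray(model_counts, float)
            if h.shape[1] != m.shape[0]:
                raise AlignmentError(
                    f"subject matrix has {h.shape[1]} sheets, model has {m.shape[0]}")
            return float(np.mean((h - m[None, :]) ** 2))
    m, h = _aligned(model_counts, human_counts)
    return float(np.mean((h - m) ** 2))


def _human_views(human_data):
    """Split human input into (per-sheet means, optional subject matrix)."""
    if isinstance(human_data, pd.DataFrame):
        cols = [STROOP_COLUMNS[k] for k in SHEET_KINDS]
        missing = [c for c in cols if c not in human_data.columns]
        if missing:
            raise AlignmentError(f"missing subject columns: {missing}")
        mat = human_data[cols].to_numpy(dtype=float)
        means = {k: float(mat[:, i].mean()) for i, k in enumerate(SHEET_KINDS)}
        return means, mat
    if isinstance(human_data, Mapping):
        if not human_data:
            raise AlignmentError("empty human data")
        return dict(human_data), None
    raise AlignmentError("human data must be a per-sheet mapping or a DataFrame")


def mean_counts(sessions) -> dict:
    """Per-sheet mean completion counts over a list of SessionResults."""
    return {
        "word": float(np.mean([r.w for r in sessions])),
        "color": float(np.mean([r.c for r in sessions])),
        "color_word": float(np.mean([r.cw for r in sessions])),
    }


def grid_fit(human_data, grid: Optional[FitGrid] = None,
             task_config: Optional[TaskConfig] = None,
             fixed: Optional[Mapping[str, float]] = None,
             sessions_per_point: int = 20,
             base_seed: int = DEFAULT_BASE_SEED,
             noise_on: bool = True,
             keep_trace: bool = True) -> FitResult:
    """Exhaustive grid search minimizing the fitness function.

    Every grid point simulates ``sessions_per_point`` sessions from the same
    ``base_seed`` (common random numbers: identical sheets and noise tables
    across points), averages per-sheet counts and scores them against the
    human per-sheet means. Ties are broken lexicographically by (d, s, f, F)
    through the enumeration order. ``human_data`` is either a mapping of
    per-sheet mean counts or a per-subject DataFrame with columns
    stroop_w / stroop_c / stroop_cw, in which case a subject-level MSD is
    also attached to the result.
    """
    grid = grid or FitGrid()
    cfg = task_config or TaskConfig()
    fixed = dict(fixed or {})
    human_means, subject_matrix = _human_views(human_data)
    if sessions_per_point < 1:
        raise ConfigError("sessions_per_point must be >= 1")

    prepared = _engine.prepare_sessions(cfg, base_seed, sessions_per_point)
    best = None
    best_counts = None
    rows = []
    for F, f, d, s in grid.points():
        params = ModelParams(F=F, f=f, d=d, s=s, **fixed)
        sessions = simulate_sessions(params, cfg, sessions_per_point,
                                     seed=base_seed, noise_on=noise_on,
                                     prepared=prepared)
        counts = mean_counts(sessions)
        fit = fitness(counts, human_means)
        if keep_trace:
            rows.append({"F": F, "f": f, "d": d, "s": s, "fitness": fit})
        if best is None or fit < best[1]:
            best = (params, fit)
            best_counts = counts
    params, fit = best
    result = FitResult(
        params=params,
        fitness=fit,
        msd=msd(best_counts, human_means),
        model_counts=best_counts,
        trace=pd.DataFrame(rows) if keep_trace else None,
        sessions_per_point=sessions_per_point,
        base_seed=base_seed,
    )
    if subject_matrix is not None:
        result.msd_subjects = msd(best_counts, subject_matrix)
    return result


def compare_groups(fit_a: FitResult, fit_b: FitResult,
                   label_a: str = "control", label_b: str = "dmd") -> dict:
    """Side-by-side report of two fits: parameter sets in the standard
    (F, f, d, s) layout, their MSDs, and the MSD ordering."""
    def row(fit):
        p = fit.params
        return {"F": p.F, "f": p.f, "d": p.d, "s": p.s,
                "fitness": fit.fitness, "msd": fit.msd,
                "msd_subjects": fit.msd_subjects}

    table = pd.DataFrame([row(fit_a), row(fit_b)], index=[label_a, label_b])

    def ordering(x, y):
        if x is None or y is None:
            return "unavailable"
        if x > y:
            return f"{label_a} > {label_b}"
        if y > x:
            return f"{label_b} > {label_a}"
        return "no difference"

    return {
        "table": table,
        "msd_ordering": ordering(fit_a.msd, fit_b.msd),
        "msd_subjects_ordering": ordering(fit_a.msd_subjects, fit_b.msd_subjects),
    }
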