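"""Three-sheet Stroop Color and Word Task simulation on the memory core.

A session runs a word-reading sheet, a color-naming sheet and an
incongruent color-word sheet in that order, each under a 45 second budget,
on a single memory store. Naming an item is a retrieval: the probe requests
the to-be-named attribute, and on the color-word sheet the printed word is
supplied as a second requested slot so that partial matching penalizes every
candidate - the Stroop effect emerges as longer retrieval times and hence a
lower completion count.

The store is primed at session start with one instance per color-word and
one per ink color (pre-experimental familiarity with reading color words and
naming colors), each carrying a single retrieval event at index 0. Within a
sheet every committed retrieval reinforces the winning instance, so the
instances laid down on the first two sheets shape retrieval on the third.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import ConfigError
from .iblt_core import MemoryStore, ModelParams, Probe, retrieve

NEUTRAL_WORD = "xxxx"   # letter string on color-naming sheet items
NEUTRAL_INK = "black"   # ink used for the word-reading sheet

SHEET_KINDS = ("word", "color", "color_word")

__all__ = [
    "NEUTRAL_WORD",
    "NEUTRAL_INK",
    "SHEET_KINDS",
    "TaskConfig",
    "StroopItem",
    "StroopSheet",
    "SheetResult",
    "SessionResult",
    "make_sheet",
    "prime_store",
    "build_probe",
    "seed_instances",
    "simulate_sheet",
    "simulate_session",
    "simulate_sessions",
    "score_session",
]


@dataclass(frozen=True)
class TaskConfig:
    """Geometry of the simulated task: color set, sheet length, time budget."""

    colors: tuple = ("red", "green", "blue", "yellow")
    n_items: int = 100
    time_budget: float = 45.0
    failure_penalty: float = 1.0  # seconds charged for a skipped (failed) item

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ConfigError("n_items must be >= 1")
        if len(self.colors) < 2:
            raise ConfigError("need at least 2 colors")
        if self.time_budget < 0:
            raise ConfigError("time_budget must be >= 0")


@dataclass(frozen=True)
class StroopItem:
    word: str
    ink: str

    @property
    def congruent(self) -> bool:
        return self.word == self.ink


@dataclass
class StroopSheet:
    kind: str
    items: list
    time_budget: float = 45.0


@dataclass
class SheetResult:
    kind: str
    items_completed: int
    latencies: np.ndarray
    n_failures: int = 0

    @property
    def total_time(self) -> float:
        return float(np.sum(self.latencies))

    @property
    def mean_rt(self) -> float:
        return float(np.mean(self.latencies)) if len(self.latencies) else float("nan")


@dataclass
class SessionResult:
    """Per-sheet completion counts and the derived Stroop-effect scores."""

    w: float
    c: float
    cw: float
    effect1: float = field(init=False)
    effect2: float = field(init=False)
    effect3: float = field(init=False)
    sheets: Optional[dict] = None

    def __post_init__(self) -> None:
        self.effect1 = self.c - self.cw
        self.effect2 = self.cw / self.w if self.w > 0 else float("nan")
        self.effect3 = self.cw / self.c if self.c > 0 else float("nan")


def score_session(w: float, c: float, cw: float) -> SessionResult:
    """Derive the three Stroop-effect scores from per-sheet word counts:
    effect1 = C - CW, effect2 = CW / W, effect3 = CW / C (NaN on zero
    denominators)."""
    return SessionResult(w=w, c=c, cw=cw)


def make_sheet(kind: str, n_items: int, colors: Sequence[str],
               rng: np.random.Generator, time_budget: float = 45.0) -> StroopSheet:
    """Build one sheet of ``n_items`` items.

    word: color words printed in the neutral ink. color: neutral letter
    strings printed in colored ink. color_word: color words whose ink always
    differs from the word (incongruent stimuli only).
    """
    if kind not in SHEET_KINDS:
        raise ConfigError(f"unknown sheet kind {kind!r}")
    if n_items < 1:
        raise ConfigError("n_items must be >= 1")
    k = len(colors)
    if k < 1 or (kind == "color_word" and k < 2):
        raise ConfigError("color_word sheets need at least 2 colors")
    if kind == "word":
        idx = rng.integers(0, k, size=n_items)
        items = [StroopItem(word=colors[i], ink=NEUTRAL_INK) for i in idx]
    elif kind == "color":
        idx = rng.integers(0, k, size=n_items)
        items = [StroopItem(word=NEUTRAL_WORD, ink=colors[i]) for i in idx]
    else:
        widx = rng.integers(0, k, size=n_items)
        off = rng.integers(1, k, size=n_items)
        items = [StroopItem(word=colors[w], ink=colors[(w + o) % k])
                 for w, o in zip(widx, off)]
    return StroopSheet(kind=kind, items=items, time_budget=time_budget)


def prime_store(colors: Sequence[str]) -> MemoryStore:
    """Session-start store: one word-reading and one color-naming instance
    per color, each with a single retrieval event at index 0."""
    store = MemoryStore(now=1)
    for c in colors:
        store.add(color=NEUTRAL_INK, word=c, events=[0])
    for c in colors:
        store.add(color=c, word=NEUTRAL_WORD, events=[0])
    return store


def build_probe(kind: str, item: StroopItem, params: ModelParams) -> Probe:
    """Probe for naming one item: the to-be-named attribute is requested;
    on the color-word sheet the printed word is a second requested slot."""
    if kind == "word":
        return Probe(requested={"word": item.word}, weights={"word": params.P})
    if kind == "color":
        return Probe(requested={"color": item.ink}, weights={"color": params.P})
    return Probe(requested={"color": item.ink, "word": item.word},
                 weights={"color": params.P, "word": params.P})


def seed_instances(store: MemoryStore, *sheet_results) -> MemoryStore:
    """Populate ``store`` from already-scored sheets: for every completed
    item, ensure its (color, word) instance exists and record one retrieval
    event. Identical items merge into one instance with multiple events."""
    for sheet, result in sheet_results:
        for item in sheet.items[: result.items_completed]:
            inst = store.add(color=item.ink, word=item.word)
            store.record(inst)
    return store


def simulate_sheet(sheet: StroopSheet, store: MemoryStore, params: ModelParams,
                   rng: Optional[np.random.Generator] = None,
                   noise_on: bool = True,
                   failure_penalty: float = 1.0) -> SheetResult:
    """Run one sheet: items in order, each costing RT + t_nonretrieval,
    stopping before the item whose cost would exceed the time budget.

    A retrieval failure (only possible with ``params.tau`` set) skips the
    item, charging ``failure_penalty`` seconds without recording an event.
    """
    latencies: list[float] = []
    n_fail = 0
    t = 0.0
    for item in sheet.items:
        probe = build_probe(sheet.kind, item, params)
        out = retrieve(store, probe, params, rng=rng, noise_on=noise_on,
                       advance=False)
        if out.failed:
            if t + failure_penalty > sheet.time_budget:
                break
            t += failure_penalty
            n_fail += 1
            continue
        cost = out.rt + params.t_nonretrieval
        if t + cost > sheet.time_budget:
            break
        store.record(out.instance)
        latencies.append(cost)
        t += cost
    return SheetResult(kind=sheet.kind, items_completed=len(latencies),
                       latencies=np.asarray(latencies), n_failures=n_fail)


def _session_rngs(seed: Union[int, np.random.SeedSequence]):
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sheet_ss, ret_ss = ss.spawn(2)
    return np.random.default_rng(sheet_ss), np.random.default_rng(ret_ss)


def simulate_session(params: ModelParams, config: TaskConfig,
                     seed: Union[int, np.random.SeedSequence],
                     noise_on: bool = True) -> SessionResult:
    """One full session: word -> color -> color_word on a carried store.

    Two independent RNG streams are derived from ``seed``: one builds the
    three sheets, the other drives retrieval noise; identical seeds give
    identical results. Within-sheet retrieval records events live, which is
    what seeds the color-word sheet with the instances laid down on the
    first two sheets.
    """
    rng_sheet, rng_ret = _session_rngs(seed)
    sheets = [make_sheet(kind, config.n_items, config.colors, rng_sheet,
                         time_budget=config.time_budget)
              for kind in SHEET_KINDS]
    store = prime_store(config.colors)
    results = {}
    for sheet in sheets:
        results[sheet.kind] = simulate_sheet(
            sheet, store, params, rng=rng_ret, noise_on=noise_on,
            failure_penalty=config.failure_penalty)
    out = score_session(results["word"].items_completed,
                        results["color"].items_completed,
                        results["color_word"].items_completed)
    out.sheets = results
    return out


def simulate_sessions(params: ModelParams, config: TaskConfig, n: int,
                      seed: Union[int, np.random.SeedSequence],
                      noise_on: bool = True,
                      prepared=None) -> list:
    """``n`` independent sessions via the vectorized engine.

    Result-equivalent to ``[simulate_session(params, config, s) for s in
    SeedSequence(seed).spawn(n)]`` but runs all sessions in lockstep numpy
    arrays (the fitting grid relies on this path). ``prepared`` allows the
    caller to reuse pre-built sheets and noise tables across parameter
    points (common random numbers).
    """
    from . import _engine  # local import to avoid a cycle

    if n == 0:
        return []
    if prepared is None:
        prepared = _engine.prepare_sessions(config, seed, n)
    return _engine.run_sessions(params, config, prepared, noise_on=noise_on)
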