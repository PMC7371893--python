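"""Instance-based declarative memory core.

Implements the ACT-R style memory equations that drive the Stroop model:
base-level activation with power-law decay over discrete retrieval events,
partial matching with a per-slot mismatch penalty, additive logistic
activation noise, and the latency law mapping activation to retrieval time.

Time is counted in *events*: the store keeps an integer clock ``now`` that
advances by one per committed retrieval, and base-level activation of an
instance sums ``(now - t_i)^-d`` over its past retrieval events ``t_i``.
Seconds appear only in retrieval time, ``RT = F * exp(-f * A)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import (
    ContractError,
    NoHistoryError,
    ParameterError,
    RetrievalError,
    VocabularyError,
)

# Uniform draws are clipped away from {0, 1} before the logit so that the
# logistic noise stays finite. Applied identically in the batched engine.
_U_EPS = 1e-12

__all__ = [
    "Instance",
    "ModelParams",
    "Probe",
    "MemoryStore",
    "RetrievalOutcome",
    "base_level_activation",
    "mismatch",
    "logistic_noise",
    "noise_draw",
    "activation",
    "retrieval_time",
    "retrieve",
]


@dataclass
class Instance:
    """One memory trace: situation slots (color, word), outcome utility and
    the ordered event indices at which it was retrieved."""

    color: str
    word: str
    outcome: float = 1.0
    retrieval_events: list = field(default_factory=list)
    created: int = 0

    @property
    def slots(self) -> dict:
        return {"color": self.color, "word": self.word}


@dataclass
class ModelParams:
    """The fitted scalars of the model plus fixed task-timing constants.

    F : latency factor (seconds), normal range 0-1.
    f : latency exponent (unitless), normal range 0-1.
    d : base-level decay (unitless), normal range 0-10.
    s : logistic noise scale (unitless), normal range 0-10.
    P : mismatch penalty weight per probe slot (>= 0). The default of 15
        keeps the penalty decisive against the recency term d*ln(lag) over
        the fitted decay range, so retrieval is match-driven rather than
        perseverative; see the methods note.
    tau : optional retrieval threshold; retrieval fails below it.
    t_nonretrieval : fixed per-item encoding/response overhead (seconds).
    """

    F: float = 1.0
    f: float = 0.0
    d: float = 0.5
    s: float = 0.0
    P: float = 15.0
    tau: Optional[float] = None
    t_nonretrieval: float = 0.0

    def __post_init__(self) -> None:
        checks = [
            ("F", self.F, 0.0, 1.0),
            ("f", self.f, 0.0, 1.0),
            ("d", self.d, 0.0, 10.0),
            ("s", self.s, 0.0, 10.0),
        ]
        for name, value, lo, hi in checks:
            if not (lo <= value <= hi):
                raise ParameterError(
                    f"{name}={value!r} outside its normal range [{lo}, {hi}]"
                )
        if self.P < 0:
            raise ParameterError(f"P={self.P!r} must be >= 0")
        if self.t_nonretrieval < 0:
            raise ParameterError(
                f"t_nonretrieval={self.t_nonretrieval!r} must be >= 0"
            )


@dataclass
class Probe:
    """A retrieval request: requested slot values and per-slot penalty
    weights ``P_l``."""

    requested: Mapping[str, str]
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for slot, w in self.weights.items():
            if w < 0:
                raise ParameterError(f"penalty weight for slot {slot!r} is negative")
        missing = set(self.requested) - {"color", "word"}
        if missing:
            raise VocabularyError(f"unknown probe slots: {sorted(missing)}")


@dataclass
class RetrievalOutcome:
    """Result of one retrieval attempt."""

    instance: Optional[Instance]
    rt: Optional[float]
    activation: float
    failed: bool = False


class MemoryStore:
    """A declarative memory: instances plus the current event clock.

    ``now`` is the index the *next* committed retrieval event will receive;
    all recorded events are strictly in the past.
    """

    def __init__(self, now: int = 1) -> None:
        self.instances: list[Instance] = []
        self.now = now
        self._index: dict[tuple, Instance] = {}

    def __len__(self) -> int:
        return len(self.instances)

    def add(self, color: str, word: str, events: Optional[Sequence[int]] = None,
            outcome: float = 1.0) -> Instance:
        """Get-or-create the instance with situation (color, word)."""
        key = (color, word)
        inst = self._index.get(key)
        if inst is None:
            inst = Instance(color=color, word=word, outcome=outcome,
                            retrieval_events=list(events or []),
                            created=len(self.instances))
            self.instances.append(inst)
            self._index[key] = inst
        elif events:
            inst.retrieval_events.extend(events)
        return inst

    def find(self, color: str, word: str) -> Optional[Instance]:
        return self._index.get((color, word))

    def record(self, instance: Instance) -> None:
        """Commit a retrieval of ``instance`` at the current event index."""
        instance.retrieval_events.append(self.now)
        self.now += 1

    def copy(self) -> "MemoryStore":
        clone = MemoryStore(now=self.now)
        for inst in self.instances:
            clone.add(inst.color, inst.word, events=list(inst.retrieval_events),
                      outcome=inst.outcome)
        return clone


def base_level_activation(instance: Instance, now: int, d: float) -> float:
    """Base-level activation ``B_i = ln(sum over past events (now - t_i)^-d)``.

    Raises NoHistoryError for an instance that was never retrieved and
    ContractError if any event is not strictly in the past.
    """
    events = np.asarray(instance.retrieval_events, dtype=float)
    if events.size == 0:
        raise NoHistoryError("instance has no retrieval history")
    lags = now - events
    if np.any(lags <= 0):
        raise ContractError("retrieval event at or after the current event index")
    return float(np.log(np.sum(lags ** (-d))))


def mismatch(requested: str, stored: str,
             vocabulary: Optional[Sequence[str]] = None,
             similarity: Optional[Mapping[frozenset, float]] = None) -> float:
    """Mismatch ``M`` in [-1, 0] between a requested and a stored slot value.

    Equal values give 0. Otherwise -1 (binary default), or ``sim - 1``
    when a graded similarity in [0, 1] is declared for the unordered pair.
    """
    if vocabulary is not None:
        for value in (requested, stored):
            if value not in vocabulary:
                raise VocabularyError(f"value {value!r} not in vocabulary")
    if requested == stored:
        return 0.0
    if similarity:
        sim = similarity.get(frozenset((requested, stored)))
        if sim is not None:
            if not (0.0 <= sim <= 1.0):
                raise ParameterError(f"similarity {sim!r} outside [0, 1]")
            return sim - 1.0
    return -1.0


def logistic_noise(s: float, u: float) -> float:
    """Deterministic kernel of the activation noise: ``s * ln((1-u)/u)``."""
    if s < 0:
        raise ParameterError(f"noise scale s={s!r} must be >= 0")
    u = min(max(u, _U_EPS), 1.0 - _U_EPS)
    return s * math.log((1.0 - u) / u)


def noise_draw(s: float, rng: np.random.Generator) -> float:
    """One activation-noise draw: logistic with scale ``s`` via a uniform u."""
    return logistic_noise(s, float(rng.random()))


def activation(instance: Instance, probe: Probe, params: ModelParams, now: int,
               rng: Optional[np.random.Generator] = None, noise_on: bool = True,
               similarity: Optional[Mapping[frozenset, float]] = None) -> float:
    """Total activation ``A = B + sum_l P_l * M_l + eps``.

    With ``noise_on=False`` (or no rng supplied) the noise term is zero.
    """
    a = base_level_activation(instance, now, params.d)
    stored = instance.slots
    for slot, wanted in probe.requested.items():
        a += probe.weights.get(slot, params.P) * mismatch(
            wanted, stored[slot], similarity=similarity)
    if noise_on and rng is not None:
        a += noise_draw(params.s, rng)
    return a


def retrieval_time(a: float, F: float, f: float) -> float:
    """Latency law ``RT = F * exp(-f * A)`` (seconds)."""
    if F < 0:
        raise ParameterError(f"latency factor F={F!r} must be >= 0")
    return F * math.exp(-f * a)


def retrieve(store: MemoryStore, probe: Probe, params: ModelParams,
             rng: Optional[np.random.Generator] = None, noise_on: bool = True,
             advance: bool = True,
             similarity: Optional[Mapping[frozenset, float]] = None
             ) -> RetrievalOutcome:
    """Noisy-argmax retrieval of the best partially matching instance.

    Every instance is scored with ``activation``; the highest-activation
    instance wins, ties going to the earliest-created instance. On success
    the winner's event list is appended and ``store.now`` advances (unless
    ``advance=False``, which lets callers commit separately via
    ``store.record``). If ``params.tau`` is set and the best activation
    falls below it, the attempt fails and nothing is committed.
    """
    n = len(store)
    if n == 0:
        raise RetrievalError("cannot retrieve from an empty store")
    if noise_on and rng is not None:
        u = rng.random(n)
        eps = [logistic_noise(params.s, float(ui)) for ui in u]
    else:
        eps = [0.0] * n
    best_i = -1
    best_a = -math.inf
    for i, inst in enumerate(store.instances):
        a = activation(inst, probe, params, store.now, rng=None,
                       noise_on=False, similarity=similarity) + eps[i]
        if a > best_a:  # strict: first max wins, i.e. lowest creation index
            best_a = a
            best_i = i
    if params.tau is not None and best_a < params.tau:
        return RetrievalOutcome(None, None, best_a, failed=True)
    winner = store.instances[best_i]
    rt = retrieval_time(best_a, params.F, params.f)
    if advance:
        store.record(winner)
    return RetrievalOutcome(winner, rt, best_a)
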