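"""Derived neuropsychological indices: RAVLT, digit span, IQ banding.

RAVLT: five learning trials (t1-t5) of a 15-word list, an interference
list B, immediate recall (t6) and delayed recall (t7). Indices:

* learning capacity  = t1 + t2 + t3 + t4 + t5
* proactive interference  PI = listB / t1
* retroactive interference RI = t6 / t5
* forgetting speed = t7 / t6
* long-term percent retention LTPR = 100 * t7 / t5
* serial position: primacy / middle / recency = recalled words in list
  positions 1-5 / 6-10 / 11-15, reported for trial 1 and summed over
  trials 1-5.

Undefined ratios (zero denominators) and missing inputs are reported as
NaN markers, never dropped. The RAVLT memory-efficiency index (MEI) has no
closed form here; it is exposed as a pluggable callable whose report
carries the published interpretive cut-offs 1.2 and 1.9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ShapeError

#: Interpretive cut-offs for the RAVLT memory-efficiency index.
MEI_CUTOFFS = (1.2, 1.9)

__all__ = [
    "RAVLTRecord",
    "DigitSpanRecord",
    "IQRecord",
    "MEI_CUTOFFS",
    "learning_capacity",
    "interference_and_retention",
    "serial_position",
    "attention_fraction",
    "iq_category",
    "classify_mei",
    "mei_report",
    "score_cohort",
]


@dataclass
class RAVLTRecord:
    t1: Optional[float] = None
    t2: Optional[float] = None
    t3: Optional[float] = None
    t4: Optional[float] = None
    t5: Optional[float] = None
    listb: Optional[float] = None
    t6: Optional[float] = None   # immediate recall
    t7: Optional[float] = None   # delayed recall
    hits: Optional[float] = None
    omissions: Optional[float] = None
    commissions: Optional[float] = None
    grid: Optional[np.ndarray] = None


@dataclass
class DigitSpanRecord:
    dsf: float
    dsb: float


@dataclass
class IQRecord:
    iq: int


def _ratio(num, den) -> float:
    if num is None or den is None or den == 0 or not math.isfinite(den):
        return float("nan")
    return num / den


def learning_capacity(r: RAVLTRecord) -> float:
    """Total words acquired over the five learning trials (NaN if any trial
    is missing)."""
    trials = (r.t1, r.t2, r.t3, r.t4, r.t5)
    if any(t is None for t in trials):
        return float("nan")
    return float(sum(trials))


def interference_and_retention(r: RAVLTRecord) -> dict:
    """PI, RI, forgetting speed and LTPR as ratio indices of the trial
    scores; zero denominators yield NaN markers."""
    ltpr = _ratio(r.t7, r.t5)
    return {
        "pi": _ratio(r.listb, r.t1),
        "ri": _ratio(r.t6, r.t5),
        "forgetting_speed": _ratio(r.t7, r.t6),
        "ltpr": 100.0 * ltpr if math.isfinite(ltpr) else float("nan"),
    }


def serial_position(grid: np.ndarray) -> dict:
    """Primacy / middle / recency scores (positions 1-5 / 6-10 / 11-15) for
    trial 1 and summed over all five trials of a binary 5 x 15 grid."""
    g = np.asarray(grid)
    if g.shape != (5, 15):
        raise ShapeError(f"recall grid must be 5 x 15, got {g.shape}")
    if not np.isin(g, (0, 1)).all():
        raise ShapeError("recall grid must be binary")
    bins = g.reshape(5, 3, 5).sum(axis=2)  # trial x (primacy, middle, recency)
    return {
        "primacy_t1": int(bins[0, 0]), "middle_t1": int(bins[0, 1]),
        "recency_t1": int(bins[0, 2]),
        "primacy_total": int(bins[:, 0].sum()),
        "middle_total": int(bins[:, 1].sum()),
        "recency_total": int(bins[:, 2].sum()),
    }


def attention_fraction(dsr: DigitSpanRecord, variant: str = "normalized") -> dict:
    """Attention fraction from forward/backward spans.

    Two candidate definitions are provided, neither privileged:
    "ratio_diff" = (DSF - DSB) / DSF and
    "normalized" = (DSF - DSB) / (DSF + DSB). The variant used is recorded
    in the output; DSF = 0 yields a NaN marker.
    """
    if variant == "ratio_diff":
        value = _ratio(dsr.dsf - dsr.dsb, dsr.dsf)
    elif variant == "normalized":
        value = _ratio(dsr.dsf - dsr.dsb, dsr.dsf + dsr.dsb)
    else:
        raise ValueError(f"unknown attention-fraction variant {variant!r}")
    if dsr.dsf == 0:
        value = float("nan")
    return {"value": value, "variant": variant}


def iq_category(iq) -> str:
    """ICD-10 style IQ banding: > 84 adequate; 70-84 borderline; 50-69 mild,
    35-49 moderate, < 35 severe/profound intellectual disability."""
    score = iq.iq if isinstance(iq, IQRecord) else iq
    if score > 84:
        return "adequate"
    if score >= 70:
        return "borderline"
    if score >= 50:
        return "mild ID"
    if score >= 35:
        return "moderate ID"
    return "severe/profound ID"


def classify_mei(value: float) -> str:
    """Band an MEI value against the published cut-offs (1.2, 1.9)."""
    lo, hi = MEI_CUTOFFS
    if not math.isfinite(value):
        return "undefined"
    if value < lo:
        return "below lower cut-off"
    if value < hi:
        return "between cut-offs"
    return "above upper cut-off"


def mei_report(records: Sequence[RAVLTRecord],
               mei_fn: Callable[[RAVLTRecord], float]) -> pd.DataFrame:
    """Apply a user-supplied MEI formula to records and attach the
    interpretive bands; no default formula is assumed."""
    values = [float(mei_fn(r)) for r in records]
    return pd.DataFrame({
        "mei": values,
        "band": [classify_mei(v) for v in values],
        "cutoff_low": MEI_CUTOFFS[0],
        "cutoff_high": MEI_CUTOFFS[1],
    })


def score_cohort(frame: pd.DataFrame, attention_variant: str = "normalized"
                 ) -> pd.DataFrame:
    """Batch-score a cohort table into the derived indices.

    Expects columns ravlt_t1..t7, ravlt_listb, dsf, dsb and optionally iq;
    emits one row per subject with NaN for any undefined index.
    """
    out = []
    for _, row in frame.iterrows():
        rec = RAVLTRecord(
            t1=row.get("ravlt_t1"), t2=row.get("ravlt_t2"), t3=row.get("ravlt_t3"),
            t4=row.get("ravlt_t4"), t5=row.get("ravlt_t5"),
            listb=row.get("ravlt_listb"), t6=row.get("ravlt_t6"),
            t7=row.get("ravlt_t7"))
        indices = {"learning_capacity": learning_capacity(rec)}
        indices.update(interference_and_retention(rec))
        att = attention_fraction(
            DigitSpanRecord(dsf=row.get("dsf", float("nan")),
                            dsb=row.get("dsb", float("nan"))),
            variant=attention_variant)
        indices["attention_fraction"] = att["value"]
        indices["attention_variant"] = att["variant"]
        if "iq" in row and pd.notna(row["iq"]):
            indices["iq_category"] = iq_category(int(round(row["iq"])))
        for key in ("subject_id", "group"):
            if key in row:
                indices[key] = row[key]
        out.append(indices)
    result = pd.DataFrame(out)
    lead = [c for c in ("subject_id", "group") if c in result.columns]
    return result[lead + [c for c in result.columns if c not in lead]]
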