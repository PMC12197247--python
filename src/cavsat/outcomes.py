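"""The six outcome metrics and the zero-improvement exclusion rule.

Metrics, per admission:

- IPR  — improvement rate, ``(day1 − discharge) / day1 × 100`` (percent);
- DIR  — daily improvement rate, ``IPR / LOS`` (percent per day);
- CER  — cost-effectiveness ratio, ``cost / (day1 − discharge)`` (CNY per
  score point);
- DIC  — daily improvement cost, ``cost / DIR`` (CNY);
- CLE  — cost–LOS efficiency, ``CER / LOS`` (CNY per day);
- LOS  — length of stay (days).

A record with an exactly zero symptom-score difference has undefined CER and
DIC and is excluded from analysis rather than rejected; worsening (discharge
above day 1) is retained with negative IPR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OUTCOME_METRICS: tuple[str, ...] = ("ipr", "dir", "cer", "dic", "cle", "los")


class OutcomeValidationError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeVector:
    ipr: float
    dir: float
    cer: float
    dic: float
    cle: float
    los: float


@dataclass(frozen=True)
class Exclusion:
    id: str
    reason: str


def compute_outcomes(
    score_day1: float, score_discharge: float, los: float, cost: float, record_id: str = "?"
) -> OutcomeVector | None:
    """Compute the six metrics for one record.

    Returns ``None`` as the exclusion signal when the score difference is
    exactly zero.  Raises :class:`OutcomeValidationError` for a nonpositive
    day-1 score or length of stay.
    """
    if score_day1 <= 0:
        raise OutcomeValidationError(f"record {record_id}: score_day1 must be > 0, got {score_day1}")
    if los <= 0:
        raise OutcomeValidationError(f"record {record_id}: los must be > 0, got {los}")
    diff = score_day1 - score_discharge
    if diff == 0:
        return None
    ipr = diff / score_day1 * 100.0
    dir_ = ipr / los
    cer = cost / diff
    dic = cost / dir_
    cle = cer / los
    return OutcomeVector(ipr=ipr, dir=dir_, cer=cer, dic=dic, cle=cle, los=los)


def outcome_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized outcome computation; assumes exclusions already applied."""
    diff = df["score_day1"] - df["score_discharge"]
    if (diff == 0).any():
        bad = df.loc[diff == 0, "id"].tolist()
        raise OutcomeValidationError(f"zero score difference (apply exclusions first): {bad}")
    if (df["score_day1"] <= 0).any() or (df["los_days"] <= 0).any():
        raise OutcomeValidationError("score_day1 and los_days must be positive")
    out = pd.DataFrame(index=df.index)
    out["ipr"] = diff / df["score_day1"] * 100.0
    out["dir"] = out["ipr"] / df["los_days"]
    out["cer"] = df["cost_cny"] / diff
    out["dic"] = df["cost_cny"] / out["dir"]
    out["cle"] = out["cer"] / df["los_days"]
    out["los"] = df["los_days"].astype(float)
    return out


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, list[Exclusion]]:
    """Drop records whose metrics are undefined; log each dropped id.

    Only the exact zero score difference triggers exclusion (the division
    that defines CER/DIC is then impossible); negative improvement is kept.
    """
    if len(df) == 0:
        raise OutcomeValidationError("empty cohort")
    log: list[Exclusion] = []
    keep = np.ones(len(df), dtype=bool)
    diff = (df["score_day1"] - df["score_discharge"]).to_numpy()
    ids = df["id"].to_numpy()
    for i, (d, rid) in enumerate(zip(diff, ids)):
        if d == 0:
            keep[i] = False
            log.append(Exclusion(id=str(rid), reason="zero symptom score difference"))
    survivors = df.loc[keep].copy()
    if len(survivors) == 0:
        raise OutcomeValidationError("no records survive exclusion")
    return survivors, log


def attach_outcomes(df: pd.DataFrame) -> tuple[pd.DataFrame, list[Exclusion]]:
    """Apply exclusions then append the six metric columns."""
    kept, log = apply_exclusions(df)
    metrics = outcome_table(kept)
    return pd.concat([kept, metrics], axis=1), log
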