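"""Goodness of fit and the percent-perfectly-predicted evaluation.

Three pseudo-R-squared measures compare the fitted log likelihood lnL with
the null log likelihood lnL0 of the zero-parameter equal-share model:

* McFadden LRI        1 - lnL/lnL0                 (0.2-0.4: excellent fit)
* Aldrich-Nelson      2(lnL-lnL0) / (2(lnL-lnL0) + N)   (>= 0.6: excellent)
* Estrella            1 - (lnL/lnL0)^(-(2/N) lnL0)

Predictive capacity is summarized by the share of occasions where the
highest-probability region equals the observed region, tabulated by
evaluation period, DML status and vessel size class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


def mcfadden_lri(lnL: float, lnL0: float) -> float:
    """McFadden's likelihood ratio index, 1 - lnL/lnL0."""
    if lnL0 == 0:
        raise ValueError("null log likelihood must be negative, got 0")
    return 1.0 - lnL / lnL0


def aldrich_nelson(lnL: float, lnL0: float, N: int) -> float:
    """Aldrich-Nelson index, 2*LR / (2*LR + N) with LR = lnL - lnL0."""
    if N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    lr2 = 2.0 * (lnL - lnL0)
    return lr2 / (lr2 + N)


def estrella(lnL: float, lnL0: float, N: int) -> float:
    """Estrella's measure, 1 - (lnL/lnL0)^(-(2/N) lnL0)."""
    if lnL0 >= 0:
        raise ValueError(f"null log likelihood must be negative, got {lnL0}")
    if N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    ratio = lnL / lnL0
    return 1.0 - ratio ** (-(2.0 / N) * lnL0)


@dataclass(frozen=True)
class PredictionRecord:
    """One evaluated occasion: probabilities, prediction, observation."""

    occasion_id: str
    vessel_id: str
    stage: str
    date: pd.Timestamp
    probabilities: np.ndarray
    observed: int  # region id

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"occasion {self.occasion_id}: probabilities sum to {p.sum()!r}"
            )

    @property
    def predicted(self) -> int:
        """Highest-probability region; ties break to the lowest region id."""
        return int(np.argmax(self.probabilities)) + 1

    @property
    def hit(self) -> bool:
        return self.predicted == self.observed


def prediction_records(results, occasions=None) -> list[PredictionRecord]:
    """Evaluate fitted results into prediction records.

    ``results`` is a ConditionalLogitResults; ``occasions`` defaults to the
    occasions the model was fitted on (within-sample evaluation).
    """
    occs = list(occasions) if occasions is not None else results.model.occasions
    probs = results.predict(occs if occasions is not None else None)
    return [
        PredictionRecord(
            occasion_id=o.occasion_id,
            vessel_id=o.vessel_id,
            stage=o.stage,
            date=o.date,
            probabilities=probs[i],
            observed=o.chosen,
        )
        for i, o in enumerate(occs)
    ]


def percent_perfect(
    records: Optional[Iterable[PredictionRecord]] = None,
    counts: Optional[tuple[int, int]] = None,
) -> tuple[int, int, int]:
    """(A, B, percent): observed count, perfect-fit count, rounded share.

    ``percent`` is 100*B/A rounded to the nearest integer.  Pass either a
    sequence of prediction records or a pre-tabulated ``counts=(A, B)``
    pair.
    """
    if counts is not None:
        A, B = int(counts[0]), int(counts[1])
    else:
        if records is None:
            raise ValueError("need records or counts")
        recs = list(records)
        A = len(recs)
        B = sum(1 for r in recs if r.hit)
    if A < 1:
        raise ValueError("need at least one observed choice")
    if not 0 <= B <= A:
        raise ValueError(f"perfect-fit count {B} outside [0, {A}]")
    return A, B, int(round(100.0 * B / A))


def prediction_table(
    records: Sequence[PredictionRecord],
    registry: pd.DataFrame,
    periods: Mapping[str, tuple] = None,
) -> pd.DataFrame:
    """Percent-perfect table by (period, DML, vessel size) plus totals.

    ``periods`` maps a period label to an inclusive (start, end) date pair;
    by default all records fall in a single period labeled "all".  Totals
    rows (vessel_size = "Total") sum their component rows exactly.
    """
    from .choice import size_class

    reg = registry.copy()
    reg["vessel_id"] = reg["vessel_id"].astype(str)
    reg = reg.set_index("vessel_id")
    rows = []
    for rec in records:
        if rec.vessel_id not in reg.index:
            raise KeyError(f"vessel {rec.vessel_id} not in registry")
        v = reg.loc[rec.vessel_id]
        label = None
        if periods is None:
            label = "all"
        else:
            for name, (start, end) in periods.items():
                if pd.Timestamp(start) <= rec.date <= pd.Timestamp(end):
                    label = name
                    break
            if label is None:
                raise KeyError(f"record {rec.occasion_id} date {rec.date} in no period")
        rows.append(
            {
                "period": label,
                "dml": int(v["dml"]),
                "vessel_size": size_class(v["capacity_t"]),
                "observed": 1,
                "perfect_fit": int(rec.hit),
            }
        )
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["period", "dml", "vessel_size"], sort=True)[["observed", "perfect_fit"]]
        .sum()
        .reset_index()
    )
    out_rows = []
    for period, sub in grouped.groupby("period", sort=True):
        for _, row in sub.iterrows():
            A, B, pct = percent_perfect(counts=(row["observed"], row["perfect_fit"]))
            out_rows.append(
                [period, row["dml"], row["vessel_size"], A, B, pct]
            )
        A, B, pct = percent_perfect(
            counts=(sub["observed"].sum(), sub["perfect_fit"].sum())
        )
        out_rows.append([period, "", "Total", A, B, pct])
    return pd.DataFrame(
        out_rows,
        columns=["period", "dml", "vessel_size", "observed", "perfect_fit", "percent"],
    )
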