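"""Motor-task performance and imaging-behaviour correlations.

Performance on the single-pellet reaching task is the success rate
(% of reach attempts ending in retrieval), normalized to training day 1.
Two correlation analyses link it to imaging:

* **Paired regression** — each imaging session is paired with the closest
  previous training day (2h and 18h -> day 1, 42h -> day 2, D6 -> day 5;
  D10 has no subsequent training day and is excluded). OLS lines are fit
  per mouse and on the across-mouse averages per timepoint.
* **Spearman matrix** — rank correlation across mice between the sGluA2
  change (or spine formation) at each of the five post-baseline imaging
  sessions and performance on each of the five training days, with
  unadjusted two-sided p-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import linregress, spearmanr

logger = logging.getLogger("spinedyn")

#: Imaging timepoint -> closest previous training day.
DEFAULT_PAIRING: dict[str, int] = {"2h": 1, "18h": 1, "42h": 2, "D6": 5}
IMAGING_TPS = ("2h", "18h", "42h", "D6", "D10")
TRAINING_DAYS = (1, 2, 3, 4, 5)


def success_rate(records: pd.DataFrame) -> pd.DataFrame:
    """Add success_rate (%) and day-1-normalized rate columns per mouse.

    ``records`` columns: mouse, day, attempts, successes. A mouse whose
    day-1 rate is zero cannot be normalized and is flagged.
    """
    df = records.copy()
    if (df["attempts"] <= 0).any():
        raise ValueError("attempts must be positive on every day")
    if ((df["successes"] < 0) | (df["successes"] > df["attempts"])).any():
        raise ValueError("successes must lie in [0, attempts]")
    df["success_rate"] = 100.0 * df["successes"] / df["attempts"]
    df["normalized_rate"] = np.nan
    df["flagged"] = False
    for mouse, grp in df.groupby("mouse"):
        day1 = grp[grp["day"] == 1]
        if len(day1) != 1 or day1["success_rate"].iloc[0] == 0:
            logger.warning("mouse %s: day-1 rate missing or zero; "
                           "normalization undefined", mouse)
            df.loc[grp.index, "flagged"] = True
            continue
        base = day1["success_rate"].iloc[0]
        df.loc[grp.index, "normalized_rate"] = grp["success_rate"] / base
    return df


def _ols(x: np.ndarray, y: np.ndarray) -> dict:
    res = linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2), "p_value": float(res.pvalue),
            "n": int(len(x))}


def paired_regression(imaging: pd.DataFrame, performance: pd.DataFrame,
                      pairing: dict[str, int] | None = None,
                      value_col: str = "value",
                      perf_col: str = "normalized_rate") -> pd.DataFrame:
    """Per-mouse and group-average OLS of imaging change vs performance.

    ``imaging`` columns: mouse, timepoint, ``value_col`` (e.g. the mouse's
    geometric-mean sGluA2 fold change at that session). Regressions with
    fewer than 3 paired points are skipped and flagged.
    """
    pairing = dict(DEFAULT_PAIRING if pairing is None else pairing)
    perf = performance.set_index(["mouse", "day"])[perf_col]
    rows = []
    pts = []
    for (mouse,), grp in imaging.groupby(["mouse"]):
        xs, ys = [], []
        for row in grp.itertuples(index=False):
            if row.timepoint not in pairing:
                continue
            key = (mouse, pairing[row.timepoint])
            if key not in perf.index or pd.isna(perf.loc[key]):
                continue
            xs.append(float(perf.loc[key]))
            ys.append(float(getattr(row, value_col)))
            pts.append({"mouse": mouse, "timepoint": row.timepoint,
                        "x": xs[-1], "y": ys[-1]})
        if len(xs) < 3 or len(set(xs)) < 2:
            logger.warning("mouse %s: %d paired points (distinct x: %d); "
                           "regression skipped", mouse, len(xs),
                           len(set(xs)))
            rows.append({"unit": mouse, "kind": "mouse", "slope": np.nan,
                         "intercept": np.nan, "r_squared": np.nan,
                         "p_value": np.nan, "n": len(xs), "flagged": True})
            continue
        rows.append({"unit": mouse, "kind": "mouse", **_ols(np.array(xs),
                                                            np.array(ys)),
                     "flagged": False})
    # group regression on the across-mouse averages per timepoint
    ptdf = pd.DataFrame(pts)
    if len(ptdf):
        avg = ptdf.groupby("timepoint")[["x", "y"]].mean()
        if len(avg) >= 3:
            rows.append({"unit": "group_average", "kind": "group",
                         **_ols(avg["x"].to_numpy(), avg["y"].to_numpy()),
                         "flagged": False})
        else:
            rows.append({"unit": "group_average", "kind": "group",
                         "slope": np.nan, "intercept": np.nan,
                         "r_squared": np.nan, "p_value": np.nan,
                         "n": len(avg), "flagged": True})
    return pd.DataFrame(rows)


def spearman_matrix(imaging: pd.DataFrame, performance: pd.DataFrame,
                    value_col: str = "value",
                    perf_col: str = "normalized_rate",
                    min_mice: int = 4) -> pd.DataFrame:
    """Imaging-timepoint x training-day Spearman correlation matrix.

    One cell per (imaging timepoint, training day): Spearman rho across
    mice between the imaging quantity and that day's performance, with a
    two-sided p. Cells with constant input or fewer than ``min_mice``
    complete mice are flagged (rho = NaN).
    """
    img = imaging.pivot_table(index="mouse", columns="timepoint",
                              values=value_col, aggfunc="first")
    perf = performance.pivot_table(index="mouse", columns="day",
                                   values=perf_col, aggfunc="first")
    rows = []
    for tp in IMAGING_TPS:
        for day in TRAINING_DAYS:
            rec = {"timepoint": tp, "day": day, "rho": np.nan,
                   "p_value": np.nan, "n": 0, "flagged": True}
            if tp in img.columns and day in perf.columns:
                both = pd.concat([img[tp], perf[day]], axis=1).dropna()
                rec["n"] = len(both)
                x, y = both.iloc[:, 0].to_numpy(), both.iloc[:, 1].to_numpy()
                if len(both) >= min_mice and len(set(x)) > 1 and len(set(y)) > 1:
                    rho, p = spearmanr(x, y)
                    rec.update({"rho": float(rho), "p_value": float(p),
                                "flagged": False})
                else:
                    logger.warning("Spearman cell (%s, day %d) flagged "
                                   "(n=%d or constant input)", tp, day,
                                   rec["n"])
            rows.append(rec)
    return pd.DataFrame(rows)
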