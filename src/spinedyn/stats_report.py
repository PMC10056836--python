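"""Hierarchical aggregation, permutation tests, and report assembly.

Observations sit in a strict nesting: spine within dendrite within mouse
within condition (genotype x hemisphere). Summaries respect that tree with
equal weight per child at every level, and group comparisons permute
labels at the mouse level — the exchangeable unit — rather than pooling
spines. This stands in for nested random-effects mixed models: the
per-level aggregation mirrors the nesting, and the permutation test gives
an exact-level test of the group difference on mouse summaries.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("spinedyn")


def _agg(values: np.ndarray, statistic: str) -> float:
    if statistic == "mean":
        return float(np.mean(values))
    if statistic in ("gmean", "geometric mean"):
        if np.any(values <= 0):
            raise ValueError("geometric mean requires positive values")
        return float(np.exp(np.mean(np.log(values))))
    raise ValueError(f"unknown statistic {statistic!r}")


def hierarchical_aggregate(observations: pd.DataFrame,
                           value_col: str = "value",
                           statistic: str = "mean",
                           levels: tuple[str, ...] = ("dendrite", "mouse", "group"),
                           within: tuple[str, ...] = (),
                           ) -> dict[str, pd.DataFrame]:
    """Bottom-up equal-weight aggregation along the nesting tree.

    Each level's value is the chosen statistic over its children's values
    (not over pooled leaves), so unbalanced trees do not overweight
    spine-rich dendrites. ``within`` columns (e.g. timepoint) are carried
    through every level. Returns per-level tables with value, n (children)
    and SEM across children.
    """
    if len(observations) == 0:
        raise ValueError("empty observation tree")
    out: dict[str, pd.DataFrame] = {}
    current = observations
    wcols = list(within)
    for i, level in enumerate(levels):
        keys = list(levels[i:]) + wcols
        rows = []
        for key, grp in current.groupby(keys, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            vals = grp[value_col].to_numpy(dtype=float)
            rows.append({**dict(zip(keys, key)),
                         "value": _agg(vals, statistic),
                         "n": len(vals),
                         "sem": float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
                         if len(vals) > 1 else np.nan})
        out[level] = pd.DataFrame(rows)
        current = out[level][keys + ["value"]].rename(
            columns={"value": value_col})
    return out


def permutation_group_test(values, labels, n_perm: int = 10_000,
                           seed: int = 0, exact: bool | None = None) -> dict:
    """Two-sided permutation test for a difference in group means.

    ``values`` are one summary per mouse, ``labels`` the two group names.
    The statistic is |mean(A) - mean(B)|; labels are permuted across mice.
    When the number of distinct label assignments is small (<= n_perm) the
    full enumeration is used and the p-value is the exact proportion of
    assignments at least as extreme; otherwise Monte-Carlo sampling with
    the add-one estimator ``p = (b + 1) / (n_perm + 1)``. Degenerate
    (all-equal) data returns p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    n_a = int(np.sum(labels == uniq[0]))
    n = len(values)
    if n_a < 2 or n - n_a < 2:
        raise ValueError("need >= 2 mice per group")
    if np.all(values == values[0]):
        return {"p_value": 1.0, "observed": 0.0, "n_perm": 0, "exact": True}

    def stat(mask_a: np.ndarray) -> float:
        return abs(values[mask_a].mean() - values[~mask_a].mean())

    obs = stat(labels == uniq[0])
    n_comb = math.comb(n, n_a)
    use_exact = exact if exact is not None else n_comb <= n_perm
    if use_exact:
        count = 0
        for idx in itertools.combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            if stat(mask) >= obs - 1e-12:
                count += 1
        p = count / n_comb
        return {"p_value": float(p), "observed": float(obs),
                "n_perm": n_comb, "exact": True}
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_a]] = True
        if stat(mask) >= obs - 1e-12:
            b += 1
    return {"p_value": float((b + 1) / (n_perm + 1)), "observed": float(obs),
            "n_perm": n_perm, "exact": False}


# ---------------------------------------------------------------------------
# Report assembly

SECTIONS = (
    ("turnover", "Spine turnover (formation / elimination / density change)"),
    ("fold_change", "sGluA2 fold change (geometric mean +/- SEM)"),
    ("dynamics", "Up / Same / Down proportions"),
    ("percentile_groups", "Baseline-percentile group trajectories"),
    ("ks", "Late-session distribution comparison (Kolmogorov-Smirnov)"),
    ("paired_regression", "Performance vs sGluA2 paired regression"),
    ("spearman", "Imaging x training-day Spearman matrix"),
)


def _table_md(df: pd.DataFrame, max_rows: int = 40) -> str:
    shown = df.head(max_rows)
    body = shown.to_csv(index=False, float_format="%.6g").strip()
    lines = body.splitlines()
    md = ["| " + " | ".join(lines[0].split(",")) + " |",
          "|" + "---|" * len(lines[0].split(","))]
    md += ["| " + " | ".join(l.split(",")) + " |" for l in lines[1:]]
    if len(df) > max_rows:
        md.append(f"\n*({len(df) - max_rows} further rows omitted)*")
    return "\n".join(md)


def build_report(tables: dict[str, pd.DataFrame | dict], config,
                 manifest: dict | None = None,
                 out_path: str | Path | None = None) -> str:
    """Assemble the markdown analysis report.

    ``tables`` maps section keys (see SECTIONS) to DataFrames or plain
    dicts of headline numbers; missing sections are replaced by a notice.
    Byte-identical for identical inputs.
    """
    lines = ["# spinedyn analysis report", ""]
    lines.append("Configuration: `" + json.dumps(
        config.model_dump() if hasattr(config, "model_dump") else dict(config),
        sort_keys=True) + "`")
    lines.append("")
    for key, title in SECTIONS:
        lines.append(f"## {title}")
        lines.append("")
        if key not in tables or tables[key] is None:
            lines.append(f"*Section `{key}` omitted: no input table.*")
        elif isinstance(tables[key], pd.DataFrame):
            if len(tables[key]) == 0:
                lines.append(f"*Section `{key}` omitted: empty table.*")
            else:
                lines.append(_table_md(tables[key]))
        else:
            lines.append("```json")
            lines.append(json.dumps(tables[key], indent=1, sort_keys=True,
                                    default=float))
            lines.append("```")
        lines.append("")
    lines.append("## Provenance")
    lines.append("")
    if manifest:
        lines.append("```json")
        lines.append(json.dumps(manifest, indent=1, sort_keys=True,
                                default=str))
        lines.append("```")
    else:
        lines.append("*No generation manifest supplied.*")
    lines.append("")
    lines.append("*P-values are reported unadjusted; the Spearman matrix "
                 "involves 25 simultaneous cells per condition, so individual "
                 "cells should be read with multiple-testing caution.*")
    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).write_text(text, encoding="utf-8")
    return text
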