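#!/usr/bin/env python
"""Assemble the analysis report from the staged result tables.

Collects whatever the earlier drivers wrote under results/ and renders the
markdown report (missing tables become notices) plus a summary.json of
headline numbers. Deterministic: identical inputs give a byte-identical
report body.

Outputs: results/report.md, results/summary.json
"""

import json
import sys
from pathlib import Path

import pandas as pd

from spinedyn.io_core import resolve_config
from spinedyn.stats_report import build_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

TABLE_FILES = {
    "turnover": "turnover_imaging.csv",
    "fold_change": "fold_summary.csv",
    "dynamics": "dynamics_proportions.csv",
    "percentile_groups": "percentile_groups.csv",
    "ks": "ks_late.csv",
    "paired_regression": "paired_regression.csv",
    "spearman": "spearman.csv",
}


def main():
    RESULTS.mkdir(exist_ok=True)
    tables = {}
    for key, fname in TABLE_FILES.items():
        path = RESULTS / fname
        if path.exists():
            tables[key] = pd.read_csv(path)
    manifest = None
    if (RESULTS / "manifest.json").exists():
        manifest = json.loads((RESULTS / "manifest.json").read_text())
    config = resolve_config({})
    build_report(tables, config, manifest=manifest,
                 out_path=RESULTS / "report.md")

    summary = {}
    if "fold_change" in tables:
        t = tables["fold_change"]
        for row in t.itertuples(index=False):
            summary[f"geomean_fold_{row.group}_{row.timepoint}"] = round(
                float(row.value), 4)
    if "turnover" in tables:
        t = tables["turnover"]
        sel = t[(t.timepoint == "18h") & ~t.flagged]
        for group, grp in sel.groupby("group"):
            summary[f"density_change_18h_{group}_pct"] = round(
                float(grp.total_spines_pct_change.mean()), 2)
    if "ks" in tables:
        for row in tables["ks"].itertuples(index=False):
            summary[f"ks_{row.group_a}_vs_{row.group_b}"] = round(
                float(row.ks_statistic), 4)
    (RESULTS / "summary.json").write_text(json.dumps(summary, indent=1,
                                                     sort_keys=True))
    print(f"report written with {len(tables)} of {len(TABLE_FILES)} sections "
          f"-> {RESULTS / 'report.md'}")
    if summary:
        print(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    sys.exit(main())
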