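"""Aggregation of fold-level benchmark results into summary tables."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bench import CVResult

__all__ = ["fold_table", "summarize"]

_GROUP_COLS = ["task", "target", "feature_set", "deconfound", "algorithm",
               "fs_method", "hpo", "sample"]


def fold_table(results: list[CVResult]) -> pd.DataFrame:
    """Long table: one row per (config, outer fold)."""
    frames = []
    for res in results:
        f = res.folds.copy()
        for col in _GROUP_COLS:
            f[col] = getattr(res.config, col)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def summarize(folds: pd.DataFrame) -> pd.DataFrame:
    """Per-config mean +/- SD of each metric, the fraction of folds where
    the model strictly beats the dummy, and the >80% robustness flag.

    Every number here is recomputable from the fold table alone.
    """
    if folds.empty:
        raise ValueError("fold table is empty")
    key = "bac" if "bac" in folds.columns else "r2"
    rows = []
    for cfg_vals, grp in folds.groupby(_GROUP_COLS, dropna=False):
        if grp.empty:  # pragma: no cover - groupby drops empty groups
            warnings.warn("empty config group dropped")
            continue
        wins = float((grp[key] > grp[f"dummy_{key}"]).mean())
        row = dict(zip(_GROUP_COLS, cfg_vals))
        metric_cols = [
            c for c in grp.columns
            if c not in _GROUP_COLS + ["fold"] and np.issubdtype(grp[c].dtype, np.number)
        ]
        for c in metric_cols:
            row[f"mean_{c}"] = float(grp[c].mean())
            row[f"sd_{c}"] = float(grp[c].std(ddof=1))
        row["dummy_win_fraction"] = wins
        row["robust"] = wins > 0.8
        row["n_folds"] = len(grp)
        rows.append(row)
    return pd.DataFrame(rows)
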