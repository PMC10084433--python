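"""Study-table screening before statistical modeling.

Three checks secure the sessions x features table: rows with missing
feature values are removed; near-zero-variance columns are flagged (the
caret-style convention: frequency ratio of the two most common values
>= 95/5 AND unique-value fraction < 10%); and highly correlated column
pairs (|r| above a threshold, default .95) are de-duplicated by greedily
dropping, from the worst pair, the member with the larger mean absolute
correlation against the remaining columns.

Column order is canonicalized (sorted names) before the greedy pass so
the removal set is deterministic; residual ties fall to the
lexicographically later name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ScreeningReport:
    rows_removed: int = 0
    removed_row_ids: list = field(default_factory=list)
    nzv_columns: list = field(default_factory=list)
    correlated_pairs: list = field(default_factory=list)  # (a, b, r)
    columns_removed: list = field(default_factory=list)
    final_dims: tuple = (0, 0)

    def to_dict(self) -> dict:
        return {
            "rows_removed": self.rows_removed,
            "removed_row_ids": self.removed_row_ids,
            "nzv_columns": self.nzv_columns,
            "correlated_pairs": [(a, b, float(r))
                                 for a, b, r in self.correlated_pairs],
            "columns_removed": self.columns_removed,
            "final_dims": list(self.final_dims),
        }


def near_zero_variance(col: pd.Series, freq_ratio: float = 95 / 5,
                       unique_frac: float = 0.10) -> bool:
    """caret-style near-zero-variance check for one column."""
    v = col.dropna()
    if len(v) == 0 or v.nunique() <= 1:
        return True
    counts = v.value_counts().to_numpy()
    ratio = counts[0] / counts[1] if len(counts) > 1 else np.inf
    return bool(ratio >= freq_ratio and v.nunique() / len(v) < unique_frac)


def drop_correlated(table: pd.DataFrame, columns: list[str],
                    r_threshold: float = 0.95):
    """Greedy de-duplication of highly correlated columns.

    While some retained pair has |r| > threshold, take the pair with the
    largest |r| and drop the member whose mean absolute correlation with
    all other retained columns is larger. Returns (kept columns, removed
    columns, flagged pairs).
    """
    cols = sorted(columns)
    corr = table[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    active = list(range(len(cols)))
    removed: list[str] = []
    pairs: list[tuple] = []
    while True:
        sub = corr[np.ix_(active, active)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= r_threshold:
            break
        a, b = active[i], active[j]
        pairs.append((cols[a], cols[b], float(corr[a, b])))
        mean_a = corr[a, active].mean()
        mean_b = corr[b, active].mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:  # tie: drop the name-sorted-later column
            drop = max(a, b)
        removed.append(cols[drop])
        active.remove(drop)
    kept = [cols[k] for k in active]
    return kept, removed, pairs


def screen(table: pd.DataFrame, feature_cols: list[str] | None = None,
           r_threshold: float = 0.95, drop_nzv: bool = False,
           id_cols: tuple = ("participant", "article", "block")):
    """Screen the study table; returns (screened table, ScreeningReport).

    Rows with any missing feature value are dropped; near-zero-variance
    columns are flagged (and only dropped when ``drop_nzv``); correlated
    columns above ``r_threshold`` are de-duplicated. Non-feature columns
    (ids, appraisal scores) pass through untouched.
    """
    if len(table) < 2:
        raise ValueError("screening needs at least 2 rows")
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in id_cols
                        and c not in ("comprehensibility", "interest")
                        and pd.api.types.is_numeric_dtype(table[c])]
    missing = table[feature_cols].isna().any(axis=1)
    if missing.all():
        raise ValueError("every row has missing feature values")
    report = ScreeningReport()
    report.rows_removed = int(missing.sum())
    report.removed_row_ids = [
        tuple(r) for r in table.loc[missing, list(id_cols[:2])]
        .itertuples(index=False)] if set(id_cols[:2]) <= set(table.columns) \
        else table.index[missing].tolist()
    out = table[~missing].copy()

    report.nzv_columns = [c for c in sorted(feature_cols)
                          if near_zero_variance(out[c])]
    cols = list(feature_cols)
    if drop_nzv:
        cols = [c for c in cols if c not in report.nzv_columns]
        out = out.drop(columns=report.nzv_columns)

    kept, removed, pairs = drop_correlated(out, cols, r_threshold)
    report.correlated_pairs = pairs
    report.columns_removed = removed
    out = out.drop(columns=removed)
    # canonical order: ids, features sorted, then appraisals
    tail = [c for c in out.columns if c in ("comprehensibility", "interest")]
    head = [c for c in out.columns if c in id_cols]
    out = out[head + sorted(kept) + tail]
    report.final_dims = (len(out), len(kept))
    return out.reset_index(drop=True), report
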