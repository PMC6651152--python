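"""Readers, writers and result summaries.

Tab-delimited text is the canonical interchange format: feature tables are
TSVs with ``subject``, ``trial``, ``valence``, ``arousal`` metadata columns
followed by the feature columns; records tables hold one row per
(test subject, repetition, classifier, method) accuracy.  Every table the
package writes is re-parseable by its own readers.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ComparisonRecord
from .features import FeatureTable
from .stats import friedman_from_records

__all__ = [
    "META_COLUMNS",
    "read_feature_table",
    "write_feature_table",
    "records_to_dataframe",
    "dataframe_to_records",
    "write_records",
    "read_records",
    "summarize_accuracy",
    "summarize_ranks",
    "write_manifest",
]

META_COLUMNS = ("subject", "trial", "valence", "arousal")


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as TSV (metadata columns, then features)."""
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, "arousal", table.arousal)
    df.insert(0, "valence", table.valence)
    df.insert(0, "trial", table.trial_ids)
    df.insert(0, "subject", table.subject_ids)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> FeatureTable:
    """Parse a TSV feature table, validating schema and cell types.

    Label cells may be 0, 1 or empty (absent); non-numeric feature cells
    and out-of-range labels are rejected with the offending row number
    (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    feat_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not feat_cols:
        raise ValueError(f"{path}: no feature columns found")

    def parse_labels(col: str) -> np.ndarray:
        out = np.empty(len(df))
        for i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
                out[i] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: row {i + 1}: {col} label {cell!r} is not numeric"
                ) from None
            if v not in (0.0, 1.0):
                raise ValueError(
                    f"{path}: row {i + 1}: {col} label must be 0 or 1, got {cell!r}"
                )
            out[i] = v
        return out

    values = np.empty((len(df), len(feat_cols)))
    for j, col in enumerate(feat_cols):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {i + 1}: feature {col!r} cell {cell!r} is not numeric"
                ) from None

    return FeatureTable(
        values=values,
        feature_names=feat_cols,
        subject_ids=df["subject"].to_numpy(dtype=object),
        trial_ids=df["trial"].to_numpy(dtype=object),
        valence=parse_labels("valence"),
        arousal=parse_labels("arousal"),
    )


def records_to_dataframe(records: list[ComparisonRecord]) -> pd.DataFrame:
    """One row per (record, method), in long format."""
    rows = []
    for rec in records:
        for method, acc in rec.accuracies.items():
            rows.append(
                {
                    "dataset": rec.dataset,
                    "label_dim": rec.label_dim,
                    "classifier": rec.classifier,
                    "test_subject": rec.test_subject,
                    "repetition": rec.repetition,
                    "method": method,
                    "accuracy": acc,
                }
            )
    return pd.DataFrame(rows)


def dataframe_to_records(df: pd.DataFrame) -> list[ComparisonRecord]:
    keys = ["dataset", "label_dim", "classifier", "test_subject", "repetition"]
    records = []
    for key_vals, group in df.groupby(keys, sort=False):
        dataset, label_dim, classifier, subj, rep = key_vals
        records.append(
            ComparisonRecord(
                test_subject=subj,
                repetition=int(rep),
                classifier=classifier,
                label_dim=label_dim,
                accuracies=dict(zip(group["method"], group["accuracy"].astype(float))),
                dataset="" if pd.isna(dataset) else str(dataset),
            )
        )
    return records


def write_records(records: list[ComparisonRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, sep="\t", index=False)


def read_records(path) -> list[ComparisonRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"dataset": str})
    return dataframe_to_records(df)


def summarize_accuracy(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Mean accuracy per (dataset, label dimension, classifier, method)."""
    df = records_to_dataframe(records)
    return (
        df.groupby(["dataset", "label_dim", "classifier", "method"], sort=False)["accuracy"]
        .mean()
        .reset_index()
        .rename(columns={"accuracy": "mean_accuracy"})
    )


def summarize_ranks(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Friedman rank summary per (dataset, label dimension, classifier) cell.

    One output row per method, carrying the cell's number of pairwise
    comparisons, the method's average rank and the cell's p-value.
    """
    rows = []
    cells: dict[tuple, list[ComparisonRecord]] = {}
    for rec in records:
        cells.setdefault((rec.dataset, rec.label_dim, rec.classifier), []).append(rec)
    for (dataset, label_dim, classifier), cell_records in cells.items():
        summary = friedman_from_records(cell_records)
        for name, rank in zip(summary.method_names, summary.avg_ranks):
            rows.append(
                {
                    "dataset": dataset,
                    "label_dim": label_dim,
                    "classifier": classifier,
                    "method": name,
                    "n_comparisons": summary.n_comparisons,
                    "avg_rank": float(rank),
                    "p_value": summary.p_value,
                }
            )
    return pd.DataFrame(rows)


def write_manifest(path, command: str, config: dict, seed, counts: dict) -> None:
    """Write a run manifest: config snapshot, seed, version, stage counts.

    Outputs are fully determined by the command, config and seed, so
    re-running with the manifest's values reproduces them bit-identically;
    the timestamp records provenance only.
    """
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "counts": counts,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
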