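"""Class-balancing strategies for the labeled feature table.

The labeled classes (benign 0 / damaging 1 / ambiguous 3) are highly
imbalanced; SMOTE interpolates synthetic minority samples between nearest
same-class neighbours so every class reaches the majority count. Plain
over/down-sampling and balanced class weights are provided as alternatives.
Unknown-labeled rows (class 2) are never balanced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .trajfeatures import FEATURE_NAMES

BALANCEABLE_LABELS = (0, 1, 3)


def _check_table(table: pd.DataFrame, feature_cols: list[str]) -> None:
    if "label" not in table.columns:
        raise ValueError("table must have a 'label' column")
    bad = set(table["label"]) - set(BALANCEABLE_LABELS)
    if bad:
        raise ValueError(
            f"labels {sorted(bad)} are not balanceable; restrict to {BALANCEABLE_LABELS}"
        )
    if table[feature_cols].isna().any().any():
        raise ValueError("feature table contains missing values")


def _feature_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_NAMES if c in table.columns] or [
        c
        for c in table.columns
        if c not in ("label", "variant", "synthetic") and pd.api.types.is_numeric_dtype(table[c])
    ]


def smote_balance(
    table: pd.DataFrame,
    k_neighbors: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic minority oversampling to the majority class count.

    Each synthetic sample interpolates a random minority sample toward one of
    its k nearest same-class neighbours: ``x_i + u * (x_nn - x_i)`` with
    u ~ Uniform(0, 1). Originals are preserved; synthetic rows carry
    ``synthetic=True``. k is capped at class size - 1.
    """
    feature_cols = _feature_cols(table)
    _check_table(table, feature_cols)
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table["label"].value_counts()
    majority = int(counts.max())
    out = table.copy()
    out["synthetic"] = out.get("synthetic", False)
    new_rows = []
    for label in sorted(counts.index):
        n_c = int(counts[label])
        deficit = majority - n_c
        if deficit == 0:
            continue
        if n_c < 2:
            raise ValueError(
                f"class {label} has a single sample; SMOTE needs >= 2 "
                "(use resample(strategy='oversample') instead)"
            )
        x = table.loc[table["label"] == label, feature_cols].to_numpy(float)
        k = min(k_neighbors, n_c - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
        _, idx = nn.kneighbors(x)  # column 0 is the point itself
        for _ in range(deficit):
            i = int(rng.integers(n_c))
            j = int(idx[i, 1 + rng.integers(k)])
            u = rng.uniform()
            synth = x[i] + u * (x[j] - x[i])
            row = {c: v for c, v in zip(feature_cols, synth)}
            row["label"] = label
            row["synthetic"] = True
            if "variant" in table.columns:
                row["variant"] = f"synthetic_{label}_{len(new_rows)}"
            new_rows.append(row)
    if new_rows:
        out = pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)
    return out


def resample(
    table: pd.DataFrame,
    strategy: str = "oversample",
    seed: int | None = None,
) -> pd.DataFrame:
    """Duplicate minorities up to the majority count, or subsample the
    majority down to the minority count (without replacement)."""
    feature_cols = _feature_cols(table)
    _check_table(table, feature_cols)
    rng = np.random.default_rng(seed)
    counts = table["label"].value_counts()
    parts = []
    if strategy == "oversample":
        target = int(counts.max())
        for label in sorted(counts.index):
            block = table[table["label"] == label]
            parts.append(block.assign(synthetic=False))
            deficit = target - len(block)
            if deficit > 0:
                picks = rng.integers(len(block), size=deficit)
                parts.append(block.iloc[picks].assign(synthetic=True))
    elif strategy == "downsample":
        target = int(counts.min())
        for label in sorted(counts.index):
            block = table[table["label"] == label]
            picks = rng.choice(len(block), size=target, replace=False)
            parts.append(block.iloc[np.sort(picks)].assign(synthetic=False))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return pd.concat(parts, ignore_index=True)


def class_weights(labels) -> dict[int, float]:
    """Balanced-heuristic weights: n_total / (n_classes * n_c)."""
    labels = pd.Series(labels)
    if len(labels) == 0:
        raise ValueError("empty label vector")
    counts = labels.value_counts()
    total = len(labels)
    k = len(counts)
    return {int(c): total / (k * int(n)) for c, n in counts.items()}
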