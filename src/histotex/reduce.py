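"""Pearson-correlation redundancy filter over feature columns.

Highly correlated texture features carry duplicated information; a greedy
keep-first scan drops any column whose absolute Pearson correlation with an
already-kept column reaches the threshold (the study's working points are
0.97 and 0.99).  Zero-variance columns are dropped first since r is undefined
for them.  The fitted model is column-name based, so it can be applied to any
table sharing the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTable


@dataclass
class CorrelationFilterModel:
    threshold: float
    kept_features: list[str]
    dropped_features: list[tuple[str, str | None]] = field(default_factory=list)
    """(dropped column, the kept partner that triggered the drop; None for
    zero-variance columns)."""


def fit_correlation_filter(table: FeatureTable, threshold: float,
                           ) -> CorrelationFilterModel:
    """Greedy keep-first scan in column order at the given |r| threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if len(table) < 2:
        raise ValueError("need at least two samples to estimate correlations")
    names = table.feature_names
    x = table.matrix.astype(np.float64)
    n = x.shape[0]
    std = x.std(axis=0)
    nonzero = std > 0
    kept: list[str] = []
    dropped: list[tuple[str, str | None]] = []
    z = np.zeros_like(x)
    z[:, nonzero] = (x[:, nonzero] - x[:, nonzero].mean(axis=0)) / std[nonzero]
    kept_idx: list[int] = []
    kept_z = np.empty((n, x.shape[1]))  # filled left-to-right as columns are kept
    for j, name in enumerate(names):
        if not nonzero[j]:
            dropped.append((name, None))
            continue
        k = len(kept_idx)
        if k:
            r = z[:, j] @ kept_z[:, :k] / n
            hit = np.flatnonzero(np.abs(r) >= threshold - 1e-12)
            if hit.size:
                dropped.append((name, names[kept_idx[hit[0]]]))
                continue
        kept_z[:, k] = z[:, j]
        kept_idx.append(j)
        kept.append(name)
    return CorrelationFilterModel(threshold, kept, dropped)


def apply_filter(table: FeatureTable, model: CorrelationFilterModel) -> FeatureTable:
    """Project a table onto the model's kept columns (labels preserved)."""
    return table.select(model.kept_features)
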