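"""Multi-condition expression statistics: tissue specificity index,
tissue-enrichment filters, per-class hierarchical clustering and the
differential-expression rule for cell-fate comparisons.

The tissue specificity index (TSI, the "tau" family of scores) of sRNA j
over N tissues with expression x_{j,i} is

    TSI_j = (N - sum_i x_{j,i} / max_i x_{j,i}) / (N - 1)

ranging from 0 (uniform expression) to 1 (expressed in a single tissue).
It is invariant to row scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import ttest_ind

DEFAULT_TSI_THRESHOLD = 0.95
# Per-class minimum RPM (in at least one tissue) for the enrichment filter.
DEFAULT_CLASS_RPM_MIN = {
    "mito_tRNA": 70.0,
    "lncRNA": 50.0,
    "snRNA": 50.0,
    "snoRNA": 30.0,
}
DEFAULT_RPM_MIN = 20.0


def compute_tsi(x: np.ndarray | Sequence[float]) -> float:
    """TSI of one expression row (requires >= 2 tissues, not all zero)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("TSI requires at least two tissues")
    if np.any(x < 0):
        raise ValueError("expression must be nonnegative")
    m = x.max()
    if m <= 0:
        raise ValueError("all-zero expression row")
    return float((n - x.sum() / m) / (n - 1))


def tsi_table(rpm: pd.DataFrame) -> pd.DataFrame:
    """TSI, max tissue and max RPM for every row of a tissue RPM matrix.

    All-zero rows get TSI = NaN rather than raising.
    """
    x = rpm.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 2:
        raise ValueError("TSI requires at least two tissues")
    m = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tsi = np.where(m > 0, (n - x.sum(axis=1) / np.where(m > 0, m, 1)) / (n - 1), np.nan)
    return pd.DataFrame(
        {
            "tsi": tsi,
            "max_tissue": rpm.columns[np.argmax(x, axis=1)],
            "max_rpm": m,
        },
        index=rpm.index,
    )


def filter_and_enrich(
    rpm: pd.DataFrame,
    classes: pd.Series,
    tsi_threshold: float = DEFAULT_TSI_THRESHOLD,
    class_rpm_min: Optional[Mapping[str, float]] = None,
    default_rpm_min: float = DEFAULT_RPM_MIN,
) -> pd.DataFrame:
    """Tissue-enriched sRNAs: TSI above threshold and a class-specific RPM
    floor reached in at least one tissue.

    Unknown classes fall back to the default floor.  Returns the passing
    rows with their class, TSI, max tissue and max RPM.
    """
    thresholds = dict(DEFAULT_CLASS_RPM_MIN)
    if class_rpm_min is not None:
        thresholds.update(class_rpm_min)
    t = tsi_table(rpm)
    floors = classes.map(lambda c: thresholds.get(c, default_rpm_min)).reindex(rpm.index)
    mask = (t["tsi"] > tsi_threshold) & (t["max_rpm"] > floors)
    out = t[mask.fillna(False)].copy()
    out.insert(0, "class", classes.reindex(out.index))
    return out


@dataclass
class ClassClustering:
    """Average-linkage tree over one class's rows (scipy linkage matrix)."""

    ref_class: str
    row_order: list[str]
    linkage_matrix: Optional[np.ndarray]  # None for trivial (<2 row) trees


def cluster_by_class(
    rpm: pd.DataFrame,
    classes: pd.Series,
    prefilter_rpm: float = DEFAULT_RPM_MIN,
    log_offset: float = 1.0,
) -> dict[str, ClassClustering]:
    """Per-class average-linkage clustering on log2-transformed expression.

    Rows are prefiltered to those exceeding ``prefilter_rpm`` in at least one
    tissue, split by class, log2(x + offset)-transformed, and clustered with
    Euclidean distances and average linkage.  Deterministic: rows enter the
    distance computation in sorted sequence order, so permuting the input
    yields the same tree.
    """
    keep = rpm.max(axis=1) > prefilter_rpm
    rpm = rpm[keep]
    out: dict[str, ClassClustering] = {}
    for cls in sorted(classes.reindex(rpm.index).dropna().unique()):
        rows = rpm[classes.reindex(rpm.index) == cls].sort_index()
        if len(rows) < 2:
            out[cls] = ClassClustering(cls, list(rows.index), None)
            continue
        values = np.log2(rows.to_numpy(dtype=float) + log_offset)
        z = linkage(values, method="average", metric="euclidean")
        out[cls] = ClassClustering(cls, list(rows.index), z)
    return out


@dataclass(frozen=True)
class DifferentialHit:
    sequence: str
    p_value: float
    fold_change: float
    direction: str  # "A>B" or "B>A"


def differential_species(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    p_max: float = 0.05,
    fc_min: float = 2.0,
) -> list[DifferentialHit]:
    """Two-group differential expression on replicate RPM matrices.

    Welch's two-sided t-test on log2(RPM + 1) per sequence; selected iff
    P < p_max and the ratio of linear group means exceeds fc_min (in either
    direction, recorded).  Requires >= 2 replicates per group.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("need at least two replicates per group")
    idx = group_a.index.union(group_b.index)
    a = group_a.reindex(idx).fillna(0.0).to_numpy(dtype=float)
    b = group_b.reindex(idx).fillna(0.0).to_numpy(dtype=float)
    la, lb = np.log2(a + 1), np.log2(b + 1)
    t, p = ttest_ind(la, lb, axis=1, equal_var=False)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    hits = []
    for i, seq in enumerate(idx):
        if not np.isfinite(p[i]) or p[i] >= p_max:
            continue
        hi, lo = (mean_a[i], mean_b[i]) if mean_a[i] >= mean_b[i] else (mean_b[i], mean_a[i])
        if lo <= 0:
            fc = np.inf if hi > 0 else 1.0
        else:
            fc = hi / lo
        if fc > fc_min:
            hits.append(
                DifferentialHit(
                    sequence=seq,
                    p_value=float(p[i]),
                    fold_change=float(fc),
                    direction="A>B" if mean_a[i] >= mean_b[i] else "B>A",
                )
            )
    return hits
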