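"""Normalization, detection calls, and level summarization.

Array signals are quantile normalized; sequencing counts get a pseudocount
and library-size scaling to counts-per-million (CPM).  Feature-level values
are summarized to gene/pattern level with a one-step Tukey biweight on the
log2 scale, the robust mean conventionally used for probe-set
summarization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import TitrationDesign
from .matrix import ExpressionMatrix

__all__ = [
    "quantile_normalize",
    "cpm_normalize",
    "detection_calls",
    "tukey_biweight",
    "summarize_to_level",
    "collapse_replicates",
]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the common mean-of-sorted-values distribution.

    Ties within a column receive the mean of the reference values over
    their rank span (the standard tie policy, which makes the transform
    idempotent).  Requires ``kind == "signal"`` and at least 2 columns with
    no missing values.
    """
    if matrix.kind != "signal":
        raise ValueError(f"quantile normalization expects signal data, got {matrix.kind}")
    df = matrix.data
    if df.shape[1] < 2:
        raise ValueError("need at least 2 columns to quantile normalize")
    if df.isna().any().any():
        raise ValueError("missing values are not allowed in quantile normalization")
    vals = df.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    reference = np.sort(vals, axis=0).mean(axis=1)

    out = np.empty_like(vals)
    ranks = np.empty_like(order)
    rows = np.arange(vals.shape[0])
    for j in range(vals.shape[1]):
        ranks[order[:, j], j] = rows
        col = reference[ranks[:, j]].astype(float)
        # average reference values across tied input values
        s = pd.Series(col).groupby(vals[:, j]).transform("mean").to_numpy()
        out[:, j] = s
    return matrix.with_data(pd.DataFrame(out, index=df.index, columns=df.columns))


def cpm_normalize(
    counts: ExpressionMatrix,
    pseudocount: float = 1,
    pseudocount_after_scaling: bool = False,
) -> ExpressionMatrix:
    """Counts-per-million with a pseudocount to keep later ratios finite.

    Default order adds the pseudocount first and includes it in the library
    size: ``cpm = (count + k) / sum(count + k) * 1e6``.  The alternative
    order (scale raw counts, then add the pseudocount in CPM units) is
    available via ``pseudocount_after_scaling``.
    """
    if counts.kind != "count":
        raise ValueError(f"cpm normalization expects count data, got {counts.kind}")
    df = counts.data.astype(float)
    if df.empty:
        raise ValueError("empty count matrix")
    if pseudocount_after_scaling:
        libsize = df.sum(axis=0)
        if (libsize <= 0).any():
            raise ValueError("zero library size column; supply a pseudocount first")
        out = df / libsize * 1e6 + pseudocount
    else:
        inc = df + pseudocount
        libsize = inc.sum(axis=0)
        if (libsize <= 0).any():
            raise ValueError("zero library size column after pseudocount")
        out = inc / libsize * 1e6
    return counts.with_data(out, kind="cpm")


def detection_calls(
    matrix: ExpressionMatrix,
    cpm_threshold: float = 0.25,
    p_threshold: float = 0.05,
    grouping: pd.Series | None = None,
) -> pd.Series:
    """Per-feature detection booleans, optionally lifted to group level.

    Sequencing rule: detected iff CPM strictly exceeds ``cpm_threshold`` in
    at least one sample.  Array rule: detected iff the detection p-value is
    strictly below ``p_threshold`` in at least one sample.  With
    ``grouping`` (feature -> gene/pattern), a group is detected iff any
    member feature is detected in any sample.
    """
    if matrix.kind == "cpm":
        detected = (matrix.data > cpm_threshold).any(axis=1)
    elif matrix.kind == "count":
        raise ValueError("apply cpm_normalize before making sequencing detection calls")
    else:
        if matrix.detection_p is None:
            raise ValueError("array detection rule requires per-feature detection p-values")
        detected = (matrix.detection_p < p_threshold).any(axis=1)
    if grouping is None:
        return detected
    grouping = grouping.reindex(detected.index)
    return detected.groupby(grouping).any()


def tukey_biweight(values, c: float = 5.0, epsilon: float = 1e-4) -> float:
    """One-step Tukey biweight location estimate.

    With median ``m`` and median absolute deviation ``s``, each point gets
    ``u = (x - m) / (c*s + epsilon)`` and weight ``(1 - u^2)^2`` for
    ``|u| < 1`` (0 outside); the estimate is the weighted mean.  Robust to
    a minority of outlying probes; a single value returns itself.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("tukey_biweight of an empty vector")
    if not np.isfinite(x).all():
        raise ValueError("tukey_biweight requires finite values")
    if x.size == 1:
        return float(x[0])
    m = np.median(x)
    s = np.median(np.abs(x - m))
    u = (x - m) / (c * s + epsilon)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def summarize_to_level(
    matrix: ExpressionMatrix,
    grouping: pd.Series,
    c: float = 5.0,
    epsilon: float = 1e-4,
    log_transform: bool = True,
) -> ExpressionMatrix:
    """Biweight-summarize member features to pattern/gene level.

    Member values are moved to ``log2(value + 1)`` (biweight assumes
    roughly symmetric noise, which holds on the log scale), summarized per
    group per column, and reported on that log2 scale.  Groups absent from
    the matrix raise; features absent from the grouping are ignored.
    """
    missing = grouping.index.difference(matrix.data.index)
    if len(missing):
        raise ValueError(f"grouping references unknown features, e.g. {missing[0]!r}")
    df = matrix.data.loc[grouping.index]
    vals = np.log2(df + 1.0) if log_transform else df.astype(float)
    grouped = vals.groupby(grouping.to_numpy()).agg(
        lambda col: tukey_biweight(col.to_numpy(), c=c, epsilon=epsilon)
    )
    grouped.index.name = "feature_id"
    return ExpressionMatrix(
        data=grouped, kind="log2" if log_transform else matrix.kind,
        platform=matrix.platform,
    )


def collapse_replicates(
    matrix: ExpressionMatrix, design: TitrationDesign
) -> ExpressionMatrix:
    """Arithmetic mean of replicate columns, one output column per sample."""
    rep_cols = design.replicate_columns(matrix.platform or "")
    out = {}
    for sample in design.samples:
        cols = [c for c in rep_cols.get(sample, []) if c in matrix.data.columns]
        if not cols:
            # fall back on prefix matching for externally produced matrices
            cols = [c for c in matrix.data.columns if c == sample or c.startswith(f"{sample}_")]
        if not cols:
            raise ValueError(f"no replicate columns found for sample {sample}")
        out[sample] = matrix.data[cols].mean(axis=1)
    return matrix.with_data(pd.DataFrame(out, index=matrix.data.index))
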