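"""Signal-domain platform evaluation: range, background, titration fidelity.

These statistics characterize each platform's raw measurements before any
fold-change analysis: the five-number signal range of the two pure
samples, a signal-to-background ratio built from 99th-percentile signals,
a quasi-background for count data derived from "noise" genes (counted
only in mixtures, never in either pure source), per-feature fidelity of
signal to the titration series, and cross-platform rank similarity.
All percentiles use linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import TitrationDesign
from .matrix import ExpressionMatrix

__all__ = [
    "SignalRangeSummary",
    "FidelityResult",
    "signal_range_summary",
    "array_background",
    "quasi_background",
    "noise_gene_ids",
    "signal_to_background",
    "titration_fidelity",
    "cross_platform_similarity",
]


@dataclass
class SignalRangeSummary:
    """Five-number summaries of non-normalized values, per sample."""

    platform: str
    table: pd.DataFrame  # rows: min q25 median q75 max iqr; columns: samples

    def __post_init__(self) -> None:
        t = self.table
        for col in t.columns:
            v = t[col]
            if not (v["min"] <= v["q25"] <= v["median"] <= v["q75"] <= v["max"]):
                raise ValueError(f"inconsistent five-number summary for {col}")


@dataclass
class FidelityResult:
    """Per-feature titration correlations and the above-threshold fraction."""

    correlations: pd.Series  # NaN marks undefined (zero-variance) features
    threshold: float
    fraction_above: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_above <= 1.0:
            raise ValueError("fraction_above must lie in [0, 1]")


def signal_range_summary(
    raw: ExpressionMatrix, samples: list[str] | None = None
) -> SignalRangeSummary:
    """min / q25 / median / q75 / max (+ IQR) of raw values per sample.

    By convention the two pure sources are inspected (they bracket the
    expression diversity); pass ``samples`` to summarize other columns.
    """
    cols = samples if samples is not None else list(raw.data.columns)
    out = {}
    for col in cols:
        v = raw.data[col].to_numpy(dtype=float)
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        out[col] = {
            "min": v.min(), "q25": q25, "median": med, "q75": q75,
            "max": v.max(), "iqr": q75 - q25,
        }
    table = pd.DataFrame(out).loc[["min", "q25", "median", "q75", "max", "iqr"]]
    return SignalRangeSummary(platform=raw.platform, table=table)


def array_background(raw: ExpressionMatrix) -> float:
    """Mean of negative-control feature values across all samples."""
    ctrl = raw.data.loc[raw.is_control]
    if ctrl.empty:
        raise ValueError(
            "no negative-control features flagged; supply a background constant instead"
        )
    return float(ctrl.to_numpy(dtype=float).mean())


def noise_gene_ids(
    raw_counts: ExpressionMatrix, design: TitrationDesign, grouping: pd.Series | None = None
) -> pd.Index:
    """Genes/features with zero counts in both pure sources but counted in
    at least one mixture replicate."""
    if raw_counts.kind != "count":
        raise ValueError("noise genes are defined on raw count data")
    df = raw_counts.data
    if grouping is not None:
        df = df.groupby(grouping.reindex(df.index).to_numpy()).sum()
    pure_cols = [c for c in df.columns
                 if c.split("_rep")[0] in (design.pure_a, design.pure_b)]
    mix_cols = [c for c in df.columns
                if c.split("_rep")[0] in design.mixtures]
    zero_pure = (df[pure_cols] == 0).all(axis=1)
    any_mix = (df[mix_cols] > 0).any(axis=1)
    return df.index[zero_pure & any_mix]


def quasi_background(
    raw_counts: ExpressionMatrix,
    design: TitrationDesign,
    grouping: pd.Series | None = None,
    noise_genes_only: bool = True,
) -> float:
    """Noise floor for count data: median over the three mixture samples of
    the 99th percentile of noise-gene raw counts.

    Count platforms have no physical background, but features counted only
    in mixtures betray low-end sampling noise; their counts in the mixture
    samples estimate it.  Returns 0 (with a warning) when no noise genes
    exist.  ``noise_genes_only=False`` takes the percentiles over all
    features instead.
    """
    df = raw_counts.data
    if grouping is not None:
        df = df.groupby(grouping.reindex(df.index).to_numpy()).sum()
    if noise_genes_only:
        idx = noise_gene_ids(raw_counts, design, grouping=grouping)
        if len(idx) == 0:
            warnings.warn("no noise genes found; quasi-background is 0", stacklevel=2)
            return 0.0
        df = df.loc[idx]
    percentiles = []
    for sample in design.mixtures:
        cols = [c for c in df.columns if c.split("_rep")[0] == sample]
        percentiles.append(np.percentile(df[cols].to_numpy(dtype=float).ravel(), 99))
    return float(np.median(percentiles))


def signal_to_background(
    matrix: ExpressionMatrix, background: float, design: TitrationDesign | None = None
) -> float:
    """Mean 99th-percentile value over the titration samples / background."""
    if background <= 0:
        raise ValueError("background must be positive")
    df = matrix.data
    if design is not None:
        p99 = [
            np.percentile(
                df[[c for c in df.columns if c.split("_rep")[0] == s]]
                .to_numpy(dtype=float).ravel(), 99)
            for s in design.samples
        ]
    else:
        p99 = [np.percentile(df[c].to_numpy(dtype=float), 99) for c in df.columns]
    return float(np.mean(p99) / background)


def titration_fidelity(
    raw: ExpressionMatrix,
    design: TitrationDesign,
    threshold: float = 0.5,
    log2: bool = False,
) -> FidelityResult:
    """Per-feature Pearson correlation of value against the mixing fraction.

    The x-variable is the source-B fraction itself (expected abundance is
    linear in it), not an ordinal index.  Features with zero variance carry
    no titration information: they are marked NaN and excluded from the
    reported fraction's denominator.  Replicate columns are averaged per
    sample first.
    """
    from .preprocess import collapse_replicates

    if len({design.bmo_fraction[s] for s in design.samples}) < 3:
        raise ValueError("need at least 3 distinct mixture fractions")
    collapsed = collapse_replicates(raw, design)
    x = np.array([design.bmo_fraction[s] for s in design.samples])
    vals = collapsed.data[list(design.samples)].to_numpy(dtype=float)
    if log2:
        vals = np.log2(vals + 1.0)

    xc = x - x.mean()
    vc = vals - vals.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sv = np.sqrt((vc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ xc) / (sv * sx)
    r[sv == 0] = np.nan
    corr = pd.Series(r, index=collapsed.data.index)
    defined = corr.dropna()
    frac = float((defined.abs() > threshold).mean()) if len(defined) else 0.0
    return FidelityResult(correlations=corr, threshold=threshold, fraction_above=frac)


def cross_platform_similarity(
    gene_aligned: dict[str, pd.Series], sample: str | None = None
) -> pd.DataFrame:
    """Spearman rank-correlation matrix across platforms on a common index.

    ``gene_aligned`` maps platform -> per-gene values for one sample (from
    matrices aligned on a shared gene set).  Diagonal is 1 by construction.
    """
    platforms = list(gene_aligned)
    common = gene_aligned[platforms[0]].index
    for p in platforms[1:]:
        common = common.intersection(gene_aligned[p].index)
    if len(common) < 2:
        raise ValueError("need at least 2 common genes for rank correlation")
    mat = pd.DataFrame(
        np.eye(len(platforms)), index=platforms, columns=platforms
    )
    for i, a in enumerate(platforms):
        for j, b in enumerate(platforms):
            if j <= i:
                continue
            rho = stats.spearmanr(
                gene_aligned[a].loc[common], gene_aligned[b].loc[common]
            ).statistic
            mat.iloc[i, j] = mat.iloc[j, i] = rho
    return mat
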