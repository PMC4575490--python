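"""Fold-change magnitude, fidelity, enhancement, and compression metrics.

Ratios of each mixture (and pure source B) against pure source A are
turned into absolute fold-changes (reciprocal for down-regulation, so up
and down magnitudes are comparable), averaged per titration contrast and
overall, correlated against the titration to score fidelity, and — for
cross-platform comparison — regressed in log2-ratio space against a
reference platform, where fold-change compression is ``(1 - slope) * 100``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import TitrationDesign
from .matrix import ExpressionMatrix

__all__ = [
    "FoldChangeTable",
    "absolute_fold_change",
    "build_fold_change_table",
    "average_abs_fc",
    "fc_titration_fidelity",
    "fc_enhancement",
    "fc_compression",
]

log = logging.getLogger(__name__)


@dataclass
class FoldChangeTable:
    """Per-gene ratios against pure source A for the titration contrasts."""

    platform: str
    contrasts: tuple[str, ...]  # mixture/pure-B sample labels, titration order
    ratio: pd.DataFrame         # genes x contrasts, linear scale
    contrast_fraction: dict[str, float]

    @property
    def log2_ratio(self) -> pd.DataFrame:
        return np.log2(self.ratio)

    @property
    def abs_fc(self) -> pd.DataFrame:
        r = self.ratio
        return r.where(r >= 1.0, 1.0 / r)

    def to_tsv(self, path) -> None:
        rows = []
        for gene, row in self.ratio.iterrows():
            for contrast in self.contrasts:
                ratio = row[contrast]
                rows.append([
                    gene, contrast, ratio, np.log2(ratio),
                    ratio if ratio >= 1 else 1 / ratio,
                ])
        pd.DataFrame(
            rows, columns=["gene_id", "contrast", "ratio", "log2_ratio", "abs_fc"]
        ).to_csv(path, sep="\t", index=False)


def absolute_fold_change(ratio: float) -> float:
    """Map a positive ratio to magnitude >= 1 (reciprocal below 1)."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    return ratio if ratio >= 1.0 else 1.0 / ratio


def build_fold_change_table(
    collapsed: ExpressionMatrix,
    design: TitrationDesign,
    gene_subset=None,
    detected: pd.Series | None = None,
    floor: float = 1e-6,
) -> FoldChangeTable:
    """Ratios of every non-reference sample against pure source A.

    Expects a normalized, replicate-collapsed matrix on the linear scale
    (CPM for counts, normalized signal for arrays; ``log2`` matrices are
    moved back to linear first).  Values are floored at a small positive
    constant to keep ratios and logs finite; flooring events are logged.
    ``detected`` restricts to features whose detection call is True.
    """
    ref = design.pure_a
    if ref not in collapsed.data.columns:
        raise ValueError(f"reference sample column {ref!r} missing")
    df = collapsed.data
    if collapsed.kind == "log2":
        df = np.exp2(df) - 1.0
    if gene_subset is not None:
        df = df.loc[df.index.intersection(pd.Index(gene_subset))]
    if detected is not None:
        keep = detected.reindex(df.index).fillna(False)
        df = df.loc[keep]
    n_floored = int((df < floor).to_numpy().sum())
    if n_floored:
        log.info("floored %d values below %g before forming ratios", n_floored, floor)
    df = df.clip(lower=floor)
    contrasts = tuple(s for s in design.samples if s != ref)
    ratio = pd.DataFrame({s: df[s] / df[ref] for s in contrasts})
    return FoldChangeTable(
        platform=collapsed.platform,
        contrasts=contrasts,
        ratio=ratio,
        contrast_fraction={s: design.bmo_fraction[s] for s in contrasts},
    )


def average_abs_fc(table: FoldChangeTable, gene_subset=None) -> tuple[pd.Series, float]:
    """Mean absolute fold-change per contrast, and the overall platform mean.

    The overall value is the unweighted mean of the per-contrast means —
    one number summarizing the platform's differential-expression
    magnitude across the whole titration.
    """
    fc = table.abs_fc
    if gene_subset is not None:
        idx = fc.index.intersection(pd.Index(gene_subset))
        if idx.empty:
            raise ValueError("empty gene subset for fold-change averaging")
        fc = fc.loc[idx]
    if fc.empty:
        raise ValueError("no genes to average")
    per_contrast = fc.mean(axis=0)
    return per_contrast, float(per_contrast.mean())


def fc_titration_fidelity(
    table: FoldChangeTable, threshold: float = 0.5, ordinal_x: bool = False
) -> tuple[pd.Series, float]:
    """Fraction of genes whose absolute fold-change follows the titration.

    Per gene, Pearson r between the four contrasts' absolute fold-changes
    and their source-B fractions (or an ordinal 1..k with ``ordinal_x``);
    reported is the fraction with r strictly above ``+threshold``
    (one-sided — anti-correlated genes do not count).  Zero-variance genes
    are excluded from the denominator.
    """
    if len(table.contrasts) < 2:
        raise ValueError("need at least 2 contrasts for fold-change fidelity")
    fc = table.abs_fc[list(table.contrasts)].to_numpy(dtype=float)
    if ordinal_x:
        x = np.arange(1.0, len(table.contrasts) + 1)
    else:
        x = np.array([table.contrast_fraction[s] for s in table.contrasts])
    xc = x - x.mean()
    vc = fc - fc.mean(axis=1, keepdims=True)
    sv = np.sqrt((vc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ xc) / (sv * np.sqrt((xc**2).sum()))
    r[sv == 0] = np.nan
    corr = pd.Series(r, index=table.abs_fc.index)
    defined = corr.dropna()
    frac = float((defined > threshold).mean()) if len(defined) else 0.0
    return corr, frac


def fc_enhancement(baseline_overall: float, refined_overall: float) -> float:
    """Relative gain (percent) in overall absolute fold-change after
    refinement (detection-call filtering or pattern restriction)."""
    if baseline_overall <= 0:
        raise ValueError("baseline overall fold-change must be positive")
    return (refined_overall - baseline_overall) / baseline_overall * 100.0


def fc_compression(reference_log2, other_log2) -> dict[str, float]:
    """OLS fit of a platform's log2 ratios on a reference's: slope, R²,
    and compression percent ``(1 - slope) * 100``.

    A slope below 1 means the platform systematically understates
    fold-changes relative to the reference.
    """
    x = np.asarray(reference_log2, dtype=float)
    y = np.asarray(other_log2, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs for the compression fit")
    if np.ptp(x) == 0:
        raise ValueError("reference log2 ratios have zero variance")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "compression_percent": float((1.0 - fit.slope) * 100.0),
    }
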