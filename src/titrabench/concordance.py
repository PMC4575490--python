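"""qRT-PCR fold-changes (delta-delta Ct) and concordance classification.

A Ct table (gene x sample x replicate cycle-threshold values) is QC
filtered, normalized to a housekeeping gene (delta Ct), referenced to a
baseline sample (delta-delta Ct), and converted to fold-change as
``2**(-ddCt)``.  Each platform fold-change is then compared with the qPCR
reference and given one of four verdicts — compressed, opposite,
overestimate, concordant — whose "concordant + overestimate" share is the
concordance rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .patterns import TranscriptPattern, assign_transcript_sets

__all__ = [
    "CtTable",
    "ConcordanceCall",
    "qc_ct",
    "delta_delta_ct",
    "signed_fold_change",
    "classify_concordance",
    "concordance_rate",
    "amplicon_pattern_overlap",
]

VERDICTS = ("compressed", "opposite", "overestimate", "concordant")


@dataclass
class CtTable:
    """Long-format qPCR Ct measurements plus the housekeeping gene id."""

    data: pd.DataFrame  # columns: gene_id, sample, replicate, ct
    housekeeping: str

    def __post_init__(self) -> None:
        required = {"gene_id", "sample", "replicate", "ct"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"Ct table needs columns {sorted(required)}")
        ct = self.data["ct"]
        if ((ct <= 0) | (ct > 40)).any():
            raise ValueError("Ct values must lie in (0, 40]")
        samples = set(self.data["sample"])
        hk = self.data[self.data["gene_id"] == self.housekeeping]
        if set(hk["sample"]) != samples:
            raise ValueError("housekeeping gene must be measured in every sample")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, housekeeping: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), housekeeping)


def qc_ct(
    raw: pd.DataFrame,
    housekeeping: str,
    max_ct: float = 40.0,
    max_cv: float = 0.30,
    fail_fraction: float = 0.5,
) -> CtTable:
    """Drop unreliable gene-sample cells before quantification.

    A cell fails when more than ``fail_fraction`` of its replicates exceed
    ``max_ct`` (amplification failure), or when the coefficient of
    variation of its replicate Ct values exceeds ``max_cv``.  ``raw`` may
    contain Ct values above ``max_ct``; surviving cells are guaranteed not
    to.  Raises if the housekeeping gene loses any sample.
    """
    kept = []
    samples = set(raw["sample"])
    for (gene, sample), grp in raw.groupby(["gene_id", "sample"], sort=False):
        ct = grp["ct"].to_numpy(dtype=float)
        if (ct > max_ct).mean() > fail_fraction:
            continue
        good = grp[grp["ct"] <= max_ct]
        ct = good["ct"].to_numpy(dtype=float)
        if len(ct) == 0:
            continue
        if len(ct) > 1 and ct.mean() > 0 and ct.std(ddof=1) / ct.mean() > max_cv:
            continue
        kept.append(good)
    if not kept:
        raise ValueError("QC removed every Ct measurement")
    out = pd.concat(kept, ignore_index=True)
    hk_samples = set(out.loc[out["gene_id"] == housekeeping, "sample"])
    if hk_samples != samples:
        missing = sorted(samples - hk_samples)
        raise ValueError(f"housekeeping gene failed QC in samples {missing}")
    return CtTable(out, housekeeping)


def delta_delta_ct(table: CtTable, reference_sample: str) -> pd.DataFrame:
    """Fold-change per gene per sample by the delta-delta Ct method.

    Replicate Ct values are averaged; ``dCt = Ct_gene - Ct_housekeeping``
    per sample, ``ddCt = dCt_sample - dCt_reference``, fold-change
    ``2**(-ddCt)``.  Genes lacking the reference sample are dropped.
    Returns genes x samples fold-changes (reference column = 1).
    """
    mean_ct = table.data.groupby(["gene_id", "sample"])["ct"].mean().unstack()
    if reference_sample not in mean_ct.columns:
        raise ValueError(f"reference sample {reference_sample!r} missing from Ct table")
    hk = mean_ct.loc[table.housekeeping]
    dct = mean_ct.subtract(hk, axis=1).drop(index=table.housekeeping)
    dct = dct.dropna(subset=[reference_sample])
    ddct = dct.subtract(dct[reference_sample], axis=0)
    return np.exp2(-ddct)


def signed_fold_change(ratio: float) -> float:
    """Linear ratio -> signed fold-change (magnitude >= 1, sign = direction)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1.0 else -1.0 / ratio


@dataclass
class ConcordanceCall:
    """One platform-vs-reference fold-change comparison."""

    gene_id: str
    x: float  # reference (qPCR) signed fold-change
    y: float  # platform signed fold-change
    verdict: str = field(init=False)
    flagged: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.verdict, self.flagged = classify_concordance(self.x, self.y, flag=True)


def classify_concordance(x: float, y: float, flag: bool = False):
    """Four-way verdict comparing platform fold-change Y against reference X.

    Both values are signed fold-changes (sign = direction of change,
    magnitude = absolute fold-change; a ratio below 1 is accepted and
    normalized to its reciprocal with flipped sign).  Same direction:
    magnitude ratio ``|X|/|Y| >= 2`` is "compressed", ``<= 0.5``
    "overestimate", in between "concordant".  Opposite directions: if
    either magnitude exceeds 2 the verdict is "opposite"; when both are
    within 2-fold neither platform claims a real change, so the comparison
    is "concordant" (flagged for transparency).
    """
    if x == 0 or y == 0:
        raise ValueError("fold-changes must be non-zero signed magnitudes")

    def norm(v):
        sign = 1.0 if v > 0 else -1.0
        mag = abs(v)
        if mag < 1.0:
            sign, mag = -sign, 1.0 / mag
        return sign, mag

    sx, mx = norm(x)
    sy, my = norm(y)
    flagged = False
    if sx == sy:
        ratio = mx / my
        if ratio >= 2.0:
            verdict = "compressed"
        elif ratio <= 0.5:
            verdict = "overestimate"
        else:
            verdict = "concordant"
    else:
        if mx > 2.0 or my > 2.0:
            verdict = "opposite"
        else:
            verdict = "concordant"
            flagged = True
    return (verdict, flagged) if flag else verdict


def concordance_rate(calls: list[ConcordanceCall]) -> float:
    """Percent of calls judged concordant or overestimate."""
    if not calls:
        raise ValueError("no concordance calls to summarize")
    good = sum(c.verdict in ("concordant", "overestimate") for c in calls)
    return 100.0 * good / len(calls)


def amplicon_pattern_overlap(
    amplicons: pd.DataFrame,
    annotation: GenomeAnnotation,
    patterns: list[TranscriptPattern],
) -> set[str]:
    """Genes whose PCR amplicon selects an existing common pattern.

    ``amplicons`` needs columns gene_id, chrom, start, end.  The amplicon
    interval is mapped with the same containment rule as probes; the gene
    is retained iff the resulting transcript set equals one of its derived
    patterns — i.e. the qPCR assay measures the same RNA species the other
    platforms' pattern features do.
    """
    probe_like = pd.DataFrame({
        "probe_id": amplicons["gene_id"].astype(str) + ":amplicon",
        "platform": "qPCR",
        "chrom": amplicons["chrom"],
        "start": amplicons["start"],
        "end": amplicons["end"],
        "gene_id": amplicons["gene_id"],
        "align_class": "unique_full",
    })
    targets = assign_transcript_sets(probe_like, annotation)
    by_gene = {(p.gene_id, p.transcript_set) for p in patterns}
    out = set()
    for probe_id, target in targets.items():
        if (target.gene_id, target.transcripts) in by_gene:
            out.add(target.gene_id)
    return out
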