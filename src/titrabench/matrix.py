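"""Feature x sample expression container shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "VALUE_KINDS"]

VALUE_KINDS = ("signal", "count", "cpm", "log2")


@dataclass
class ExpressionMatrix:
    """Features x sample-replicate values plus detection/control metadata.

    Parameters
    ----------
    data
        Values, indexed by feature id, one column per sample replicate.
    kind
        One of ``signal`` (continuous array intensities), ``count``
        (non-negative integers from sequencing), ``cpm`` or ``log2``.
    detection_p
        Optional per-feature per-column detection p-values (array platforms).
    is_control
        Boolean flag per feature marking negative-control features.
    feature_gene
        Optional feature id -> gene id map (used for gene-level grouping
        and accounting).
    """

    data: pd.DataFrame
    kind: str
    platform: str = ""
    detection_p: pd.DataFrame | None = None
    is_control: pd.Series | None = None
    feature_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.kind!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.kind == "count":
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise ValueError("counts must be non-negative")
        if self.detection_p is not None and not self.detection_p.index.equals(
            self.data.index
        ):
            raise ValueError("detection_p index must match data index")
        if self.is_control is None:
            self.is_control = pd.Series(False, index=self.data.index)

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def columns(self) -> pd.Index:
        return self.data.columns

    def non_control(self) -> "ExpressionMatrix":
        keep = ~self.is_control
        return self.subset(self.data.index[keep])

    def subset(self, feature_ids) -> "ExpressionMatrix":
        idx = pd.Index(feature_ids)
        return replace(
            self,
            data=self.data.loc[idx],
            detection_p=None if self.detection_p is None else self.detection_p.loc[idx],
            is_control=self.is_control.loc[idx],
            feature_gene=None if self.feature_gene is None else self.feature_gene.loc[
                self.feature_gene.index.intersection(idx)
            ],
        )

    def with_data(self, data: pd.DataFrame, kind: str | None = None) -> "ExpressionMatrix":
        return replace(self, data=data, kind=kind or self.kind)

    # -- TSV I/O ---------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, kind: str, platform: str = "") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("feature_id")
        if kind == "count":
            df = df.astype(np.int64) if (df.round() == df).all().all() else df
        return cls(data=df, kind=kind, platform=platform)
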