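"""Titration mixture design.

The benchmark rests on a five-sample titration between two pure RNA sources:
a universal reference ("AGO", source A) and bone marrow ("BMO", source B).
Three mixtures are made by diluting A into B so that expected expression of
every gene is linear in the source-B proportion.  Sample labels follow the
``AG<a>BM<b>`` convention, read as *a* parts of source A per *b* total parts,
so AG1BM4 carries 1/4 source A and 3/4 source B.  (The naive reading "1 part
A : 4 parts B" would give 80 % B, which contradicts the design's stated
75 / 93.75 / 98.4375 % series; the percentage series is authoritative.)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

__all__ = [
    "TitrationDesign",
    "mixing_fraction",
    "canonical_design",
    "CANONICAL_SAMPLES",
]

#: Canonical sample labels in titration order (pure A -> pure B).
CANONICAL_SAMPLES = ("AGO", "AG1BM4", "AG1BM16", "AG1BM64", "BMO")

_CANONICAL_FRACTIONS = {
    "AGO": 0.0,
    "AG1BM4": 0.75,
    "AG1BM16": 0.9375,
    "AG1BM64": 0.984375,
    "BMO": 1.0,
}

_LABEL_RE = re.compile(r"^AG(\d+)BM(\d+)$")
_RATIO_RE = re.compile(r"^(\d+(?:\.\d+)?):(\d+(?:\.\d+)?)$")


def mixing_fraction(sample_label: str) -> float:
    """Source-B (BMO) proportion in ``[0, 1]`` for a titration sample.

    Canonical labels map AGO -> 0, AG1BM4 -> 0.75, AG1BM16 -> 0.9375,
    AG1BM64 -> 0.984375, BMO -> 1.  A generic ``AG<a>BM<b>`` label is read
    as *a* parts source A in *b* total parts (fraction ``1 - a/b``), and a
    bare ratio string ``"a:b"`` the same way.

    Raises
    ------
    ValueError
        If the label is neither canonical nor parseable.
    """
    label = sample_label.strip()
    if label in _CANONICAL_FRACTIONS:
        return _CANONICAL_FRACTIONS[label]
    m = _LABEL_RE.match(label) or _RATIO_RE.match(label)
    if m:
        a, b = float(m.group(1)), float(m.group(2))
        if b <= 0 or a > b:
            raise ValueError(f"impossible mixing ratio in label {sample_label!r}")
        return 1.0 - a / b
    raise ValueError(f"unparseable titration sample label: {sample_label!r}")


@dataclass
class TitrationDesign:
    """Samples of a two-source titration and their replicate structure.

    Parameters
    ----------
    samples
        Ordered sample labels; fractions must be strictly increasing with
        endpoints exactly 0 and 1.
    bmo_fraction
        Source-B proportion per sample.
    replicates
        ``{platform: {sample: n_replicates}}``; every sample needs >= 1.
    """

    samples: tuple[str, ...]
    bmo_fraction: dict[str, float]
    replicates: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fracs = [self.bmo_fraction[s] for s in self.samples]
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("mixture fractions must be strictly increasing")
        if fracs[0] != 0.0 or fracs[-1] != 1.0:
            raise ValueError("titration endpoints must be the pure sources (0 and 1)")
        for platform, per_sample in self.replicates.items():
            for s, n in per_sample.items():
                if n < 1:
                    raise ValueError(f"sample {s} on {platform} has {n} replicates")

    @property
    def pure_a(self) -> str:
        return self.samples[0]

    @property
    def pure_b(self) -> str:
        return self.samples[-1]

    @property
    def mixtures(self) -> tuple[str, ...]:
        return self.samples[1:-1]

    def n_replicates(self, platform: str, sample: str) -> int:
        return self.replicates.get(platform, {}).get(sample, 1)

    def replicate_columns(self, platform: str) -> dict[str, list[str]]:
        """Column labels ``sample_rep<i>`` per sample for one platform."""
        return {
            s: [f"{s}_rep{i + 1}" for i in range(self.n_replicates(platform, s))]
            for s in self.samples
        }

    def to_yaml(self, path) -> None:
        doc = {
            "samples": list(self.samples),
            "bmo_fraction": {s: float(f) for s, f in self.bmo_fraction.items()},
            "replicates": self.replicates,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TitrationDesign":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            samples=tuple(doc["samples"]),
            bmo_fraction=doc["bmo_fraction"],
            replicates=doc.get("replicates", {}),
        )


def canonical_design(
    platforms: dict[str, int] | None = None,
) -> TitrationDesign:
    """The study's five-sample AGO/BMO series.

    ``platforms`` maps platform name to a uniform replicate count per sample
    (default 2, roughly the study's duplicate-on-average structure).
    """
    platforms = platforms or {}
    replicates = {
        p: {s: n for s in CANONICAL_SAMPLES} for p, n in platforms.items()
    }
    return TitrationDesign(
        samples=CANONICAL_SAMPLES,
        bmo_fraction=dict(_CANONICAL_FRACTIONS),
        replicates=replicates,
    )
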