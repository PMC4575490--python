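"""In-silico analogue of a multi-platform titration experiment.

Generates, with known ground truth, everything the downstream evaluation
needs: a multi-isoform annotation, per-platform probe tables, and
feature x sample expression matrices for the five-sample two-source
titration.  The model:

* expected pre-noise abundance of gene *g* in sample *s* is
  ``f * eB_g + (1 - f) * eA_g`` where ``f`` is the source-B mixing fraction
  and ``eA``/``eB`` are the pure-source baselines;
* array-like platforms emit ``background + gain * abundance**c`` with
  multiplicative log-normal noise — the power-law exponent ``c`` in (0, 1]
  plants fold-change compression, since a log2 ratio scales by exactly
  ``c``;
* sequencing-like platforms emit per-exon counts from a negative binomial
  with mean proportional to ``abundance**c`` x exon length x library size
  (dispersion 0 degenerates to Poisson; noise scale 0 emits the mean
  deterministically);
* "noise" genes have zero baseline in both pure sources but receive
  occasional low counts (1-12) in the mixture samples only, emulating the
  low-end read noise that motivates a quasi-background estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .annotation import Exon, Gene, GenomeAnnotation
from .design import TitrationDesign
from .matrix import ExpressionMatrix

__all__ = [
    "PlatformSpec",
    "SyntheticTruth",
    "make_truth",
    "generate_platform_probes",
    "generate_expression",
    "count_mean_matrix",
    "pattern_demo",
    "write_probes_bed",
    "read_probes_bed",
]

PROBE_COLUMNS = ["probe_id", "platform", "chrom", "start", "end", "gene_id", "align_class"]


@dataclass
class PlatformSpec:
    """Static description of one measurement platform.

    ``kind`` is ``signal`` (probe-based array) or ``count`` (exon-level
    sequencing).  ``placement`` biases probe positions toward the 3' end
    (``three_prime``) or spreads them over the whole transcript.
    ``decoy_fraction`` of probes are deliberately emitted as multi-mapping
    or partial alignments to exercise the ambiguity filter.
    """

    name: str
    kind: str = "signal"
    probe_length: int = 50
    probes_per_gene: int = 3
    placement: str = "whole_transcript"
    decoy_fraction: float = 0.0
    n_controls: int = 20
    detection_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("signal", "count"):
            raise ValueError(f"platform kind must be signal or count, got {self.kind!r}")
        if self.placement not in ("whole_transcript", "three_prime"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if not 0 <= self.decoy_fraction <= 1:
            raise ValueError("decoy_fraction must be in [0, 1]")
        if self.probe_length < 1 or self.probes_per_gene < 1:
            raise ValueError("probe_length and probes_per_gene must be positive")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters that fully determine a simulated experiment."""

    genes: list[str]
    baseline_a: np.ndarray
    baseline_b: np.ndarray
    noise_gene: np.ndarray
    compression: dict[str, float]
    noise_scale: dict[str, float]
    background: dict[str, float]
    gain: dict[str, float]
    library_size: dict[str, float]
    dispersion: dict[str, float]
    noise_count_rate: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name, d in (
            ("compression", self.compression),
            ("gain", self.gain),
            ("library_size", self.library_size),
        ):
            for k, v in d.items():
                if v <= 0:
                    raise ValueError(f"{name}[{k}] must be positive, got {v}")
        for k, v in self.compression.items():
            if v > 1:
                raise ValueError(f"compression[{k}] must be in (0, 1], got {v}")
        for name, d in (
            ("noise_scale", self.noise_scale),
            ("background", self.background),
            ("dispersion", self.dispersion),
        ):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"{name}[{k}] must be non-negative, got {v}")
        if (self.baseline_a < 0).any() or (self.baseline_b < 0).any():
            raise ValueError("baselines must be non-negative")
        ng = self.noise_gene.astype(bool)
        if (self.baseline_a[ng] != 0).any() or (self.baseline_b[ng] != 0).any():
            raise ValueError("noise genes must have zero baseline in both sources")

    def abundance(self, fraction: float) -> pd.Series:
        """Expected pre-noise abundance per gene at mixing fraction ``f``."""
        vals = fraction * self.baseline_b + (1.0 - fraction) * self.baseline_a
        return pd.Series(vals, index=self.genes)

    def to_yaml(self, path) -> None:
        doc = {
            "seed": int(self.seed),
            "genes": list(self.genes),
            "baseline_a": [float(x) for x in self.baseline_a],
            "baseline_b": [float(x) for x in self.baseline_b],
            "noise_gene": [bool(x) for x in self.noise_gene],
            "compression": {k: float(v) for k, v in self.compression.items()},
            "noise_scale": {k: float(v) for k, v in self.noise_scale.items()},
            "background": {k: float(v) for k, v in self.background.items()},
            "gain": {k: float(v) for k, v in self.gain.items()},
            "library_size": {k: float(v) for k, v in self.library_size.items()},
            "dispersion": {k: float(v) for k, v in self.dispersion.items()},
            "noise_count_rate": float(self.noise_count_rate),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            genes=doc["genes"],
            baseline_a=np.asarray(doc["baseline_a"], dtype=float),
            baseline_b=np.asarray(doc["baseline_b"], dtype=float),
            noise_gene=np.asarray(doc["noise_gene"], dtype=bool),
            compression=doc["compression"],
            noise_scale=doc["noise_scale"],
            background=doc["background"],
            gain=doc["gain"],
            library_size=doc["library_size"],
            dispersion=doc["dispersion"],
            noise_count_rate=doc.get("noise_count_rate", 0.35),
            seed=doc.get("seed", 0),
        )


def make_truth(
    annotation: GenomeAnnotation,
    platforms: list[PlatformSpec],
    seed: int = 0,
    noise_gene_fraction: float = 0.05,
    compression: dict[str, float] | None = None,
    noise_scale: dict[str, float] | None = None,
    background: dict[str, float] | None = None,
    gain: dict[str, float] | None = None,
    library_size: dict[str, float] | None = None,
    dispersion: dict[str, float] | None = None,
    log2fc_sd: float = 1.5,
) -> SyntheticTruth:
    """Draw per-gene baselines and assemble per-platform truth parameters.

    Baselines are log-normal (abundances span several orders of magnitude,
    as real transcriptomes do); the B-vs-A differential is log-normal with
    spread ``log2fc_sd`` on the log2 scale.  ``noise_gene_fraction`` of
    genes are flagged as noise genes with zero baseline in both sources.
    Per-platform defaults: no compression (c = 1), noise scale 0.3,
    background 20 (signal platforms), gain 1, library size 2e6, NB
    dispersion 0.05.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(annotation.genes)
    n = len(genes)
    baseline_a = rng.lognormal(mean=3.0, sigma=1.3, size=n)
    log2fc = rng.normal(0.0, log2fc_sd, size=n)
    baseline_b = baseline_a * np.exp2(log2fc)
    noise_gene = np.zeros(n, dtype=bool)
    n_noise = int(round(noise_gene_fraction * n))
    if n_noise:
        noise_idx = rng.choice(n, size=n_noise, replace=False)
        noise_gene[noise_idx] = True
        baseline_a[noise_gene] = 0.0
        baseline_b[noise_gene] = 0.0

    names = [p.name for p in platforms]

    def fill(given, default):
        given = given or {}
        return {nm: float(given.get(nm, default)) for nm in names}

    return SyntheticTruth(
        genes=genes,
        baseline_a=baseline_a,
        baseline_b=baseline_b,
        noise_gene=noise_gene,
        compression=fill(compression, 1.0),
        noise_scale=fill(noise_scale, 0.3),
        background=fill(background, 20.0),
        gain=fill(gain, 1.0),
        library_size=fill(library_size, 2e6),
        dispersion=fill(dispersion, 0.05),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# probe generation


def generate_platform_probes(
    annotation: GenomeAnnotation, spec: PlatformSpec, seed: int = 0
) -> pd.DataFrame:
    """Place probes fully inside exons of each gene, plus optional decoys.

    Returns a table with one row per probe interval (multi-mapping decoys
    contribute two rows sharing a probe id) and an ``align_class`` column in
    {unique_full, multiple, partial}.  With ``decoy_fraction = 0`` every
    probe lies fully within an exon of its source gene.
    """
    rng = np.random.default_rng([seed, abs(hash(spec.name)) % (2**31)])
    rows = []
    chroms = sorted(annotation.chromosomes())
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        exon_ids = sorted(
            {e for tx in gene.transcripts.values() for e in tx},
            key=lambda e: annotation.exons[e].start,
        )
        usable = [
            e
            for e in exon_ids
            if annotation.exons[e].end - annotation.exons[e].start >= spec.probe_length
        ]
        if not usable:
            raise ValueError(
                f"gene {gene_id} has no exon long enough for probe length "
                f"{spec.probe_length}"
            )
        if spec.placement == "three_prime":
            # weight toward the transcript's downstream end
            w = np.arange(1, len(usable) + 1, dtype=float)
            if gene.strand == "-":
                w = w[::-1]
        else:
            w = np.ones(len(usable))
        w = w / w.sum()
        for pi in range(spec.probes_per_gene):
            probe_id = f"{spec.name}:{gene_id}:p{pi + 1}"
            exon = annotation.exons[usable[rng.choice(len(usable), p=w)]]
            offset = int(rng.integers(0, exon.end - exon.start - spec.probe_length + 1))
            start = exon.start + offset
            end = start + spec.probe_length
            if rng.random() < spec.decoy_fraction:
                if rng.random() < 0.5:
                    # multi-mapping: a second spurious hit elsewhere
                    other = chroms[int(rng.integers(0, len(chroms)))]
                    rows.append([probe_id, spec.name, exon.chrom, start, end,
                                 gene_id, "multiple"])
                    rows.append([probe_id, spec.name, other,
                                 start + 10_000_000, end + 10_000_000,
                                 gene_id, "multiple"])
                else:
                    # partial: slide half the probe past the exon boundary
                    shift = spec.probe_length // 2 + 1
                    rows.append([probe_id, spec.name, exon.chrom,
                                 exon.end - spec.probe_length + shift,
                                 exon.end + shift, gene_id, "partial"])
            else:
                rows.append([probe_id, spec.name, exon.chrom, start, end,
                             gene_id, "unique_full"])
    return pd.DataFrame(rows, columns=PROBE_COLUMNS)


def write_probes_bed(probes: pd.DataFrame, path) -> None:
    """BED6: chrom, start, end, probe_id, score 0, strand '+'."""
    with open(path, "w") as fh:
        for row in probes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.probe_id}\t0\t+\n")


def read_probes_bed(path, platform: str, align_class: str = "unique_full") -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name = line.split("\t")[:4]
            rows.append([name, platform, chrom, int(start), int(end), "", align_class])
    return pd.DataFrame(rows, columns=PROBE_COLUMNS)


# ---------------------------------------------------------------------------
# expression generation


def _exon_weights(annotation: GenomeAnnotation) -> pd.DataFrame:
    rows = [
        (eid, ex.gene_id, ex.end - ex.start)
        for eid, ex in sorted(annotation.exons.items())
    ]
    return pd.DataFrame(rows, columns=["exon_id", "gene_id", "length"])


def count_mean_matrix(
    annotation: GenomeAnnotation,
    design: TitrationDesign,
    truth: SyntheticTruth,
    platform: str,
) -> pd.DataFrame:
    """Expected (pre-sampling) NB mean count per exon per replicate column."""
    ex = _exon_weights(annotation)
    c = truth.compression[platform]
    lib = truth.library_size[platform]
    scale = _count_scale(ex, truth, platform)
    cols = {}
    for sample, reps in design.replicate_columns(platform).items():
        ab = truth.abundance(design.bmo_fraction[sample]) ** c
        intensity = ab.loc[ex["gene_id"]].to_numpy() * ex["length"].to_numpy()
        mu = lib * intensity * scale
        for col in reps:
            cols[col] = mu
    return pd.DataFrame(cols, index=pd.Index(ex["exon_id"], name="feature_id"))


def _count_scale(ex: pd.DataFrame, truth: SyntheticTruth, platform: str) -> float:
    """Constant converting abundance x length into expected reads.

    The scale is fixed from the mean of the two pure-source totals so the
    NB mean stays strictly proportional to abundance across the titration
    (library sizes then fluctuate mildly with composition, as real
    sequencing depth does around its target).
    """
    c = truth.compression[platform]
    totals = []
    for f in (0.0, 1.0):
        ab = truth.abundance(f) ** c
        totals.append((ab.loc[ex["gene_id"]].to_numpy() * ex["length"].to_numpy()).sum())
    mean_total = float(np.mean(totals))
    if mean_total <= 0:
        raise ValueError("annotation/truth yield zero total abundance")
    return 1.0 / mean_total


def generate_expression(
    annotation: GenomeAnnotation,
    probes: dict[str, pd.DataFrame],
    design: TitrationDesign,
    truth: SyntheticTruth,
    specs: list[PlatformSpec],
) -> dict[str, ExpressionMatrix]:
    """One ExpressionMatrix per platform under the titration mixture model.

    Signal platforms measure one value per probe of their probe table
    (decoys included — filtering them is downstream's job) plus
    ``n_controls`` negative-control features sitting at background.  Count
    platforms measure one value per annotated exon.
    """
    out: dict[str, ExpressionMatrix] = {}
    for p_idx, spec in enumerate(specs):
        rng = np.random.default_rng([truth.seed, 7_000_003 + p_idx])
        rep_cols = design.replicate_columns(spec.name)
        col_fraction = {
            col: design.bmo_fraction[s] for s, cols in rep_cols.items() for col in cols
        }
        columns = [c for s in design.samples for c in rep_cols[s]]
        if spec.kind == "signal":
            out[spec.name] = _signal_matrix(
                spec, probes[spec.name], truth, columns, col_fraction, rng
            )
        else:
            out[spec.name] = _count_matrix(
                spec, annotation, design, truth, columns, col_fraction, rng
            )
    return out


def _signal_matrix(spec, probe_table, truth, columns, col_fraction, rng):
    probe_gene = (
        probe_table.drop_duplicates("probe_id").set_index("probe_id")["gene_id"]
    )
    c = truth.compression[spec.name]
    sigma = truth.noise_scale[spec.name]
    bg = truth.background[spec.name]
    gain = truth.gain[spec.name]
    features = list(probe_gene.index) + [f"{spec.name}:NC{i + 1}" for i in range(spec.n_controls)]
    n_probes, n_ctrl = len(probe_gene), spec.n_controls

    data = {}
    pvals = {}
    for col in columns:
        ab = truth.abundance(col_fraction[col]).loc[probe_gene.to_numpy()].to_numpy()
        mu = gain * np.power(ab, c, where=ab > 0, out=np.zeros_like(ab))
        noise = np.exp(sigma * rng.standard_normal(n_probes)) if sigma > 0 else 1.0
        sig = bg + mu * noise
        ctrl_noise = (
            np.exp(sigma * rng.standard_normal(n_ctrl)) if sigma > 0 else np.ones(n_ctrl)
        )
        ctrl = bg * ctrl_noise
        vals = np.concatenate([sig, ctrl])
        data[col] = vals
        # detection p-value: survival of the signal under a log-normal
        # pure-background null (sigma floored so noise-free runs still
        # yield a graded p)
        sigma_eff = max(sigma, 0.1)
        if bg > 0:
            z = np.log(np.clip(vals, 1e-12, None) / bg) / sigma_eff
            pvals[col] = stats.norm.sf(z)
        else:
            pvals[col] = np.where(vals > 0, 0.0, 1.0)

    idx = pd.Index(features, name="feature_id")
    is_control = pd.Series([False] * n_probes + [True] * n_ctrl, index=idx)
    feature_gene = pd.Series(
        list(probe_gene.to_numpy()) + [""] * n_ctrl, index=idx
    )
    return ExpressionMatrix(
        data=pd.DataFrame(data, index=idx),
        kind="signal",
        platform=spec.name,
        detection_p=pd.DataFrame(pvals, index=idx),
        is_control=is_control,
        feature_gene=feature_gene,
    )


def _count_matrix(spec, annotation, design, truth, columns, col_fraction, rng):
    ex = _exon_weights(annotation)
    c = truth.compression[spec.name]
    lib = truth.library_size[spec.name]
    sigma = truth.noise_scale[spec.name]
    alpha = truth.dispersion[spec.name]
    noise_gene = pd.Series(truth.noise_gene, index=truth.genes)
    noise_gene_rows = {
        g: np.flatnonzero((ex["gene_id"] == g).to_numpy())
        for g in noise_gene.index[noise_gene]
    }
    mixture_fracs = {design.bmo_fraction[s] for s in design.mixtures}
    scale = _count_scale(ex, truth, spec.name)

    data = {}
    for col in columns:
        ab = truth.abundance(col_fraction[col]) ** c
        intensity = ab.loc[ex["gene_id"]].to_numpy() * ex["length"].to_numpy()
        mu = lib * intensity * scale
        if sigma > 0:
            if alpha > 0:
                nsize = 1.0 / alpha
                p = nsize / (nsize + mu)
                counts = rng.negative_binomial(nsize, p).astype(float)
            else:
                counts = rng.poisson(mu).astype(float)
        else:
            counts = mu
        if col_fraction[col] in mixture_fracs and truth.noise_count_rate > 0:
            # low-count noise lands on one exon per gene so gene-level
            # totals stay in the intended 1-12 range
            for rows_g in noise_gene_rows.values():
                if rng.random() < truth.noise_count_rate:
                    counts[rows_g[rng.integers(0, len(rows_g))]] += rng.integers(1, 13)
        data[col] = counts

    idx = pd.Index(ex["exon_id"], name="feature_id")
    return ExpressionMatrix(
        data=pd.DataFrame(data, index=idx),
        kind="count",
        platform=spec.name,
        feature_gene=pd.Series(ex["gene_id"].to_numpy(), index=idx),
    )


# ---------------------------------------------------------------------------
# hand-built multi-isoform demonstration gene


def pattern_demo():
    """A five-transcript gene whose exon geometry plants known patterns.

    Six exon slots with designed transcript membership:

    ========  ==========================  =====================
    exon      transcripts                 planted pattern
    ========  ==========================  =====================
    E1, E6    all five                    (full set)
    E2        T001, T003, T004, T005      targeted on 1 platform
    E3        T002, T003                  common to all 4
    E4        T001, T002                  targeted on 1 platform
    E5        T004, T005                  common to all 4
    ========  ==========================  =====================

    Four array platforms each carry probes for E3 and E5 plus one
    platform-specific exon, so exactly the {T002, T003} and {T004, T005}
    patterns are common across all platforms — two retained patterns for a
    single gene.

    Returns ``(annotation, probes_by_platform, expected_patterns)`` where
    ``expected_patterns`` is the set of frozensets of transcript ids.
    """
    gene_id = "DEMO1"
    chrom, strand = "chr1", "+"
    ann = GenomeAnnotation()
    gene = Gene(gene_id, chrom, strand)
    for i in range(1, 7):
        ann.add_exon(Exon(f"{gene_id}.E{i}", chrom, 1000 * i, 1000 * i + 200, strand, gene_id))
    membership = {
        "E1": [1, 2, 3, 4, 5],
        "E2": [1, 3, 4, 5],
        "E3": [2, 3],
        "E4": [1, 2],
        "E5": [4, 5],
        "E6": [1, 2, 3, 4, 5],
    }
    tx_exons: dict[str, list[str]] = {f"{gene_id}.T{t:03d}": [] for t in range(1, 6)}
    for e, txs in membership.items():
        for t in txs:
            tx_exons[f"{gene_id}.T{t:03d}"].append(f"{gene_id}.{e}")
    for tx, exons in tx_exons.items():
        gene.transcripts[tx] = tuple(
            sorted(exons, key=lambda eid: ann.exons[eid].start)
        )
    ann.add_gene(gene)
    ann.validate()

    placements = {
        "P1": ["E2", "E3", "E5"],
        "P2": ["E3", "E5", "E6"],
        "P3": ["E3", "E4", "E5"],
        "P4": ["E1", "E3", "E5"],
    }
    probes = {}
    for platform, exons in placements.items():
        rows = []
        for pi, e in enumerate(exons):
            ex = ann.exons[f"{gene_id}.{e}"]
            rows.append([
                f"{platform}:{gene_id}:p{pi + 1}", platform, ex.chrom,
                ex.start + 50, ex.start + 100, gene_id, "unique_full",
            ])
        probes[platform] = pd.DataFrame(rows, columns=PROBE_COLUMNS)

    t = lambda *ids: frozenset(f"{gene_id}.T{i:03d}" for i in ids)
    expected = {t(2, 3), t(4, 5)}
    return ann, probes, expected
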