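"""Probe-to-transcript mapping and cross-platform transcript patterns.

A *transcript pattern* is a gene together with the exact set of its
transcripts jointly measured by a feature.  When features on every compared
platform target the same transcript set, that set defines a comparison
point that is immune to isoform-mixture confounding — platforms are then
quantifying the same RNA species, not merely the same gene symbol.  A gene
may contribute several patterns (different exon regions select different
transcript subsets), and patterns within a gene are kept distinct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GenomeAnnotation

__all__ = [
    "ProbeTarget",
    "TranscriptPattern",
    "filter_ambiguous_probes",
    "assign_transcript_sets",
    "derive_transcript_patterns",
    "map_exons_to_patterns",
    "align_genes_across_platforms",
    "patterns_to_tsv",
    "pattern_regions_bed",
]

log = logging.getLogger(__name__)


class ProbeTarget(NamedTuple):
    gene_id: str
    transcripts: frozenset[str]


@dataclass(frozen=True)
class TranscriptPattern:
    """A gene plus the exact transcript set shared by features per platform."""

    pattern_id: str
    gene_id: str
    transcripts: tuple[str, ...]  # sorted
    members: dict[str, tuple[str, ...]]  # platform -> feature ids

    @property
    def transcript_set(self) -> frozenset[str]:
        return frozenset(self.transcripts)


def filter_ambiguous_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Keep only probes whose genome alignment is unique and full-length.

    Probes classed ``multiple`` (several genomic hits) or ``partial``
    (incomplete alignment) are omitted; removal counts per class are
    logged.  Empty input yields empty output.
    """
    if probes.empty:
        return probes.copy()
    per_probe = probes.groupby("probe_id", sort=False)["align_class"].first()
    removed = per_probe[per_probe != "unique_full"].value_counts()
    for cls, n in removed.items():
        log.info("filtered %d probes with %s alignment", n, cls)
    keep = probes["align_class"] == "unique_full"
    return probes.loc[keep].copy()


def _transcript_unions(annotation: GenomeAnnotation) -> dict[str, list[tuple[int, int]]]:
    unions = {}
    for gene_id, gene in annotation.genes.items():
        for tx_id in gene.transcripts:
            unions[tx_id] = annotation.transcript_exon_union(gene_id, tx_id)
    return unions


def _contained(start: int, end: int, union: list[tuple[int, int]]) -> bool:
    return any(s <= start and end <= e for s, e in union)


def assign_transcript_sets(
    probes: pd.DataFrame, annotation: GenomeAnnotation
) -> dict[str, ProbeTarget]:
    """Map each retained probe to the transcripts that fully contain it.

    A transcript is targeted iff *every* interval of the probe lies fully
    inside that transcript's exon union (containment, not overlap — a
    partially overlapping probe reports mixed exon/intron signal).  Probes
    targeting no transcript, or transcripts of more than one gene, are
    dropped.
    """
    chroms = annotation.chromosomes()
    missing = set(probes["chrom"]) - chroms
    if missing:
        raise ValueError(f"annotation lacks chromosomes referenced by probes: {sorted(missing)}")

    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}
    for exon in annotation.exons.values():
        trees[exon.chrom].addi(exon.start, exon.end, exon.exon_id)
    unions = _transcript_unions(annotation)

    out: dict[str, ProbeTarget] = {}
    n_empty = n_multigene = 0
    for probe_id, group in probes.groupby("probe_id", sort=False):
        intervals = list(zip(group["chrom"], group["start"], group["end"]))
        # candidate transcripts: those owning an exon overlapping interval 0
        per_interval_sets = []
        for chrom, start, end in intervals:
            hits = trees[chrom].overlap(start, end)
            candidates = set()
            for h in hits:
                exon = annotation.exons[h.data]
                gene = annotation.genes[exon.gene_id]
                for tx_id, exon_ids in gene.transcripts.items():
                    if exon.exon_id in exon_ids and _contained(start, end, unions[tx_id]):
                        candidates.add((exon.gene_id, tx_id))
            per_interval_sets.append(candidates)
        common = set.intersection(*per_interval_sets) if per_interval_sets else set()
        if not common:
            n_empty += 1
            continue
        genes = {g for g, _ in common}
        if len(genes) > 1:
            n_multigene += 1
            continue
        (gene_id,) = genes
        out[probe_id] = ProbeTarget(gene_id, frozenset(t for _, t in common))
    if n_empty:
        log.info("dropped %d probes contained in no transcript", n_empty)
    if n_multigene:
        log.info("dropped %d probes spanning multiple genes", n_multigene)
    return out


def derive_transcript_patterns(
    per_platform_maps: dict[str, dict[str, ProbeTarget]],
    required_platforms: list[str] | None = None,
) -> list[TranscriptPattern]:
    """Transcript sets targeted by at least one feature on *every* platform.

    Pattern identity is exact set equality: two features agree only if they
    measure exactly the same transcripts.  A gene may yield several
    patterns, each kept as a separate data point.  Output is sorted by gene
    then pattern id.
    """
    required = list(required_platforms or per_platform_maps.keys())
    if len(required) < 2:
        raise ValueError("at least 2 platforms are required to derive common patterns")
    for p in required:
        if p not in per_platform_maps:
            raise ValueError(f"required platform {p!r} missing from input maps")

    # (gene, transcript set) -> platform -> member feature ids
    members: dict[tuple[str, frozenset], dict[str, list[str]]] = {}
    for platform in required:
        for feature_id, target in per_platform_maps[platform].items():
            key = (target.gene_id, target.transcripts)
            members.setdefault(key, {}).setdefault(platform, []).append(feature_id)

    patterns = []
    per_gene_sets: dict[str, list[frozenset]] = {}
    for (gene_id, tx_set), by_platform in members.items():
        if all(by_platform.get(p) for p in required):
            per_gene_sets.setdefault(gene_id, []).append(tx_set)
    for gene_id in sorted(per_gene_sets):
        for i, tx_set in enumerate(
            sorted(per_gene_sets[gene_id], key=lambda s: tuple(sorted(s)))
        ):
            by_platform = members[(gene_id, tx_set)]
            patterns.append(
                TranscriptPattern(
                    pattern_id=f"{gene_id}|PT{i + 1}",
                    gene_id=gene_id,
                    transcripts=tuple(sorted(tx_set)),
                    members={p: tuple(sorted(by_platform[p])) for p in required},
                )
            )
    return patterns


def map_exons_to_patterns(
    annotation: GenomeAnnotation, patterns: list[TranscriptPattern]
) -> dict[str, str]:
    """Exon id -> pattern id where the exon's transcript membership equals
    the pattern's transcript set exactly; other exons stay unmapped."""
    by_key = {(p.gene_id, p.transcript_set): p.pattern_id for p in patterns}
    out = {}
    for exon_id in annotation.exons:
        gene_id = annotation.exons[exon_id].gene_id
        txs = annotation.transcripts_containing_exon(exon_id)
        pid = by_key.get((gene_id, txs))
        if pid is not None:
            out[exon_id] = pid
    return out


def align_genes_across_platforms(per_platform_gene_lists: dict[str, list[str]]) -> set[str]:
    """Exact intersection of the per-platform gene id lists."""
    sets = [set(v) for v in per_platform_gene_lists.values()]
    return set.intersection(*sets) if sets else set()


def patterns_to_tsv(patterns: list[TranscriptPattern], path) -> None:
    rows = []
    for p in patterns:
        for platform, feats in p.members.items():
            for f in feats:
                rows.append([p.pattern_id, p.gene_id, ";".join(p.transcripts), platform, f])
    pd.DataFrame(
        rows, columns=["pattern_id", "gene_id", "transcript_ids", "platform", "feature_id"]
    ).to_csv(path, sep="\t", index=False)


def pattern_regions_bed(
    annotation: GenomeAnnotation, patterns: list[TranscriptPattern], path
) -> None:
    """BED of exons that select each pattern (the pattern's select region)."""
    exon_map = map_exons_to_patterns(annotation, patterns)
    with open(path, "w") as fh:
        for exon_id in sorted(exon_map):
            ex = annotation.exons[exon_id]
            fh.write(f"{ex.chrom}\t{ex.start}\t{ex.end}\t{exon_map[exon_id]}\t0\t{ex.strand}\n")
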