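"""Minimal gene/transcript/exon annotation model with GTF round-trip.

Coordinates are 0-based half-open (BED convention) in memory; GTF output
converts to the 1-based inclusive convention.  Exons are gene-level units:
two transcripts sharing an exonic region reference the same exon id, which
is what makes "the set of transcripts containing this exon" well defined —
the construct that transcript-pattern analysis is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Exon", "Gene", "GenomeAnnotation", "generate_annotation"]


@dataclass(frozen=True)
class Exon:
    exon_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"exon {self.exon_id} has non-positive length")


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    #: transcript id -> tuple of exon ids, sorted by genomic start
    transcripts: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class GenomeAnnotation:
    """Genes, their transcripts, and shared exon intervals."""

    genes: dict[str, Gene] = field(default_factory=dict)
    exons: dict[str, Exon] = field(default_factory=dict)

    def add_gene(self, gene: Gene) -> None:
        self.genes[gene.gene_id] = gene

    def add_exon(self, exon: Exon) -> None:
        self.exons[exon.exon_id] = exon

    def validate(self) -> None:
        """Check transcript exons are sorted, non-overlapping, single-gene."""
        for gene in self.genes.values():
            for tx_id, exon_ids in gene.transcripts.items():
                ivs = [(self.exons[e].start, self.exons[e].end) for e in exon_ids]
                for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                    if s2 < e1:
                        raise ValueError(
                            f"transcript {tx_id}: exons overlap or are unsorted"
                        )
                for e in exon_ids:
                    if self.exons[e].gene_id != gene.gene_id:
                        raise ValueError(f"exon {e} assigned to two genes")

    # -- queries ---------------------------------------------------------

    def transcript_exon_union(self, gene_id: str, tx_id: str) -> list[tuple[int, int]]:
        """Merged, sorted exonic intervals of one transcript."""
        gene = self.genes[gene_id]
        ivs = sorted(
            (self.exons[e].start, self.exons[e].end) for e in gene.transcripts[tx_id]
        )
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def transcripts_containing_exon(self, exon_id: str) -> frozenset[str]:
        gene = self.genes[self.exons[exon_id].gene_id]
        return frozenset(
            tx for tx, exon_ids in gene.transcripts.items() if exon_id in exon_ids
        )

    def chromosomes(self) -> set[str]:
        return {e.chrom for e in self.exons.values()}

    # -- GTF I/O ---------------------------------------------------------

    def to_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self.genes.values(), key=lambda g: g.gene_id):
                exon_ids = {e for tx in gene.transcripts.values() for e in tx}
                if not exon_ids:
                    continue
                g_start = min(self.exons[e].start for e in exon_ids)
                g_end = max(self.exons[e].end for e in exon_ids)
                fh.write(
                    _gtf_line(gene.chrom, "gene", g_start, g_end, gene.strand,
                              f'gene_id "{gene.gene_id}";')
                )
                for tx_id in sorted(gene.transcripts):
                    t_ex = gene.transcripts[tx_id]
                    t_start = min(self.exons[e].start for e in t_ex)
                    t_end = max(self.exons[e].end for e in t_ex)
                    fh.write(
                        _gtf_line(gene.chrom, "transcript", t_start, t_end,
                                  gene.strand,
                                  f'gene_id "{gene.gene_id}"; '
                                  f'transcript_id "{tx_id}";')
                    )
                    for e in t_ex:
                        ex = self.exons[e]
                        fh.write(
                            _gtf_line(ex.chrom, "exon", ex.start, ex.end, ex.strand,
                                      f'gene_id "{gene.gene_id}"; '
                                      f'transcript_id "{tx_id}"; '
                                      f'exon_id "{ex.exon_id}";')
                        )

    @classmethod
    def from_gtf(cls, path) -> "GenomeAnnotation":
        ann = cls()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != "exon":
                    continue
                chrom, _, _, start1, end1, _, strand, _, attrs = parts[:9]
                a = _parse_attrs(attrs)
                gene_id, tx_id, exon_id = a["gene_id"], a["transcript_id"], a["exon_id"]
                start, end = int(start1) - 1, int(end1)
                if gene_id not in ann.genes:
                    ann.add_gene(Gene(gene_id, chrom, strand))
                if exon_id not in ann.exons:
                    ann.add_exon(Exon(exon_id, chrom, start, end, strand, gene_id))
                gene = ann.genes[gene_id]
                gene.transcripts.setdefault(tx_id, ())
                gene.transcripts[tx_id] = gene.transcripts[tx_id] + (exon_id,)
        # restore genomic order within transcripts
        for gene in ann.genes.values():
            for tx_id, exon_ids in gene.transcripts.items():
                gene.transcripts[tx_id] = tuple(
                    sorted(set(exon_ids), key=lambda e: ann.exons[e].start)
                )
        return ann


def _gtf_line(chrom, feature, start0, end0, strand, attrs) -> str:
    return (
        f"{chrom}\ttitrabench\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"
    )


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def generate_annotation(
    n_genes: int,
    transcripts_per_gene: tuple[int, int] = (2, 5),
    exons_per_transcript: tuple[int, int] = (2, 6),
    exon_length: tuple[int, int] = (120, 320),
    intron_length: tuple[int, int] = (200, 1200),
    n_chromosomes: int = 3,
    seed: int = 0,
) -> GenomeAnnotation:
    """Simulate a multi-isoform annotation with shared exon slots.

    Each gene lays down a pool of non-overlapping exon "slots"; every
    transcript takes a random sorted subset that always includes the first
    and last slot (so isoforms differ internally, giving probe-targetable
    regions that distinguish transcript subsets).  Deterministic for a
    fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    for lo, hi, what in (
        (*transcripts_per_gene, "transcripts_per_gene"),
        (*exons_per_transcript, "exons_per_transcript"),
        (*exon_length, "exon_length"),
        (*intron_length, "intron_length"),
    ):
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid range for {what}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    ann = GenomeAnnotation()
    cursors = {f"chr{i + 1}": 1000 for i in range(n_chromosomes)}

    for gi in range(n_genes):
        gene_id = f"G{gi + 1:05d}"
        chrom = f"chr{gi % n_chromosomes + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(transcripts_per_gene[0], transcripts_per_gene[1] + 1))
        max_ex = int(rng.integers(exons_per_transcript[0], exons_per_transcript[1] + 1))
        n_slots = max(max_ex, 2) + int(rng.integers(0, 3))

        pos = cursors[chrom]
        slots = []
        for si in range(n_slots):
            length = int(rng.integers(exon_length[0], exon_length[1] + 1))
            slots.append((pos, pos + length))
            pos += length + int(rng.integers(intron_length[0], intron_length[1] + 1))
        cursors[chrom] = pos + 5000

        gene = Gene(gene_id, chrom, strand)
        for si, (s, e) in enumerate(slots):
            ann.add_exon(Exon(f"{gene_id}.E{si + 1}", chrom, s, e, strand, gene_id))

        for ti in range(n_tx):
            k = int(rng.integers(exons_per_transcript[0], min(max_ex, n_slots) + 1))
            k = max(k, 2) if n_slots >= 2 else 1
            inner = rng.permutation(n_slots - 2)[: max(k - 2, 0)] + 1
            chosen = sorted({0, n_slots - 1, *inner.tolist()})
            gene.transcripts[f"{gene_id}.T{ti + 1:03d}"] = tuple(
                f"{gene_id}.E{si + 1}" for si in chosen
            )
        ann.add_gene(gene)

    used = {e for g in ann.genes.values() for tx in g.transcripts.values() for e in tx}
    ann.exons = {e: ex for e, ex in ann.exons.items() if e in used}
    ann.validate()
    return ann
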