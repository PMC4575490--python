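"""End-to-end orchestration of the cross-platform benchmark.

Stages: simulate -> map patterns -> preprocess -> signal metrics ->
fold-change metrics -> (optional) qPCR concordance.  Each stage logs its
inputs and feature counts; the run emits a machine-readable JSON summary
plus TSV tables, and is fully determined by the config's seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import foldchange as fcm
from . import signal_metrics as sm
from .design import TitrationDesign, canonical_design
from .matrix import ExpressionMatrix
from .patterns import (
    ProbeTarget,
    align_genes_across_platforms,
    assign_transcript_sets,
    derive_transcript_patterns,
    filter_ambiguous_probes,
    patterns_to_tsv,
)
from .preprocess import (
    collapse_replicates,
    cpm_normalize,
    detection_calls,
    quantile_normalize,
    summarize_to_level,
)
from .simulate import (
    PlatformSpec,
    generate_expression,
    generate_platform_probes,
    make_truth,
    write_probes_bed,
)
from .annotation import generate_annotation

log = logging.getLogger(__name__)

DEFAULT_PLATFORMS = [
    # four array-like platforms with platform-specific compression/noise,
    # two sequencing-like protocols — the study's 4 + 2 layout
    {"name": "arrayA", "kind": "signal", "placement": "three_prime"},
    {"name": "arrayB", "kind": "signal", "placement": "whole_transcript"},
    {"name": "arrayC", "kind": "signal", "placement": "whole_transcript"},
    {"name": "arrayD", "kind": "signal", "placement": "three_prime"},
    {"name": "seqA", "kind": "count"},
    {"name": "seqB", "kind": "count"},
]

DEFAULT_COMPRESSION = {
    "arrayA": 1.0, "arrayB": 0.6, "arrayC": 0.5, "arrayD": 0.7,
    "seqA": 1.0, "seqB": 0.9,
}


@dataclass
class RunConfig:
    """Everything one benchmark run needs; defaults mirror the study design."""

    seed: int = 0
    n_genes: int = 300
    noise_gene_fraction: float = 0.05
    replicates: int = 2
    platforms: list[dict] = field(default_factory=lambda: [dict(d) for d in DEFAULT_PLATFORMS])
    compression: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPRESSION))
    noise_scale: dict[str, float] = field(default_factory=dict)
    cpm_threshold: float = 0.25
    p_threshold: float = 0.05
    fidelity_threshold: float = 0.5
    pseudocount: float = 1.0
    reference_platform: str = "arrayA"
    subset: str = "patterns"  # entire | common_genes | patterns
    ct_table: str | None = None
    housekeeping: str = ""

    def __post_init__(self) -> None:
        names = [p["name"] for p in self.platforms]
        if self.reference_platform not in names:
            raise ValueError(f"reference platform {self.reference_platform!r} not in platforms")
        if self.subset not in ("entire", "common_genes", "patterns"):
            raise ValueError(f"unknown subset level {self.subset!r}")
        for thr in (self.cpm_threshold, self.p_threshold, self.fidelity_threshold):
            if thr <= 0:
                raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and write the report bundle to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # -- simulate --------------------------------------------------------
    specs = [PlatformSpec(**p) for p in config.platforms]
    design = canonical_design({s.name: config.replicates for s in specs})
    annotation = generate_annotation(config.n_genes, seed=config.seed)
    truth = make_truth(
        annotation, specs, seed=config.seed,
        noise_gene_fraction=config.noise_gene_fraction,
        compression=config.compression, noise_scale=config.noise_scale or None,
    )
    probes = {
        s.name: generate_platform_probes(annotation, s, seed=config.seed)
        for s in specs if s.kind == "signal"
    }
    matrices = generate_expression(annotation, probes, design, truth, specs)
    annotation.to_gtf(out / "annotation.gtf")
    truth.to_yaml(out / "truth.yaml")
    design.to_yaml(out / "design.yaml")
    for name, ptab in probes.items():
        write_probes_bed(ptab, out / f"probes_{name}.bed")
    for name, m in matrices.items():
        m.to_tsv(out / f"raw_{name}.tsv")
    report["stages"]["simulate"] = {
        "n_genes": config.n_genes,
        "platforms": [s.name for s in specs],
        "features": {n: int(len(m.features)) for n, m in matrices.items()},
    }

    # -- patterns --------------------------------------------------------
    per_platform_maps = {}
    for name, ptab in probes.items():
        retained = filter_ambiguous_probes(ptab)
        per_platform_maps[name] = assign_transcript_sets(retained, annotation)
    # sequencing features are exons: their transcript set is direct membership
    for s in specs:
        if s.kind == "count":
            per_platform_maps[s.name] = {
                exon_id: ProbeTarget(
                    annotation.exons[exon_id].gene_id,
                    annotation.transcripts_containing_exon(exon_id),
                )
                for exon_id in annotation.exons
            }
    patterns = derive_transcript_patterns(per_platform_maps, [s.name for s in specs])
    patterns_to_tsv(patterns, out / "patterns.tsv")
    report["stages"]["patterns"] = {"n_patterns": len(patterns)}

    # -- preprocess ------------------------------------------------------
    normalized: dict[str, ExpressionMatrix] = {}
    detected: dict[str, pd.Series] = {}
    for s in specs:
        m = matrices[s.name]
        if s.kind == "signal":
            norm = quantile_normalize(m.non_control())
            det = detection_calls(
                m.non_control(), p_threshold=s.detection_p_threshold,
                grouping=m.non_control().feature_gene,
            )
        else:
            norm = cpm_normalize(m, pseudocount=config.pseudocount)
            det = detection_calls(
                norm, cpm_threshold=config.cpm_threshold, grouping=m.feature_gene,
            )
        normalized[s.name] = norm
        detected[s.name] = det

    gene_level = {
        name: summarize_to_level(norm, _gene_grouping(matrices[name], norm))
        for name, norm in normalized.items()
    }
    collapsed = {
        name: collapse_replicates(g, design) for name, g in gene_level.items()
    }

    # -- signal metrics --------------------------------------------------
    metrics: dict[str, dict] = {}
    for s in specs:
        raw = matrices[s.name]
        rng_summary = sm.signal_range_summary(
            raw, [c for c in raw.data.columns
                  if c.split("_rep")[0] in (design.pure_a, design.pure_b)]
        )
        rng_summary.table.to_csv(out / f"signal_range_{s.name}.tsv", sep="\t")
        if s.kind == "signal":
            bg = sm.array_background(raw)
        else:
            bg = sm.quasi_background(raw, design, grouping=raw.feature_gene)
        s2b = sm.signal_to_background(raw, bg, design) if bg > 0 else float("nan")
        fid = sm.titration_fidelity(raw.non_control(), design, config.fidelity_threshold)
        metrics[s.name] = {
            "background": bg,
            "signal_to_background": s2b,
            "fidelity_fraction": fid.fraction_above,
        }
    common_genes = align_genes_across_platforms(
        {name: list(g.data.index) for name, g in collapsed.items()}
    )
    similarity = {}
    for sample in (design.pure_a, design.pure_b):
        mat = sm.cross_platform_similarity(
            {name: g.data[sample] for name, g in collapsed.items()}, sample
        )
        mat.to_csv(out / f"similarity_{sample}.tsv", sep="\t")
        similarity[sample] = mat.to_dict()
    report["stages"]["signal_metrics"] = metrics
    report["stages"]["common_genes"] = {"n": len(common_genes)}

    # -- fold-change metrics ---------------------------------------------
    subset_genes = None
    if config.subset == "common_genes":
        subset_genes = common_genes
    elif config.subset == "patterns":
        subset_genes = {p.gene_id for p in patterns} & common_genes
    fc_report = {}
    log2_ratios = {}
    for s in specs:
        table = fcm.build_fold_change_table(
            collapsed[s.name], design, gene_subset=subset_genes,
            detected=None,
        )
        table.to_tsv(out / f"foldchange_{s.name}.tsv")
        per_contrast, overall = fcm.average_abs_fc(table)
        _, frac = fcm.fc_titration_fidelity(table, config.fidelity_threshold)
        log2_ratios[s.name] = table.log2_ratio[design.pure_b]
        fc_report[s.name] = {
            "per_contrast_mean_abs_fc": {k: float(v) for k, v in per_contrast.items()},
            "overall_mean_abs_fc": overall,
            "fc_fidelity_fraction": frac,
        }
    ref = log2_ratios[config.reference_platform]
    for s in specs:
        if s.name == config.reference_platform:
            continue
        common = ref.index.intersection(log2_ratios[s.name].index)
        fit = fcm.fc_compression(ref.loc[common], log2_ratios[s.name].loc[common])
        fc_report[s.name]["compression_vs_reference"] = fit
    report["stages"]["foldchange"] = fc_report

    # -- concordance (optional) ------------------------------------------
    if config.ct_table:
        table = conc.qc_ct(pd.read_csv(config.ct_table, sep="\t"), config.housekeeping)
        fold = conc.delta_delta_ct(table, design.pure_a)
        rates = {}
        for s in specs:
            calls = []
            plat = collapsed[s.name]
            genes = fold.index.intersection(plat.data.index)
            for g in genes:
                x = conc.signed_fold_change(float(fold.loc[g, design.pure_b]))
                lr = float(np.log2(
                    np.exp2(plat.data.loc[g, design.pure_b])
                    / np.exp2(plat.data.loc[g, design.pure_a])
                )) if plat.kind == "log2" else float(np.log2(
                    max(plat.data.loc[g, design.pure_b], 1e-6)
                    / max(plat.data.loc[g, design.pure_a], 1e-6)
                ))
                y = conc.signed_fold_change(float(2.0**lr))
                calls.append(conc.ConcordanceCall(g, x, y))
            if calls:
                rates[s.name] = conc.concordance_rate(calls)
        report["stages"]["concordance"] = rates

    # -- accounting & summary --------------------------------------------
    accounting = feature_accounting(matrices, detected, patterns)
    accounting.to_csv(out / "accounting.tsv", sep="\t", index=False)
    report["accounting"] = accounting.to_dict(orient="records")
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _gene_grouping(raw: ExpressionMatrix, norm: ExpressionMatrix) -> pd.Series:
    fg = raw.feature_gene
    fg = fg[fg.index.isin(norm.data.index) & (fg != "")]
    return fg


def feature_accounting(
    matrices: dict[str, ExpressionMatrix],
    detected: dict[str, pd.Series],
    patterns,
) -> pd.DataFrame:
    """Per-platform feature/gene counts, mirroring the study's accounting."""
    pattern_members = {
        name: sum(len(p.members.get(name, ())) for p in patterns)
        for name in matrices
    }
    rows = []
    for name, m in matrices.items():
        genes = m.feature_gene[m.feature_gene != ""] if m.feature_gene is not None else pd.Series(dtype=str)
        det = detected.get(name)
        rows.append({
            "platform": name,
            "total_features": len(m.features),
            "non_control_features": int((~m.is_control).sum()),
            "gene_level_entities": int(genes.nunique()),
            "detected_entities": int(det.sum()) if det is not None else 0,
            "pattern_member_features": pattern_members.get(name, 0),
        })
    return pd.DataFrame(rows)
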