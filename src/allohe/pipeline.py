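"""End-to-end orchestration: run the three evidence tracks and the LTR
dating on a synthetic universe (in memory) or on files, and score the HE
calls against planted truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .integrate import (EvidenceMatrix, HERegion, call_he, export_tracks,
                        precision_recall, regions_to_frame)
from .layout import CoverageTrack, make_windows
from .ltr import (DEFAULT_MU, GENERATION_YEARS_RANGE, LTRMatch, age_sweep_mya,
                  date_elements, match_shared_ltrs, parse_pass_list,
                  write_pass_list, youngest_shared_generations)
from .partition import (KmerIndex, ReadClass, class_counts, classify_fragments,
                        exact_map, genomic_evidence)
from .proteins import iaa_evidence, quantile70_confirm
from .rna import pooled_coverage, rna_evidence
from .sequences import Genome

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline-wide parameters; defaults carry the published constants.

    Window sizes: 100 kb for the genomic track, 250 kb for the RNA and
    protein tracks, 1 Mb for the identity-quantile confirmation. Clock:
    µ = 7.7e-9 substitutions/site/generation, generation time swept over
    10-60 years.
    """

    seed: int = 0
    window_genomic: int = 100_000
    window_rna: int = 250_000
    window_iaa: int = 250_000
    window_confirm: int = 1_000_000
    mu: float = DEFAULT_MU
    generation_years: tuple[float, float] = GENERATION_YEARS_RANGE
    harmonize_policy: str = "any"
    tie_epsilon: float = 0.0
    identity_tolerance: float = 1e-4
    mapper_k: int = 31
    max_insert: int = 2_000
    min_reciprocal_overlap: float = 0.5
    sim: sim.SimConfig | None = None


@dataclass
class LTRReport:
    """Shared-element matches and youngest insertion ages per genome pair."""

    dated: pd.DataFrame
    matches: dict[tuple[str, str], list[LTRMatch]]
    youngest: dict[tuple[str, str], float]

    def youngest_frame(self) -> pd.DataFrame:
        rows = []
        for (g1, g2), T in sorted(self.youngest.items()):
            lo, hi = age_sweep_mya(T) if np.isfinite(T) else (np.nan, np.nan)
            rows.append({
                "genome_1": g1, "genome_2": g2,
                "n_shared": len(self.matches[(g1, g2)]),
                "youngest_generations": round(T, 1) if np.isfinite(T) else np.nan,
                "age_min_mya": round(lo, 3) if np.isfinite(T) else np.nan,
                "age_max_mya": round(hi, 3) if np.isfinite(T) else np.nan,
            })
        return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    config: RunConfig
    truth: sim.SimTruth
    read_classes: dict[str, int]
    evidence: EvidenceMatrix
    regions: list[HERegion]
    metrics: dict[str, float]
    ltr_report: LTRReport
    timings: dict[str, float] = field(default_factory=dict)


def _chrom_pairs_for(g1: str, g2: str, n_chrom: int) -> list[tuple[str, str]]:
    """Homoeologous chromosome pairing between any two of the four
    (sub)genome element sets; hybrid chromosomes carry _a/_f suffixes."""
    def name(g, i):
        # hybrid element sets live on subgenome-suffixed chromosomes
        if g == "hybrid_a":
            return f"chr{i}_a"
        if g == "hybrid_f":
            return f"chr{i}_f"
        return f"chr{i}"

    return [(name(g1, i), name(g2, i)) for i in range(1, n_chrom + 1)]


LTR_GENOME_PAIRS = [
    ("hybrid_a", sim.ANCESTOR_A_ID),
    ("hybrid_f", sim.ANCESTOR_F_ID),
    (sim.ANCESTOR_A_ID, sim.ANCESTOR_F_ID),
    ("hybrid_a", "hybrid_f"),
    (sim.ANCESTOR_A_ID, "hybrid_f"),
    (sim.ANCESTOR_F_ID, "hybrid_a"),
]


def ltr_analysis(
    elements: dict[str, list],
    config: RunConfig,
    n_chrom: int,
    genome_pairs: list[tuple[str, str]] = LTR_GENOME_PAIRS,
) -> LTRReport:
    """Date every element and match shared ones per genome pair."""
    dated = pd.concat(
        [date_elements(els, config.mu, config.generation_years)
         for els in elements.values()],
        ignore_index=True,
    ) if elements else pd.DataFrame()
    matches: dict[tuple[str, str], list[LTRMatch]] = {}
    youngest: dict[tuple[str, str], float] = {}
    for g1, g2 in genome_pairs:
        m = match_shared_ltrs(
            elements.get(g1, []), elements.get(g2, []),
            identity_tolerance=config.identity_tolerance,
            enforce_order=True,
            chromosome_pairs=_chrom_pairs_for(g1, g2, n_chrom),
        )
        matches[(g1, g2)] = m
        youngest[(g1, g2)] = youngest_shared_generations(m, config.mu)
    return LTRReport(dated=dated, matches=matches, youngest=youngest)


def run_synthetic(config: RunConfig | None = None, outdir: str | Path | None = None
                  ) -> PipelineResult:
    """Full HE + LTR analysis on a freshly generated synthetic universe.

    Stages: simulate -> map hybrid read pairs to both ancestors -> classify
    into the four origin classes -> re-map ancestor-unique sets onto the
    hybrid -> genomic / RNA / protein evidence -> intersect and call HE
    regions -> score against planted truth -> date and match LTRs.
    """
    config = config or RunConfig()
    scfg = config.sim or sim.default_config(config.seed)
    timings: dict[str, float] = {}

    def tic(stage):
        timings[stage] = time.perf_counter()

    def toc(stage):
        timings[stage] = time.perf_counter() - timings[stage]
        logger.info("%s: %.1f s", stage, timings[stage])

    tic("simulate")
    anc_a, anc_f = sim.simulate_ancestors(scfg)
    hybrid, truth = sim.simulate_hybrid(anc_a, anc_f, scfg)
    reads = sim.simulate_reads(hybrid, scfg)
    proteins, genes = sim.simulate_proteins(anc_a, anc_f, hybrid, scfg, truth)
    truth.gene_table = genes
    rna_tracks = sim.simulate_rna_tracks(hybrid, genes, scfg)
    ltr_elements, ltr_truth = sim.simulate_ltrs(scfg)
    truth.ltr_truth = ltr_truth
    toc("simulate")

    tic("map_ancestors")
    map_a = exact_map(reads, anc_a, k=config.mapper_k, max_insert=config.max_insert)
    map_f = exact_map(reads, anc_f, k=config.mapper_k, max_insert=config.max_insert)
    classes = classify_fragments(map_a, map_f)
    counts = class_counts(classes)
    toc("map_ancestors")

    tic("remap_hybrid")
    hybrid_index = KmerIndex(hybrid, config.mapper_k)
    remap_a = exact_map(reads.subset(classes == int(ReadClass.UNIQUE_A)),
                        hybrid_index, max_insert=config.max_insert)
    remap_f = exact_map(reads.subset(classes == int(ReadClass.UNIQUE_F)),
                        hybrid_index, max_insert=config.max_insert)
    genomic = genomic_evidence(remap_a, remap_f, hybrid.layout(),
                               config.window_genomic)
    toc("remap_hybrid")

    tic("rna_iaa")
    layout = hybrid.layout()
    grid = make_windows(layout, config.window_rna)
    hybrid_tracks = [
        CoverageTrack.from_intervals(name, grid, iv)
        for name, iv in rna_tracks.items() if name.startswith("hybrid_acc")
    ]
    cov_hybrid = pooled_coverage(hybrid_tracks, "hybrid_pooled")
    cov_a = CoverageTrack.from_intervals("ancestor_a_rna", grid,
                                         rna_tracks["ancestor_a_rna"])
    cov_f = CoverageTrack.from_intervals("ancestor_f_rna", grid,
                                         rna_tracks["ancestor_f_rna"])
    rna = rna_evidence(cov_hybrid, cov_a, cov_f)
    iaa = iaa_evidence(proteins, layout, config.window_iaa, config.tie_epsilon)
    confirm = quantile70_confirm(proteins, layout, config.window_confirm)
    toc("rna_iaa")

    tic("integrate")
    evidence = EvidenceMatrix.build(genomic, rna, iaa, confirm,
                                    config.harmonize_policy)
    regions = call_he(evidence)
    metrics = precision_recall(regions, truth.he_intervals,
                               config.min_reciprocal_overlap)
    ltr_report = ltr_analysis(ltr_elements, config, scfg.n_chromosomes)
    toc("integrate")

    result = PipelineResult(
        config=config, truth=truth, read_classes=counts, evidence=evidence,
        regions=regions, metrics=metrics, ltr_report=ltr_report,
        timings=timings,
    )
    if outdir is not None:
        write_run(result, outdir)
    return result


def write_run(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Persist a run: evidence TSVs, HE BED, LTR reports, truth, metrics
    and a manifest with parameter values and output checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = export_tracks(result.evidence, result.regions, outdir / "he")
    p = outdir / "he_regions.tsv"
    regions_to_frame(result.regions).to_csv(p, sep="\t", index=False)
    paths["regions_tsv"] = p
    p = outdir / "ltr_dated.tsv"
    result.ltr_report.dated.to_csv(p, sep="\t", index=False)
    paths["ltr_dated"] = p
    p = outdir / "ltr_youngest.tsv"
    result.ltr_report.youngest_frame().to_csv(p, sep="\t", index=False)
    paths["ltr_youngest"] = p
    p = outdir / "he_truth.bed"
    result.truth.he_bed(p)
    paths["truth"] = p
    p = outdir / "metrics.json"
    payload = {"metrics": result.metrics,
               "read_classes": result.read_classes}
    p.write_text(json.dumps(payload, indent=2))
    paths["metrics"] = p

    manifest = {
        "parameters": {
            **{k: v for k, v in asdict(result.config).items() if k != "sim"},
            "sim": asdict(result.config.sim) if result.config.sim else None,
        },
        "checksums": {
            key: hashlib.sha256(path.read_bytes()).hexdigest()
            for key, path in sorted(paths.items())
        },
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = mpath
    return paths
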