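"""Intersection of the three homoeologous-exchange evidence tracks at
250-kb resolution, merging of qualifying window runs into directed HE
regions, and review-ready track export.

The genomic track is computed on a finer 100-kb grid and is harmonised
onto the 250-kb grid by overlap ("any" flagged overlapping window by
default, configurable to "all"). The 1-Mb identity-quantile confirmation
is annotation on the calls, not a fourth AND-criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import GenomeLayout, WindowGrid, make_windows
from .partition import GenomicEvidence
from .proteins import IaaEvidence, QuantileConfirmation
from .rna import RnaEvidence


def harmonize_genomic(
    genomic: GenomicEvidence,
    grid_250k: WindowGrid,
    policy: str = "any",
) -> tuple[np.ndarray, np.ndarray]:
    """Lift the 100-kb genomic flags onto a coarser grid by overlap.

    policy="any": a coarse window is flagged iff >=1 overlapping fine
    window is flagged. policy="all": every overlapping fine window with
    data must be flagged. Returns (flag, no_data) on the coarse grid; a
    coarse window has no data iff all overlapping fine windows do.
    """
    if policy not in ("any", "all"):
        raise ValueError("policy must be 'any' or 'all'")
    if genomic.grid.layout.lengths != grid_250k.layout.lengths:
        raise ValueError("grids must cover the same layout")
    flag = np.zeros(grid_250k.n_windows, dtype=bool)
    no_data = np.zeros(grid_250k.n_windows, dtype=bool)
    fine = genomic.grid
    for name in grid_250k.layout.names:
        cs, fs = grid_250k.chrom_slice(name), fine.chrom_slice(name)
        f_start, f_end = fine.start[fs], fine.end[fs]
        f_flag, f_nd = genomic.flag[fs], genomic.no_data[fs]
        for w, (cstart, cend) in enumerate(
            zip(grid_250k.start[cs], grid_250k.end[cs])
        ):
            ov = (f_start < cend) & (f_end > cstart)
            gi = cs.start + w
            if not ov.any() or f_nd[ov].all():
                no_data[gi] = True
                continue
            informative = ov & ~f_nd
            if policy == "any":
                flag[gi] = bool(f_flag[ov].any())
            else:
                flag[gi] = bool(f_flag[informative].all())
    return flag, no_data


@dataclass
class EvidenceMatrix:
    """Per-250-kb-window flags of the three HE criteria plus confirmation."""

    grid: WindowGrid
    flag_genomic: np.ndarray
    flag_rna: np.ndarray
    flag_iaa: np.ndarray
    no_data_genomic: np.ndarray
    no_data_rna: np.ndarray
    no_data_iaa: np.ndarray
    confirmation: QuantileConfirmation | None = None

    @classmethod
    def build(
        cls,
        genomic: GenomicEvidence,
        rna: RnaEvidence,
        iaa: IaaEvidence,
        confirmation: QuantileConfirmation | None = None,
        harmonize_policy: str = "any",
    ) -> "EvidenceMatrix":
        grid = rna.grid
        if grid.window_size != iaa.grid.window_size or (
            grid.layout.lengths != iaa.grid.layout.lengths
        ):
            raise ValueError("RNA and IAA tracks must share the 250-kb grid")
        g_flag, g_nd = harmonize_genomic(genomic, grid, harmonize_policy)
        return cls(grid, g_flag, rna.flag, iaa.flag,
                   g_nd, rna.no_data, iaa.no_data, confirmation)

    @property
    def qualifying(self) -> np.ndarray:
        return self.flag_genomic & self.flag_rna & self.flag_iaa

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["subgenome"] = self.grid.subgenome_labels()
        df["flag_genomic"] = self.flag_genomic
        df["flag_rna"] = self.flag_rna
        df["flag_iaa"] = self.flag_iaa
        df["no_data_genomic"] = self.no_data_genomic
        df["no_data_rna"] = self.no_data_rna
        df["no_data_iaa"] = self.no_data_iaa
        df["qualifying"] = self.qualifying
        return df


@dataclass
class HERegion:
    """A directed homoeologous-exchange call: a maximal run of adjacent
    qualifying 250-kb windows on one chromosome, interpreted as replacement
    of this segment by the homoeologous subgenome's copy."""

    subgenome: str
    chromosome: str
    start: int
    end: int
    n_windows: int
    direction: str = "replaced_by_other_subgenome"
    confirmed: bool | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def call_he(evidence: EvidenceMatrix) -> list[HERegion]:
    """Merge runs of windows satisfying all three criteria into regions.

    Single qualifying windows stand as regions of one window. Regions are
    annotated as confirmed when any overlapping 1-Mb confirmation window is
    confirmed (None when no confirmation track was supplied).
    """
    if evidence.grid.n_windows == 0:
        raise ValueError("empty evidence matrix")
    q = evidence.qualifying
    regions: list[HERegion] = []
    grid = evidence.grid
    for name in grid.layout.names:
        sl = grid.chrom_slice(name)
        flags = q[sl]
        starts, ends = grid.start[sl], grid.end[sl]
        label = grid.layout.label(name)
        i = 0
        while i < flags.size:
            if not flags[i]:
                i += 1
                continue
            j = i
            while j + 1 < flags.size and flags[j + 1]:
                j += 1
            regions.append(HERegion(
                subgenome=label, chromosome=name,
                start=int(starts[i]), end=int(ends[j]),
                n_windows=j - i + 1,
            ))
            i = j + 1
    if evidence.confirmation is not None:
        conf = evidence.confirmation
        for region in regions:
            sl = conf.grid.chrom_slice(region.chromosome)
            ov = (conf.grid.start[sl] < region.end) & (
                conf.grid.end[sl] > region.start)
            region.confirmed = bool(conf.confirmed[sl][ov].any())
    return regions


def regions_to_frame(regions: list[HERegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": r.chromosome, "start": r.start, "end": r.end,
                "subgenome": r.subgenome, "n_windows": r.n_windows,
                "direction": r.direction, "confirmed": r.confirmed,
            }
            for r in regions
        ],
        columns=["chromosome", "start", "end", "subgenome", "n_windows",
                 "direction", "confirmed"],
    )


def write_regions_bed(regions: list[HERegion], path: str | Path) -> None:
    """BED6-style export (0-based half-open), deterministic order."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for i, r in enumerate(
            sorted(regions, key=lambda r: (r.chromosome, r.start))
        ):
            conf = {True: "confirmed", False: "unconfirmed", None: "na"}[r.confirmed]
            name = f"HE_{r.subgenome}_{i}|windows={r.n_windows}|{conf}"
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{name}\t{r.n_windows}\t+\n")


def read_regions_bed(path: str | Path, layout: GenomeLayout) -> list[HERegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score, _ = line.rstrip("\n").split("\t")
            conf_txt = name.split("|")[-1]
            conf = {"confirmed": True, "unconfirmed": False, "na": None}[conf_txt]
            regions.append(HERegion(
                subgenome=layout.label(chrom), chromosome=chrom,
                start=int(start), end=int(end), n_windows=int(score),
                confirmed=conf,
            ))
    return regions


def export_tracks(
    evidence: EvidenceMatrix, regions: list[HERegion], out_prefix: str | Path
) -> dict[str, Path]:
    """Write the evidence matrix (TSV), region calls (BED) and a
    circular-plot-ready per-window table. Returns the paths written."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": prefix.with_suffix(".evidence.tsv"),
        "regions": prefix.with_suffix(".he_regions.bed"),
        "plot": prefix.with_suffix(".plot.tsv"),
    }
    evidence.to_frame().to_csv(paths["matrix"], sep="\t", index=False)
    write_regions_bed(regions, paths["regions"])
    plot = evidence.to_frame()[["chromosome", "start", "end", "qualifying"]]
    plot = plot.assign(value=plot.pop("qualifying").astype(int))
    plot.to_csv(paths["plot"], sep="\t", index=False)
    return paths


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def precision_recall(
    calls: list[HERegion],
    truth: list[tuple[str, int, int]],
    min_reciprocal: float = 0.5,
) -> dict[str, float]:
    """Score calls against planted truth intervals.

    A truth interval is recovered (and a call is a true positive) when the
    pair overlaps reciprocally by at least ``min_reciprocal`` of each
    length. Returns recall, precision and the raw counts.
    """
    truth_hit = [False] * len(truth)
    call_hit = [False] * len(calls)
    for ti, (chrom, ts, te) in enumerate(truth):
        for ci, call in enumerate(calls):
            if call.chromosome != chrom:
                continue
            if _reciprocal_overlap((ts, te), (call.start, call.end)) >= min_reciprocal:
                truth_hit[ti] = True
                call_hit[ci] = True
    recall = sum(truth_hit) / len(truth) if truth else float("nan")
    precision = sum(call_hit) / len(calls) if calls else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_truth": len(truth),
        "n_calls": len(calls),
        "n_truth_recovered": sum(truth_hit),
        "n_calls_matched": sum(call_hit),
    }
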