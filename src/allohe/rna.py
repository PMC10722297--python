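"""Transcriptomic evidence track: per-250-kb coverage differences between
hybrid RNA-seq and each ancestral species' RNA-seq mapped onto the hybrid.

For a subgenome-a window the intraspecific delta is (hybrid - ancestor A)
coverage and the interspecific delta is (hybrid - ancestor F); mirrored
for subgenome f. The intraspecific delta is expected to sit near zero;
windows where it strictly exceeds the interspecific delta point at
homoeologous exchange.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import CoverageTrack, GenomeLayout, WindowGrid, make_windows


def pooled_coverage(tracks: list[CoverageTrack], dataset_id: str = "pooled") -> CoverageTrack:
    """Union-pool several datasets of one species into a single track.

    A base counts as covered if it is covered in at least one dataset, so
    pooling happens at base level (interval union), not by averaging
    fractions. Every input track must retain its source intervals and share
    one grid.
    """
    if not tracks:
        raise ValueError("no tracks to pool")
    grid = tracks[0].grid
    for t in tracks[1:]:
        if t.grid is not grid and (
            t.grid.window_size != grid.window_size
            or t.grid.layout.lengths != grid.layout.lengths
        ):
            raise ValueError("pooled tracks must share one window grid")
    merged: dict[str, np.ndarray] = {}
    for name in grid.layout.names:
        pieces = []
        for t in tracks:
            if t.intervals is None:
                raise ValueError(
                    f"track {t.dataset_id} lacks source intervals; "
                    "base-level pooling needs them")
            iv = t.intervals.get(name)
            if iv is not None and len(iv):
                pieces.append(np.asarray(iv).reshape(-1, 2))
        merged[name] = (np.vstack(pieces) if pieces
                        else np.empty((0, 2), dtype=np.int64))
    return CoverageTrack.from_intervals(dataset_id, grid, merged,
                                        tracks[0].depth_threshold)


@dataclass
class RnaEvidence:
    """Per-window RNA coverage deltas and HE flags on the 250-kb grid."""

    grid: WindowGrid
    cov_hybrid: np.ndarray
    cov_ancestor_a: np.ndarray
    cov_ancestor_f: np.ndarray
    delta_a: np.ndarray
    delta_f: np.ndarray
    flag: np.ndarray
    no_data: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["subgenome"] = self.grid.subgenome_labels()
        df["cov_hybrid"] = self.cov_hybrid
        df["cov_ancestor_a"] = self.cov_ancestor_a
        df["cov_ancestor_f"] = self.cov_ancestor_f
        df["delta_a"] = self.delta_a
        df["delta_f"] = self.delta_f
        df["flag_rna"] = self.flag
        df["no_data"] = self.no_data
        return df


def rna_evidence(
    cov_hybrid: CoverageTrack,
    cov_ancestor_a: CoverageTrack,
    cov_ancestor_f: CoverageTrack,
    hybrid_layout: GenomeLayout | None = None,
) -> RnaEvidence:
    """Flag windows whose intraspecific coverage delta exceeds the
    interspecific one (strict inequality; ties are not flagged).

    Signed deltas are used: delta_a = hybrid - ancestor A coverage,
    delta_f = hybrid - ancestor F. Windows with zero coverage in all three
    datasets carry no data and are never flagged.
    """
    grid = cov_hybrid.grid
    for t in (cov_ancestor_a, cov_ancestor_f):
        if t.grid is not grid and (
            t.grid.window_size != grid.window_size
            or t.grid.layout.lengths != grid.layout.lengths
        ):
            raise ValueError("all three tracks must share one grid")
    labels = grid.subgenome_labels()
    if (labels == "none").any():
        raise ValueError("hybrid layout must label every chromosome a or f")
    delta_a = cov_hybrid.values - cov_ancestor_a.values
    delta_f = cov_hybrid.values - cov_ancestor_f.values
    is_a = labels == "a"
    delta_intra = np.where(is_a, delta_a, delta_f)
    delta_inter = np.where(is_a, delta_f, delta_a)
    no_data = (
        (cov_hybrid.values == 0)
        & (cov_ancestor_a.values == 0)
        & (cov_ancestor_f.values == 0)
    )
    flag = (delta_intra > delta_inter) & ~no_data
    return RnaEvidence(
        grid, cov_hybrid.values, cov_ancestor_a.values, cov_ancestor_f.values,
        delta_a, delta_f, flag, no_data,
    )
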