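"""Genomic evidence track: SAM-flag filtering, four-way read-pair
classification against the two ancestral genomes, re-mapping of the
ancestor-unique read sets onto the hybrid subgenomes, and per-100-kb
flagging of windows whose interspecific coverage exceeds the
intraspecific one.

The built-in mapper is an exact matcher for error-free synthetic reads
(seed k-mer lookup plus full-length verification); real data enter
through SAM/BAM. A fragment "matches" a genome iff both mates align in a
proper pair, mirroring a ``samtools view -f 3 -F 2304`` filter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import CoverageTrack, GenomeLayout, WindowGrid, make_windows
from .sequences import Genome, PairedReads

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_LAST = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

REQUIRE_BITS = FLAG_PAIRED | FLAG_PROPER          # samtools -f 3
EXCLUDE_BITS = FLAG_SECONDARY | FLAG_SUPPLEMENTARY  # samtools -F 2304


def passes_filter(flag: int) -> bool:
    """True iff a SAM flag survives ``-f 3 -F 2304`` filtering."""
    if flag < 0:
        raise ValueError("negative SAM flag")
    return (flag & REQUIRE_BITS) == REQUIRE_BITS and (flag & EXCLUDE_BITS) == 0


class ReadClass(enum.IntEnum):
    """Origin class of a hybrid read pair against the two ancestors."""

    UNIQUE_A = 0
    UNIQUE_F = 1
    BOTH = 2
    NEITHER = 3


class KmerIndex:
    """Sorted k-mer index over the concatenated chromosomes of a genome."""

    def __init__(self, genome: Genome, k: int = 31):
        if not 1 <= k <= 31:
            raise ValueError("k must be in [1, 31]")
        self.genome = genome
        self.k = k
        lengths = [genome.length(n) for n in genome.names]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
        self.concat = np.concatenate([genome[n] for n in genome.names])

        kmer_chunks, pos_chunks = [], []
        for ci, name in enumerate(genome.names):
            codes = genome[name]
            n = codes.size - k + 1
            if n <= 0:
                continue
            kmer_chunks.append(_rolling_kmers(codes, k))
            pos_chunks.append(np.arange(n, dtype=np.int64) + self.offsets[ci])
        kmers = np.concatenate(kmer_chunks) if kmer_chunks else np.empty(0, np.uint64)
        pos = np.concatenate(pos_chunks) if pos_chunks else np.empty(0, np.int64)
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.sorted_pos = pos[order]

    def lookup(self, kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(start, count) ranges into ``sorted_pos`` for each query k-mer."""
        lo = np.searchsorted(self.sorted_kmers, kmers, side="left")
        hi = np.searchsorted(self.sorted_kmers, kmers, side="right")
        return lo, hi - lo

    def chrom_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, side="right") - 1


def _rolling_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.size - k + 1
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = out * np.uint64(4) + codes[j:j + n].astype(np.uint64)
    return out


def _matrix_kmers(mat: np.ndarray, k: int) -> np.ndarray:
    """Leading k-mer of each row of a (n, L) read matrix."""
    out = np.zeros(mat.shape[0], dtype=np.uint64)
    for j in range(k):
        out = out * np.uint64(4) + mat[:, j].astype(np.uint64)
    return out


def _find_exact(index: KmerIndex, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All full-length exact hits of the rows of ``mat`` in the genome.

    Returns (read_idx, global_pos), unsorted. A full-length match must match
    the leading k-mer, so seed lookup is complete for error-free reads.
    """
    k, L = index.k, mat.shape[1]
    if k > L:
        raise ValueError("seed length k exceeds read length")
    seeds = _matrix_kmers(mat, k)
    lo, counts = index.lookup(seeds)

    has = counts > 0
    ridx = np.repeat(np.nonzero(has)[0], counts[has])
    cum = np.concatenate([[0], np.cumsum(counts[has])])
    within = np.arange(cum[-1], dtype=np.int64) - np.repeat(cum[:-1], counts[has])
    cand = index.sorted_pos[np.repeat(lo[has], counts[has]) + within]

    # the full read must stay inside its chromosome
    ci = index.chrom_of(cand)
    ok = cand + L <= index.offsets[ci + 1]
    ridx, cand = ridx[ok], cand[ok]

    keep_r, keep_p = [], []
    chunk = 200_000
    span = np.arange(L, dtype=np.int64)
    for s in range(0, cand.size, chunk):
        r, p = ridx[s:s + chunk], cand[s:s + chunk]
        hit = (index.concat[p[:, None] + span] == mat[r]).all(axis=1)
        keep_r.append(r[hit])
        keep_p.append(p[hit])
    if not keep_r:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(keep_r), np.concatenate(keep_p)


@dataclass
class MappingResult:
    """Exact-mapping outcome of a paired read set against one genome.

    Per-mate primary placements use global (concatenated) coordinates;
    ``proper`` marks fragments whose primary placement is a converging
    proper pair within the insert bound. ``hits`` holds every full-length
    match as (read_idx, mate, strand, global_pos) columns.
    """

    genome: Genome
    index: KmerIndex
    n_pairs: int
    read_length: int
    max_insert: int
    proper: np.ndarray                      # (n,) bool
    primary_chrom: np.ndarray               # (n, 2) int, -1 if unmapped
    primary_start: np.ndarray               # (n, 2) chromosome-local start
    primary_strand: np.ndarray              # (n, 2) 0 fwd / 1 rev
    n_hits: np.ndarray                      # (n, 2) int
    hits: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]

    @property
    def mapped_pair(self) -> np.ndarray:
        """Fragments where both mates have at least one full-length hit."""
        return (self.n_hits > 0).all(axis=1)

    def primary_intervals(self, proper_only: bool = True) -> dict[str, np.ndarray]:
        """Per-chromosome (n,2) reference spans of primary alignments."""
        sel = self.proper if proper_only else self.mapped_pair
        out: dict[str, np.ndarray] = {}
        for ci, name in enumerate(self.genome.names):
            spans = []
            for mate in (0, 1):
                m = sel & (self.primary_chrom[:, mate] == ci)
                s = self.primary_start[m, mate]
                spans.append(np.column_stack([s, s + self.read_length]))
            out[name] = np.vstack(spans) if spans else np.empty((0, 2), np.int64)
        return out

    def to_alignment_table(self) -> pd.DataFrame:
        """All hits as SAM-semantics records (0-based starts internally)."""
        ridx, mate, strand, gpos = self.hits
        ci = self.index.chrom_of(gpos)
        start = gpos - self.index.offsets[ci]
        m = mate.astype(np.int64)
        prim_ci = self.primary_chrom[ridx, m]
        is_primary = (
            (prim_ci == ci)
            & (self.primary_start[ridx, m] == start)
            & (self.primary_strand[ridx, m] == strand)
        )
        flags = np.full(ridx.size, FLAG_PAIRED, dtype=np.int64)
        flags |= np.where(self.proper[ridx], FLAG_PROPER, 0)
        flags |= np.where(strand == 1, FLAG_REVERSE, 0)
        mate_strand = self.primary_strand[ridx, 1 - mate]
        flags |= np.where(mate_strand == 1, FLAG_MATE_REVERSE, 0)
        flags |= np.where(mate == 0, FLAG_FIRST, FLAG_LAST)
        flags |= np.where(self.n_hits[ridx, 1 - mate] == 0, FLAG_MATE_UNMAPPED, 0)
        flags |= np.where(is_primary, 0, FLAG_SECONDARY)
        names = np.array(self.genome.names, dtype=object)
        return pd.DataFrame(
            {
                "fragment": ridx,
                "mate": mate + 1,
                "flag": flags,
                "chromosome": names[ci],
                "start": start,
                "end": start + self.read_length,
            }
        ).sort_values(["fragment", "mate", "chromosome", "start"], ignore_index=True)


def exact_map(
    reads: PairedReads,
    genome: Genome | KmerIndex,
    k: int = 31,
    max_insert: int = 2000,
) -> MappingResult:
    """Map error-free read pairs by exact full-length matching.

    A read maps wherever it matches the reference exactly on either strand.
    The primary placement of a pair is the lexicographically smallest
    (chromosome, forward-mate start) converging placement with insert size
    between the read length and ``max_insert``; pairs with such a placement
    are flagged proper.
    """
    index = genome if isinstance(genome, KmerIndex) else KmerIndex(genome, k)
    n, L = reads.n_pairs, reads.read_length

    hit_r, hit_m, hit_s, hit_p = [], [], [], []
    per_mate = []
    for mate, mat in enumerate((reads.r1, reads.r2)):
        rc = np.ascontiguousarray((3 - mat)[:, ::-1])
        rf, pf = _find_exact(index, mat)
        rr, pr = _find_exact(index, rc)
        ridx = np.concatenate([rf, rr])
        strand = np.concatenate([np.zeros(rf.size, np.int8), np.ones(rr.size, np.int8)])
        gpos = np.concatenate([pf, pr])
        order = np.lexsort((gpos, strand, ridx))
        ridx, strand, gpos = ridx[order], strand[order], gpos[order]
        per_mate.append((ridx, strand, gpos))
        hit_r.append(ridx)
        hit_m.append(np.full(ridx.size, mate, np.int8))
        hit_s.append(strand)
        hit_p.append(gpos)

    proper = np.zeros(n, dtype=bool)
    primary_chrom = np.full((n, 2), -1, dtype=np.int64)
    primary_start = np.zeros((n, 2), dtype=np.int64)
    primary_strand = np.zeros((n, 2), dtype=np.int8)
    n_hits = np.zeros((n, 2), dtype=np.int64)
    for mate in (0, 1):
        np.add.at(n_hits[:, mate], per_mate[mate][0], 1)

    r1, s1, p1 = per_mate[0]
    r2, s2, p2 = per_mate[1]
    counts2 = np.bincount(r2, minlength=n)
    off2 = np.concatenate([[0], np.cumsum(counts2)])

    group = counts2[r1]                       # mate-2 hits per mate-1 hit
    total = int(group.sum())
    if total:
        i1 = np.repeat(np.arange(r1.size), group)
        cum = np.concatenate([[0], np.cumsum(group)])
        within = np.arange(total, dtype=np.int64) - np.repeat(cum[:-1], group)
        i2 = off2[r1[i1]] + within

        g1, g2 = p1[i1], p2[i2]
        st1, st2 = s1[i1], s2[i2]
        fwd = np.where(st1 == 0, g1, g2)
        rev = np.where(st1 == 0, g2, g1)
        insert = rev + L - fwd
        ci1 = index.chrom_of(g1)
        ok = (
            (st1 != st2)
            & (ci1 == index.chrom_of(g2))
            & (rev >= fwd)
            & (insert >= L)
            & (insert <= max_insert)
        )
        if ok.any():
            frag = r1[i1[ok]]
            key_pos = np.minimum(g1[ok], g2[ok])
            order = np.lexsort((key_pos, frag))
            frag_o = frag[order]
            first = np.concatenate([[True], frag_o[1:] != frag_o[:-1]])
            pick = order[first]
            f = frag[pick]
            proper[f] = True
            for mate, (gp, st) in ((0, (g1, st1)), (1, (g2, st2))):
                gsel = gp[ok][pick]
                ci = index.chrom_of(gsel)
                primary_chrom[f, mate] = ci
                primary_start[f, mate] = gsel - index.offsets[ci]
                primary_strand[f, mate] = st[ok][pick]

    # mates of non-proper fragments: primary = lowest-coordinate hit
    for mate, (ridx, strand, gpos) in enumerate(per_mate):
        need = ~proper[ridx]
        if need.any():
            r_, s_, g_ = ridx[need], strand[need], gpos[need]
            first = np.concatenate([[True], r_[1:] != r_[:-1]])
            ci = index.chrom_of(g_[first])
            primary_chrom[r_[first], mate] = ci
            primary_start[r_[first], mate] = g_[first] - index.offsets[ci]
            primary_strand[r_[first], mate] = s_[first]

    hits = (
        np.concatenate(hit_r),
        np.concatenate(hit_m),
        np.concatenate(hit_s),
        np.concatenate(hit_p),
    )
    return MappingResult(
        genome=index.genome, index=index, n_pairs=n, read_length=L,
        max_insert=max_insert, proper=proper, primary_chrom=primary_chrom,
        primary_start=primary_start, primary_strand=primary_strand,
        n_hits=n_hits, hits=hits,
    )


def classify_fragments(
    match_a: MappingResult | np.ndarray, match_f: MappingResult | np.ndarray
) -> np.ndarray:
    """Partition fragments into the four origin classes.

    Inputs are either :class:`MappingResult` objects against the two
    ancestors or boolean per-fragment "matches genome" masks (both mates in
    a filter-passing proper pair). The partition is exhaustive and
    exclusive.
    """
    a = match_a.proper if isinstance(match_a, MappingResult) else np.asarray(match_a)
    f = match_f.proper if isinstance(match_f, MappingResult) else np.asarray(match_f)
    if a.shape != f.shape:
        raise ValueError("mismatched fragment counts between the two mappings")
    out = np.full(a.size, int(ReadClass.NEITHER), dtype=np.uint8)
    out[a & ~f] = int(ReadClass.UNIQUE_A)
    out[f & ~a] = int(ReadClass.UNIQUE_F)
    out[a & f] = int(ReadClass.BOTH)
    return out


def class_counts(classes: np.ndarray) -> dict[str, int]:
    return {c.name: int((classes == int(c)).sum()) for c in ReadClass}


def classes_to_frame(classes: np.ndarray, prefix: str = "frag") -> pd.DataFrame:
    names = np.array([c.name for c in ReadClass], dtype=object)
    return pd.DataFrame(
        {
            "fragment_id": [f"{prefix}{i}" for i in range(classes.size)],
            "read_class": names[classes],
        }
    )


def fragment_match_mask_from_sam(path: str | Path) -> pd.Series:
    """Per-fragment "matches this genome" mask from a SAM/BAM file.

    A fragment matches iff both mates carry at least one filter-passing
    (``-f 3 -F 2304``) alignment. Returns a boolean Series indexed by query
    name, covering every query present in the file.
    """
    import pysam

    seen: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            mask = seen.setdefault(rec.query_name, 0)
            if not passes_filter(rec.flag):
                continue
            if rec.is_read1:
                seen[rec.query_name] = mask | 1
            elif rec.is_read2:
                seen[rec.query_name] = mask | 2
    return pd.Series({name: m == 3 for name, m in seen.items()}, dtype=bool)


@dataclass
class GenomicEvidence:
    """Per-100-kb intraspecific vs interspecific coverage and HE flags.

    For a subgenome-a window, cov_intra is the fraction covered by the
    ancestor-A-unique read set and cov_inter by the ancestor-F-unique set;
    mirrored for subgenome f. A window is flagged iff cov_intra < cov_inter
    (strict); windows with zero coverage from both sets carry no data.
    """

    grid: WindowGrid
    cov_intra: np.ndarray
    cov_inter: np.ndarray
    flag: np.ndarray
    no_data: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["subgenome"] = self.grid.subgenome_labels()
        df["cov_intra"] = self.cov_intra
        df["cov_inter"] = self.cov_inter
        df["flag_genomic"] = self.flag
        df["no_data"] = self.no_data
        return df


def genomic_evidence_from_tracks(
    cov_by_a_set: CoverageTrack, cov_by_f_set: CoverageTrack
) -> GenomicEvidence:
    """Assemble the genomic evidence track from the two re-mapped coverages."""
    grid = cov_by_a_set.grid
    if grid is not cov_by_f_set.grid and grid.window_size != cov_by_f_set.grid.window_size:
        raise ValueError("coverage tracks must share one grid")
    labels = grid.subgenome_labels()
    if (labels == "none").any():
        raise ValueError("hybrid layout must label every chromosome a or f")
    is_a = labels == "a"
    cov_intra = np.where(is_a, cov_by_a_set.values, cov_by_f_set.values)
    cov_inter = np.where(is_a, cov_by_f_set.values, cov_by_a_set.values)
    no_data = (cov_by_a_set.values == 0) & (cov_by_f_set.values == 0)
    flag = (cov_intra < cov_inter) & ~no_data
    return GenomicEvidence(grid, cov_intra, cov_inter, flag, no_data)


def genomic_evidence(
    remap_unique_a: MappingResult,
    remap_unique_f: MappingResult,
    hybrid_layout: GenomeLayout,
    window_size: int = 100_000,
) -> GenomicEvidence:
    """Genomic HE evidence from the re-mapped ancestor-unique read sets."""
    grid = make_windows(hybrid_layout, window_size)
    cov_a = CoverageTrack.from_intervals(
        "unique_a", grid, remap_unique_a.primary_intervals())
    cov_f = CoverageTrack.from_intervals(
        "unique_f", grid, remap_unique_f.primary_intervals())
    ev = genomic_evidence_from_tracks(cov_a, cov_f)
    return ev
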