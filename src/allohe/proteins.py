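"""Protein evidence track: per-protein amino-acid identity to each
ancestor, windowed similarity-majority statistics at 250 kb, a 70 %
quantile confirmation at 1 Mb, and per-chromosome aggregation of
transcript sharing.

The canonical in-memory form of a protein table is a pandas DataFrame
with columns (protein_id, chromosome, anchor, iaa_a, iaa_f); identities
are percentages in [0, 100] and may be missing (NaN). A protein's window
is determined by its coding-region start (anchor).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import GenomeLayout, WindowGrid, make_windows

PROTEIN_COLUMNS = ["protein_id", "chromosome", "anchor", "iaa_a", "iaa_f"]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY*X")

_DIAG, _UP, _LEFT = 0, 1, 2


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Percent identity from a global alignment of two protein sequences.

    Scoring: match +1, mismatch 0, linear gap -1. Identity is
    100 * matches / alignment columns, taken from the optimal-score
    alignment; score ties are broken by maximal matches, then minimal
    alignment length, which makes the value deterministic.
    """
    for s in (seq1, seq2):
        if not s:
            raise ValueError("empty protein sequence")
        bad = set(s) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-amino-acid symbols: {sorted(bad)}")
    n, m = len(seq1), len(seq2)
    # lexicographic (score, matches, -columns) packed into one integer:
    # matches and columns stay far below 10**6 for protein-scale input, so
    # the three fields cannot interfere (score steps are integral).
    M = 10**6
    S = M * M
    gap = -S - 1                  # one column, no match, score -1
    match_step = S + M - 1
    mismatch_step = -1
    s2 = np.frombuffer(seq2.encode("ascii"), dtype=np.uint8)
    prev = np.arange(m + 1, dtype=np.int64) * gap
    ptr = np.empty((n + 1, m + 1), dtype=np.int8)
    ptr[0, 0] = _DIAG
    ptr[0, 1:] = _LEFT
    jgap = np.arange(m + 1, dtype=np.int64) * gap
    for i in range(1, n + 1):
        is_match = s2 == ord(seq1[i - 1])
        diag = prev[:-1] + np.where(is_match, match_step, mismatch_step)
        up = prev[1:] + gap
        cand = np.maximum(diag, up)
        # cur[j] = max(cand[j], cur[j-1] + gap) solved as a prefix max:
        # cur[j] = gap*j + max_{t<=j} d[t] with d[0] = prev[0] + gap and
        # d[t] = cand[t] - gap*t for t >= 1.
        d = np.empty(m + 1, dtype=np.int64)
        d[0] = prev[0] + gap
        d[1:] = cand - jgap[1:]
        cur = np.maximum.accumulate(d) + jgap
        ptr[i, 0] = _UP
        row = np.where(cur[1:] == diag, _DIAG,
                       np.where(cur[1:] == up, _UP, _LEFT)).astype(np.int8)
        ptr[i, 1:] = row
        prev = cur
    # traceback to count matches and columns
    i, j, matches, columns = n, m, 0, 0
    while i > 0 or j > 0:
        p = ptr[i, j]
        columns += 1
        if p == _DIAG:
            if seq1[i - 1] == seq2[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif p == _UP:
            i -= 1
        else:
            j -= 1
    return 100.0 * matches / columns


def assign_similarity(
    iaa_a: float | None, iaa_f: float | None, tie_epsilon: float = 0.0
) -> str:
    """Classify one protein as a_higher / f_higher / tie / unassigned.

    A missing identity counts as no homolog in that ancestor: with only one
    identity present the protein is assigned to that ancestor; with both
    missing it is unassigned. Ties use |iaa_a - iaa_f| <= tie_epsilon.
    """
    a_missing = iaa_a is None or (isinstance(iaa_a, float) and np.isnan(iaa_a))
    f_missing = iaa_f is None or (isinstance(iaa_f, float) and np.isnan(iaa_f))
    if a_missing and f_missing:
        return "unassigned"
    if f_missing:
        return "a_higher"
    if a_missing:
        return "f_higher"
    diff = iaa_a - iaa_f
    if diff > tie_epsilon:
        return "a_higher"
    if -diff > tie_epsilon:
        return "f_higher"
    return "tie"


def assign_similarity_frame(records: pd.DataFrame, tie_epsilon: float = 0.0) -> pd.Series:
    """Vectorised :func:`assign_similarity` over a protein table."""
    a = records["iaa_a"].to_numpy(dtype=float)
    f = records["iaa_f"].to_numpy(dtype=float)
    out = np.full(len(records), "unassigned", dtype=object)
    both = ~np.isnan(a) & ~np.isnan(f)
    out[~np.isnan(a) & np.isnan(f)] = "a_higher"
    out[np.isnan(a) & ~np.isnan(f)] = "f_higher"
    diff = a - f
    out[both & (diff > tie_epsilon)] = "a_higher"
    out[both & (-diff > tie_epsilon)] = "f_higher"
    out[both & (np.abs(diff) <= tie_epsilon)] = "tie"
    return pd.Series(out, index=records.index, name="assignment")


@dataclass
class IaaEvidence:
    """Windowed amino-acid-identity majority statistics and HE flags.

    Percentages are over assigned proteins in the window and close to 100;
    iaa_diff = pct_f_higher - pct_a_higher. A subgenome-a window is flagged
    when pct_a_higher < pct_f_higher (mirror for f); empty windows carry no
    data.
    """

    grid: WindowGrid
    pct_a_higher: np.ndarray
    pct_f_higher: np.ndarray
    pct_tie: np.ndarray
    iaa_diff: np.ndarray
    n_proteins: np.ndarray
    flag: np.ndarray
    no_data: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["subgenome"] = self.grid.subgenome_labels()
        df["n_proteins"] = self.n_proteins
        df["pct_a_higher"] = self.pct_a_higher
        df["pct_f_higher"] = self.pct_f_higher
        df["pct_tie"] = self.pct_tie
        df["iaa_diff"] = self.iaa_diff
        df["flag_iaa"] = self.flag
        df["no_data"] = self.no_data
        return df


def _window_indices(records: pd.DataFrame, grid: WindowGrid) -> np.ndarray:
    idx = np.empty(len(records), dtype=np.int64)
    for i, (chrom, anchor) in enumerate(
        zip(records["chromosome"], records["anchor"])
    ):
        idx[i] = grid.window_of(str(chrom), int(anchor))
    return idx


def iaa_evidence(
    records: pd.DataFrame,
    hybrid_layout: GenomeLayout,
    window_size: int = 250_000,
    tie_epsilon: float = 0.0,
) -> IaaEvidence:
    """Windowed identity-majority statistic over anchored proteins."""
    grid = make_windows(hybrid_layout, window_size)
    labels = grid.subgenome_labels()
    if (labels == "none").any():
        raise ValueError("hybrid layout must label every chromosome a or f")
    assignment = assign_similarity_frame(records, tie_epsilon)
    widx = _window_indices(records, grid)

    def count(cat: str) -> np.ndarray:
        return np.bincount(widx[(assignment == cat).to_numpy()],
                           minlength=grid.n_windows).astype(float)

    n_a, n_f, n_tie = count("a_higher"), count("f_higher"), count("tie")
    assigned = n_a + n_f + n_tie
    no_data = assigned == 0
    denom = np.where(no_data, 1.0, assigned)
    pct_a = 100.0 * n_a / denom
    pct_f = 100.0 * n_f / denom
    pct_tie = 100.0 * n_tie / denom
    is_a = labels == "a"
    flag = np.where(is_a, pct_a < pct_f, pct_f < pct_a) & ~no_data
    return IaaEvidence(
        grid, pct_a, pct_f, pct_tie, pct_f - pct_a,
        assigned.astype(np.int64), flag, no_data,
    )


def quantile70(values: np.ndarray, q: float = 0.7) -> float:
    """Quantile by linear interpolation between order statistics
    (rank q*(n-1)); a single value is its own quantile."""
    return float(np.quantile(np.asarray(values, dtype=float), q))


@dataclass
class QuantileConfirmation:
    """Per-1-Mb confirmation of HE candidates from identity quantiles."""

    grid: WindowGrid
    q70_homologous: np.ndarray
    q70_homoeologous: np.ndarray
    confirmed: np.ndarray
    no_data: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["subgenome"] = self.grid.subgenome_labels()
        df["q70_homologous"] = self.q70_homologous
        df["q70_homoeologous"] = self.q70_homoeologous
        df["confirmed"] = self.confirmed
        df["no_data"] = self.no_data
        return df


def quantile70_confirm(
    records: pd.DataFrame,
    hybrid_layout: GenomeLayout,
    window_size: int = 1_000_000,
    q: float = 0.7,
) -> QuantileConfirmation:
    """Confirm candidate windows where the 70 % quantile of identity to the
    homoeologous ancestor strictly exceeds that to the homologous one.

    For a subgenome-a window the homologous ancestor is A and the
    homoeologous one F; mirrored for f. Windows without any protein carrying
    the respective identity are reported as no-data.
    """
    grid = make_windows(hybrid_layout, window_size)
    labels = grid.subgenome_labels()
    widx = _window_indices(records, grid)
    a = records["iaa_a"].to_numpy(dtype=float)
    f = records["iaa_f"].to_numpy(dtype=float)
    q_homo = np.full(grid.n_windows, np.nan)
    q_homoeo = np.full(grid.n_windows, np.nan)
    for w in range(grid.n_windows):
        in_w = widx == w
        homo_vals = a[in_w] if labels[w] == "a" else f[in_w]
        homoeo_vals = f[in_w] if labels[w] == "a" else a[in_w]
        homo_vals = homo_vals[~np.isnan(homo_vals)]
        homoeo_vals = homoeo_vals[~np.isnan(homoeo_vals)]
        if homo_vals.size:
            q_homo[w] = quantile70(homo_vals, q)
        if homoeo_vals.size:
            q_homoeo[w] = quantile70(homoeo_vals, q)
    no_data = np.isnan(q_homo) | np.isnan(q_homoeo)
    confirmed = np.zeros(grid.n_windows, dtype=bool)
    ok = ~no_data
    confirmed[ok] = q_homoeo[ok] > q_homo[ok]
    return QuantileConfirmation(grid, q_homo, q_homoeo, confirmed, no_data)


def summarize_chromosomes(
    records: pd.DataFrame, tie_epsilon: float = 0.0
) -> pd.DataFrame:
    """Per-chromosome transcript sharing summary plus a genome-level sum row.

    Counts: n_transcripts (all records), n_from_f / n_from_a (identity to
    that ancestor present), n_shared_both (both present). Fractions
    frac_higher_f / frac_tie / frac_higher_a are over shared proteins.
    """
    if records.empty:
        return pd.DataFrame(columns=[
            "chromosome", "n_transcripts", "n_from_f", "n_from_a",
            "n_shared_both", "frac_higher_f", "frac_tie", "frac_higher_a"])
    assignment = assign_similarity_frame(records, tie_epsilon)
    rows = []
    groups = list(records.groupby("chromosome", sort=True))
    groups.append(("ALL", records))
    for chrom, sub in groups:
        asg = assignment.loc[sub.index]
        has_a = sub["iaa_a"].notna()
        has_f = sub["iaa_f"].notna()
        shared = has_a & has_f
        n_shared = int(shared.sum())
        denom = n_shared if n_shared else 1
        rows.append({
            "chromosome": chrom,
            "n_transcripts": len(sub),
            "n_from_f": int(has_f.sum()),
            "n_from_a": int(has_a.sum()),
            "n_shared_both": n_shared,
            "frac_higher_f": float((shared & (asg == "f_higher")).sum()) / denom,
            "frac_tie": float((shared & (asg == "tie")).sum()) / denom,
            "frac_higher_a": float((shared & (asg == "a_higher")).sum()) / denom,
        })
    return pd.DataFrame(rows)


def load_published_transcript_counts() -> pd.DataFrame:
    """Published per-chromosome transcript-sharing counts for the sour
    cherry subgenomes (a: sweet-cherry derived, f: ground-cherry derived).

    Columns: chromosome, subgenome, n_transcripts, n_from_f, n_from_a,
    n_shared_both, frac_higher_f, frac_tie, frac_higher_a.
    """
    with resources.files("allohe.data").joinpath(
        "cherry_transcript_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def aggregate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-sum the per-chromosome counts per subgenome and overall."""
    cols = ["n_transcripts", "n_from_f", "n_from_a", "n_shared_both"]
    rows = []
    for sub, grp in counts.groupby("subgenome", sort=True):
        rows.append({"subgenome": sub, **{c: int(grp[c].sum()) for c in cols}})
    rows.append({"subgenome": "total",
                 **{c: int(counts[c].sum()) for c in cols}})
    return pd.DataFrame(rows)


def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Read a (protein_id, chromosome, anchor, iaa_a, iaa_f) TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PROTEIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"protein table misses columns: {sorted(missing)}")
    return df


def write_protein_table(df: pd.DataFrame, path: str | Path) -> None:
    df[PROTEIN_COLUMNS].to_csv(path, sep="\t", index=False)
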