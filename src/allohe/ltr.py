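"""LTR retrotransposon insertion-time dating and shared-element matching.

The two long terminal repeats of an element are identical at insertion
and diverge neutrally afterwards, so their residual identity dates the
insertion: T = K / (2µ) generations, with K = 1 - identity and µ the
per-site, per-generation substitution rate (Prunus default 7.7e-9).
Calendar ages follow from a years-per-generation assumption, swept over
10-60 years here because long-lived trees have no sharp generation time.

Shared elements across two (sub)genomes are pairs of the same family
with indistinguishable insertion times (identity within a tolerance)
occurring in the same positional order; order is enforced as a
maximum-cardinality collinear matching per chromosome pair (LCS-style
dynamic programming).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MU = 7.7e-9
GENERATION_YEARS_RANGE = (10.0, 60.0)


@dataclass(frozen=True)
class MutationClock:
    """Substitution clock: rate per site per generation, and the
    years-per-generation used to convert generations to calendar time."""

    mu: float = DEFAULT_MU
    years_per_generation: float = 10.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.years_per_generation <= 0:
            raise ValueError("clock constants must be positive")


def insertion_generations(identity: float, mu: float = DEFAULT_MU) -> float:
    """Generations since insertion: T = (1 - identity) / (2 µ)."""
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity {identity} outside [0, 1]")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return (1.0 - identity) / (2.0 * mu)


def generations_to_mya(T: float, years_per_generation: float) -> float:
    """Convert generations to million years: Mya = T * years / 1e6."""
    if T < 0 or years_per_generation < 0:
        raise ValueError("negative inputs")
    return T * years_per_generation / 1e6


def age_sweep_mya(
    T: float, years_range: tuple[float, float] = GENERATION_YEARS_RANGE
) -> tuple[float, float]:
    """Calendar-age interval spanned by a generations estimate over a
    years-per-generation range (default 10-60 years)."""
    lo, hi = years_range
    return generations_to_mya(T, lo), generations_to_mya(T, hi)


@dataclass(frozen=True)
class LTRElement:
    """An intact LTR retrotransposon with left-vs-right LTR identity."""

    genome_id: str
    chromosome: str
    start: int
    end: int
    family: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")
        if self.start >= self.end:
            raise ValueError("start must be < end")

    def generations(self, mu: float = DEFAULT_MU) -> float:
        return insertion_generations(self.identity, mu)


@dataclass(frozen=True)
class LTRMatch:
    element_1: LTRElement
    element_2: LTRElement

    def delta_generations(self, mu: float = DEFAULT_MU) -> float:
        return abs(self.element_1.generations(mu) - self.element_2.generations(mu))


def _collinear_lcs(
    els1: list[LTRElement], els2: list[LTRElement], tol: float
) -> list[tuple[int, int]]:
    """Maximum-cardinality order-preserving matching of compatible pairs."""
    n, m = len(els1), len(els2)
    compat = np.zeros((n, m), dtype=bool)
    for i, e1 in enumerate(els1):
        for j, e2 in enumerate(els2):
            compat[i, j] = (
                e1.family == e2.family and abs(e1.identity - e2.identity) <= tol
            )
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(dp[i - 1, j], dp[i, j - 1])
            if compat[i - 1, j - 1]:
                best = max(best, dp[i - 1, j - 1] + 1)
            dp[i, j] = best
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        if compat[i - 1, j - 1] and dp[i, j] == dp[i - 1, j - 1] + 1:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif dp[i - 1, j] >= dp[i, j - 1]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _max_unordered(
    els1: list[LTRElement], els2: list[LTRElement], tol: float
) -> list[tuple[int, int]]:
    """Maximum-cardinality one-to-one matching without the order
    constraint (Kuhn's augmenting-path algorithm); always at least as
    large as the collinear matching."""
    adj = [
        [
            j
            for j, e2 in enumerate(els2)
            if e1.family == e2.family and abs(e1.identity - e2.identity) <= tol
        ]
        for e1 in els1
    ]
    match2 = [-1] * len(els2)

    def augment(i: int, seen: list[bool]) -> bool:
        for j in adj[i]:
            if not seen[j]:
                seen[j] = True
                if match2[j] == -1 or augment(match2[j], seen):
                    match2[j] = i
                    return True
        return False

    for i in range(len(els1)):
        augment(i, [False] * len(els2))
    pairs = sorted((i, j) for j, i in enumerate(match2) if i != -1)
    return pairs


def match_shared_ltrs(
    elements_1: list[LTRElement],
    elements_2: list[LTRElement],
    identity_tolerance: float = 1e-4,
    enforce_order: bool = True,
    chromosome_pairs: list[tuple[str, str]] | None = None,
) -> list[LTRMatch]:
    """Identify shared elements between two (sub)genomes.

    Candidate pairs require equal family and identities within
    ``identity_tolerance`` ("same insertion time"). With ``enforce_order``
    the result is a maximum collinear subset per chromosome pair; each
    element is matched at most once. Chromosome pairs default to pairing
    the i-th chromosome (sorted name order) of each genome.
    """
    def by_chrom(els):
        chroms: dict[str, list[LTRElement]] = {}
        for e in els:
            chroms.setdefault(e.chromosome, []).append(e)
        for name, lst in chroms.items():
            if any(lst[i].start > lst[i + 1].start for i in range(len(lst) - 1)):
                raise ValueError(f"elements on {name} are not sorted by start")
        return chroms

    c1, c2 = by_chrom(elements_1), by_chrom(elements_2)
    if chromosome_pairs is None:
        chromosome_pairs = list(zip(sorted(c1), sorted(c2)))
    matches: list[LTRMatch] = []
    for name1, name2 in chromosome_pairs:
        els1 = c1.get(name1, [])
        els2 = c2.get(name2, [])
        if not els1 or not els2:
            continue
        if enforce_order:
            pairs = _collinear_lcs(els1, els2, identity_tolerance)
        else:
            pairs = _max_unordered(els1, els2, identity_tolerance)
        matches.extend(LTRMatch(els1[i], els2[j]) for i, j in pairs)
    return matches


def youngest_shared_generations(
    matches: list[LTRMatch], mu: float = DEFAULT_MU
) -> float:
    """Minimum insertion age (generations, averaged within each pair)
    over the shared elements."""
    if not matches:
        return float("nan")
    return min(
        (m.element_1.generations(mu) + m.element_2.generations(mu)) / 2.0
        for m in matches
    )


PASS_LIST_COLUMNS = ["location", "category", "identity", "superfamily"]


def parse_pass_list(path: str | Path, genome_id: str | None = None) -> list[LTRElement]:
    """Parse an intact-LTR annotation table ("pass list") into elements.

    Expects a whitespace/tab-separated table whose header names a location
    column (``chrom:start..end``), an ``Identity`` column (fraction) and a
    ``SuperFamily`` classification column, as written by common LTR
    annotation tools. Malformed rows are skipped and counted in a warning.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            logger.warning("empty pass list %s", path)
            return []
        cols = header.lstrip("#").split()
        lower = [c.lower() for c in cols]

        def col_idx(*names):
            for name in names:
                if name in lower:
                    return lower.index(name)
            return None

        loc_i = col_idx("ltr_loc", "location", "loc")
        id_i = col_idx("identity")
        fam_i = col_idx("superfamily", "family")
        if id_i is None:
            raise ValueError(f"{path}: no identity column in header")
        if loc_i is None:
            loc_i = 0

        elements: list[LTRElement] = []
        skipped = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            try:
                loc = fields[loc_i]
                chrom, span = loc.split(":")
                start_s, end_s = span.split("..")
                identity = float(fields[id_i])
                family = fields[fam_i] if fam_i is not None else "unknown"
                elements.append(LTRElement(
                    genome_id=genome_id or path.stem,
                    chromosome=chrom, start=int(start_s), end=int(end_s),
                    family=family, identity=identity,
                ))
            except (IndexError, ValueError) as exc:
                skipped += 1
                logger.warning("%s line %d skipped: %s", path, lineno, exc)
        if skipped:
            logger.warning("%s: skipped %d malformed rows", path, skipped)
    elements.sort(key=lambda e: (e.chromosome, e.start))
    return elements


def write_pass_list(elements: list[LTRElement], path: str | Path) -> None:
    """Write elements in the pass-list layout that :func:`parse_pass_list`
    reads back (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("#LTR_loc\tCategory\tIdentity\tSuperFamily\n")
        for e in sorted(elements, key=lambda e: (e.chromosome, e.start)):
            fh.write(
                f"{e.chromosome}:{e.start}..{e.end}\tpass\t"
                f"{e.identity:.6f}\t{e.family}\n"
            )


def date_elements(
    elements: list[LTRElement],
    mu: float = DEFAULT_MU,
    years_range: tuple[float, float] = GENERATION_YEARS_RANGE,
) -> pd.DataFrame:
    """Dated-element table: identity, generations and the calendar-age
    interval over the years-per-generation sweep. Report values round
    generations to one decimal; full precision stays in the elements."""
    rows = []
    for e in elements:
        T = e.generations(mu)
        lo, hi = age_sweep_mya(T, years_range)
        rows.append({
            "genome": e.genome_id, "chromosome": e.chromosome,
            "start": e.start, "end": e.end, "family": e.family,
            "identity": e.identity, "t_generations": round(T, 1),
            "age_min_mya": round(lo, 3), "age_max_mya": round(hi, 3),
        })
    return pd.DataFrame(rows, columns=[
        "genome", "chromosome", "start", "end", "family", "identity",
        "t_generations", "age_min_mya", "age_max_mya"])
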