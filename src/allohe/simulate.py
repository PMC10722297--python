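"""Seeded generator of a segmental-allotetraploid test universe.

The generator emulates the data a real HE analysis consumes: two
ancestral genomes diverged by a tunable substitution rate, a hybrid
carrying both subgenomes with planted duplication-deletion homoeologous
exchanges, error-free paired short reads, gene/protein tables with
ancestor-specific amino-acid identity, RNA coverage tracks and LTR
element tables — each with machine-readable ground truth.

The model is substitution-only (no indels), which keeps coordinates
shared between ancestors, hybrid and genes, and makes exact-match read
mapping and identity arithmetic closed-form. Every output is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .layout import make_windows
from .proteins import pairwise_identity
from .ltr import LTRElement, write_pass_list
from .sequences import Genome, PairedReads, decode

HYBRID_ID = "hybrid"
ANCESTOR_A_ID = "ancestor_a"
ANCESTOR_F_ID = "ancestor_f"


@dataclass
class SimConfig:
    """Study conditions for the synthetic allotetraploid.

    Defaults mirror the real system the generator emulates: 3 % ancestor
    divergence (sweet vs ground cherry scale), 0.2 % post-hybridisation
    drift of each subgenome from its ancestor, 150-bp error-free pairs at
    ~550-bp inserts and 20x coverage, genes every 50 kb. HE segments are
    (subgenome, chromosome_index, start, end) with coordinates snapped to
    250-kb boundaries in the shipped configuration so expected flagged
    window sets are exact.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    ancestor_divergence: float = 0.03
    subgenome_drift: float = 0.002
    he_segments: list[tuple[str, int, int, int]] = field(default_factory=list)
    read_length: int = 150
    insert_mean: float = 550.0
    insert_sd: float = 50.0
    coverage: float = 20.0
    gene_spacing: int = 50_000
    gene_length: int = 2_000
    protein_nt: int = 300
    expressed_fraction: float = 0.9
    accession_capture: float = 0.8
    n_hybrid_rna_accessions: int = 3
    ltr_spec: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rate in (self.ancestor_divergence, self.subgenome_drift):
            if not 0.0 <= rate < 0.5:
                raise ValueError("substitution rates must lie in [0, 0.5)")
        per_chrom: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for sub, ci, start, end in self.he_segments:
            if sub not in ("a", "f"):
                raise ValueError("HE subgenome must be 'a' or 'f'")
            if not (0 <= start < end <= self.chromosome_length):
                raise ValueError(f"HE segment [{start},{end}) out of bounds")
            per_chrom.setdefault((sub, ci), []).append((start, end))
        for segs in per_chrom.values():
            segs.sort()
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError("overlapping HE segments on one chromosome")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def hybrid_chrom(self, subgenome: str, ci: int) -> str:
        return f"chr{ci + 1}_{subgenome}"


def default_config(seed: int = 0) -> SimConfig:
    """The shipped synthetic configuration: 2 chromosomes per subgenome of
    5 Mb, six planted HEs of 0.5-2 Mb snapped to 250-kb boundaries across
    both subgenomes, plus an LTR complement whose youngest shared elements
    carry the identities observed in the sour cherry study."""
    he = [
        ("a", 0, 1_000_000, 2_250_000),
        ("a", 0, 3_500_000, 4_000_000),
        ("a", 1, 2_000_000, 4_000_000),
        ("f", 0, 500_000, 1_250_000),
        ("f", 1, 1_500_000, 2_500_000),
        ("f", 1, 3_750_000, 4_250_000),
    ]
    return SimConfig(seed=seed, he_segments=he, ltr_spec=default_ltr_spec())


@dataclass
class SimTruth:
    """Ground truth of one simulated universe."""

    he_intervals: list[tuple[str, int, int]]  # hybrid chromosome, start, end
    gene_table: pd.DataFrame | None = None    # gene_id, chromosome, anchor, origin
    ltr_truth: pd.DataFrame | None = None

    def he_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\n")
            for i, (chrom, s, e) in enumerate(sorted(self.he_intervals)):
                fh.write(f"{chrom}\t{s}\t{e}\ttruth_he_{i}\n")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate``; a substituted site
    always receives a different base."""
    out = codes.copy()
    if rate <= 0:
        return out
    hits = np.nonzero(rng.random(codes.size) < rate)[0]
    # add 1..3 modulo 4 guarantees a change
    out[hits] = (out[hits] + rng.integers(1, 4, hits.size)) % 4
    return out


def expected_pairwise_mismatch(divergence: float) -> float:
    """Expected observed mismatch fraction between the two ancestors under
    the change-to-different-base model with rate divergence/2 per branch:
    sites hit on exactly one branch always differ; sites hit on both
    differ with probability 2/3."""
    q = divergence / 2.0
    return 2 * q * (1 - q) + q * q * (2.0 / 3.0)


def simulate_ancestors(config: SimConfig) -> tuple[Genome, Genome]:
    """Two ancestors descending from a common random root, each branch
    substituted at divergence/2."""
    rng = np.random.default_rng([config.seed, 1])
    a_seqs, f_seqs = {}, {}
    for name in config.chrom_names:
        root = rng.integers(0, 4, config.chromosome_length, dtype=np.uint8)
        a_seqs[name] = _mutate(root, config.ancestor_divergence / 2, rng)
        f_seqs[name] = _mutate(root, config.ancestor_divergence / 2, rng)
    return (
        Genome(ANCESTOR_A_ID, config.chrom_names, a_seqs),
        Genome(ANCESTOR_F_ID, config.chrom_names, f_seqs),
    )


def simulate_hybrid(
    ancestor_a: Genome, ancestor_f: Genome, config: SimConfig
) -> tuple[Genome, SimTruth]:
    """Hybrid with subgenome a from ancestor A and f from ancestor F,
    planted unidirectional duplication-deletion HEs, then independent
    post-hybridisation drift on every chromosome.

    An HE replaces a segment of one subgenome with the homoeologous
    ancestral segment of the other (coordinates shared, substitution-only
    model); both copies subsequently drift independently.
    """
    rng = np.random.default_rng([config.seed, 2])
    names: list[str] = []
    seqs: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    he_intervals: list[tuple[str, int, int]] = []
    for sub, donor_genome, own_genome in (
        ("a", ancestor_f, ancestor_a),
        ("f", ancestor_a, ancestor_f),
    ):
        for ci, src_name in enumerate(config.chrom_names):
            name = config.hybrid_chrom(sub, ci)
            chrom = own_genome[src_name].copy()
            for seg_sub, seg_ci, start, end in config.he_segments:
                if seg_sub == sub and seg_ci == ci:
                    chrom[start:end] = donor_genome[src_name][start:end]
                    he_intervals.append((name, start, end))
            names.append(name)
            seqs[name] = _mutate(chrom, config.subgenome_drift, rng)
            labels[name] = sub
    hybrid = Genome(HYBRID_ID, names, seqs, labels)
    return hybrid, SimTruth(he_intervals=sorted(he_intervals))


def simulate_reads(genome: Genome, config: SimConfig) -> PairedReads:
    """Error-free converging mate pairs at the configured coverage.

    Inserts are Normal(insert_mean, insert_sd) truncated to at least two
    read lengths; fragment starts are uniform. Mate 1 is the forward or
    reverse mate with equal probability.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng([config.seed, 3])
    L = config.read_length
    r1_parts, r2_parts = [], []
    t_chrom, t_s1, t_s2 = [], [], []
    span = np.arange(L, dtype=np.int64)
    for ci, name in enumerate(genome.names):
        codes = genome[name]
        length = codes.size
        min_insert = 2 * L
        if length < min_insert:
            raise ValueError(f"chromosome {name} shorter than one insert")
        n_pairs = int(round(config.coverage * length / (2 * L)))
        inserts = rng.normal(config.insert_mean, config.insert_sd, n_pairs)
        inserts = np.clip(np.rint(inserts), min_insert, length).astype(np.int64)
        starts = rng.integers(0, length - inserts + 1)
        fwd = codes[starts[:, None] + span]
        rev_start = starts + inserts - L
        rev = 3 - codes[rev_start[:, None] + span][:, ::-1]
        swap = rng.random(n_pairs) < 0.5
        r1 = np.where(swap[:, None], rev, fwd)
        r2 = np.where(swap[:, None], fwd, rev)
        r1_parts.append(r1.astype(np.uint8))
        r2_parts.append(r2.astype(np.uint8))
        t_chrom.append(np.full(n_pairs, ci, dtype=np.int64))
        t_s1.append(starts)
        t_s2.append(rev_start)
    return PairedReads(
        np.vstack(r1_parts), np.vstack(r2_parts),
        np.concatenate(t_chrom), np.concatenate(t_s1), np.concatenate(t_s2),
    )


def _gene_anchors(config: SimConfig) -> list[int]:
    last = config.chromosome_length - max(config.gene_length, config.protein_nt)
    return list(range(config.gene_spacing, last, config.gene_spacing))


def _translate(codes: np.ndarray) -> str:
    return str(Seq(decode(codes)).translate()).replace("*", "X")


def simulate_proteins(
    ancestor_a: Genome,
    ancestor_f: Genome,
    hybrid: Genome,
    config: SimConfig,
    truth: SimTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Anchored hybrid proteins with identities to both ancestors.

    Genes sit at regular anchors; each hybrid protein is translated from
    its local (possibly HE-swapped) sequence, and identity against the
    translation of the corresponding ancestral stretch is computed with
    the package's global aligner. Returns (protein table, gene truth
    table); truth records each gene's ancestral origin.
    """
    anchors = _gene_anchors(config)
    he_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in truth.he_intervals:
        he_by_chrom.setdefault(chrom, []).append((s, e))
    rows, truth_rows = [], []
    nt = config.protein_nt
    for name in hybrid.names:
        sub = hybrid.label(name)
        src = "chr" + name.split("chr")[1].split("_")[0]
        for gi, anchor in enumerate(anchors):
            pid = f"{name}_g{gi}"
            prot = _translate(hybrid[name][anchor:anchor + nt])
            prot_a = _translate(ancestor_a[src][anchor:anchor + nt])
            prot_f = _translate(ancestor_f[src][anchor:anchor + nt])
            in_he = any(s <= anchor < e for s, e in he_by_chrom.get(name, []))
            origin = ("f" if sub == "a" else "a") if in_he else sub
            rows.append({
                "protein_id": pid, "chromosome": name, "anchor": anchor,
                "iaa_a": pairwise_identity(prot, prot_a),
                "iaa_f": pairwise_identity(prot, prot_f),
            })
            truth_rows.append({
                "gene_id": pid, "chromosome": name, "anchor": anchor,
                "origin": origin, "in_he": in_he,
            })
    proteins = pd.DataFrame(rows)
    genes = pd.DataFrame(truth_rows)
    return proteins, genes


def simulate_rna_tracks(
    hybrid: Genome, genes: pd.DataFrame, config: SimConfig
) -> dict[str, dict[str, np.ndarray]]:
    """Per-dataset aligned-interval sets emulating mapped RNA coverage.

    The hybrid species is represented by several accessions, each capturing
    an expressed gene with probability ``accession_capture``; ancestor
    datasets cover expressed genes whose local origin matches their own
    genome (HE-swapped genes are covered by the homoeologous ancestor's
    reads). Returned as dataset -> chromosome -> (n, 2) interval arrays.
    """
    rng = np.random.default_rng([config.seed, 4])
    expressed = rng.random(len(genes)) < config.expressed_fraction
    gene_iv = np.column_stack([
        genes["anchor"].to_numpy(),
        np.minimum(genes["anchor"].to_numpy() + config.gene_length,
                   [hybrid.length(c) for c in genes["chromosome"]]),
    ])
    tracks: dict[str, dict[str, np.ndarray]] = {}

    def collect(mask: np.ndarray) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name in hybrid.names:
            sel = mask & (genes["chromosome"] == name).to_numpy()
            out[name] = gene_iv[sel]
        return out

    for acc in range(config.n_hybrid_rna_accessions):
        captured = expressed & (rng.random(len(genes)) < config.accession_capture)
        tracks[f"hybrid_acc{acc + 1}"] = collect(captured)
    origin = genes["origin"].to_numpy()
    tracks["ancestor_a_rna"] = collect(expressed & (origin == "a"))
    tracks["ancestor_f_rna"] = collect(expressed & (origin == "f"))
    return tracks


def default_ltr_spec() -> list[dict]:
    """Planted LTR complement: per genome pair, a shared youngest element
    whose left-right LTR identity matches the corresponding value observed
    for sour cherry, plus older shared and private elements to make
    "youngest shared" a real minimum and to exercise collinearity."""
    spec: list[dict] = []

    def plant(pair_id, genome1, genome2, family, identity, chrom="chr1", pos=100_000):
        for g in (genome1, genome2):
            spec.append({
                "genome": g, "chromosome": chrom, "position": pos,
                "family": family, "identity": identity, "pair": pair_id,
            })

    # youngest shared elements, one per genome pair
    plant("a_vs_A", "hybrid_a", ANCESTOR_A_ID, "Gypsy_G1", 0.9984, pos=200_000)
    plant("f_vs_F", "hybrid_f", ANCESTOR_F_ID, "Gypsy_G1", 0.9985, pos=200_000)
    plant("A_vs_F", ANCESTOR_A_ID, ANCESTOR_F_ID, "Copia_C1", 0.9982, pos=400_000)
    plant("a_vs_f", "hybrid_a", "hybrid_f", "Copia_C2", 0.9970, pos=600_000)
    plant("A_vs_f", ANCESTOR_A_ID, "hybrid_f", "Gypsy_G2", 0.9968, pos=800_000)
    plant("F_vs_a", ANCESTOR_F_ID, "hybrid_a", "Gypsy_G3", 0.9977, pos=1_000_000)
    # older shared elements so the youngest is a strict minimum
    plant("a_vs_A_old", "hybrid_a", ANCESTOR_A_ID, "Gypsy_G1", 0.9960, pos=1_400_000)
    plant("f_vs_F_old", "hybrid_f", ANCESTOR_F_ID, "Copia_C1", 0.9955, pos=1_600_000)
    plant("A_vs_F_old", ANCESTOR_A_ID, ANCESTOR_F_ID, "Gypsy_G2", 0.9950, pos=1_800_000)
    plant("a_vs_f_old", "hybrid_a", "hybrid_f", "Gypsy_G3", 0.9945, pos=2_000_000)
    plant("A_vs_f_old", ANCESTOR_A_ID, "hybrid_f", "Copia_C2", 0.9940, pos=2_200_000)
    plant("F_vs_a_old", ANCESTOR_F_ID, "hybrid_a", "Copia_C1", 0.9935, pos=2_400_000)
    # private elements (matched by nothing)
    for g, ident, pos in (
        (ANCESTOR_A_ID, 0.9991, 2_800_000),
        (ANCESTOR_F_ID, 0.9910, 3_000_000),
        ("hybrid_a", 0.9881, 3_200_000),
        ("hybrid_f", 0.9872, 3_400_000),
    ):
        spec.append({"genome": g, "chromosome": "chr1", "position": pos,
                     "family": f"Private_{g}", "identity": ident, "pair": None})
    return spec


# logical LTR genome ids -> (genome_id, chromosome renamer) for the hybrid,
# where elements live on subgenome-labelled chromosomes
def _ltr_target(genome_key: str, chromosome: str) -> tuple[str, str]:
    if genome_key == "hybrid_a":
        return HYBRID_ID + "_a", f"{chromosome}_a"
    if genome_key == "hybrid_f":
        return HYBRID_ID + "_f", f"{chromosome}_f"
    return genome_key, chromosome


def simulate_ltrs(config: SimConfig) -> tuple[dict[str, list[LTRElement]], pd.DataFrame]:
    """Materialise the planted LTR spec as per-genome element lists plus a
    truth table. Element length is fixed (8 kb); overlap is rejected."""
    spec = config.ltr_spec or default_ltr_spec()
    per_genome: dict[str, list[LTRElement]] = {}
    truth_rows = []
    for entry in spec:
        if int(entry["position"]) + 8_000 > config.chromosome_length:
            raise ValueError(
                f"LTR element at {entry['position']} exceeds chromosome "
                f"length {config.chromosome_length}")
        gid, chrom = _ltr_target(entry["genome"], entry["chromosome"])
        el = LTRElement(
            genome_id=gid, chromosome=chrom,
            start=int(entry["position"]), end=int(entry["position"]) + 8_000,
            family=entry["family"], identity=float(entry["identity"]),
        )
        per_genome.setdefault(gid, []).append(el)
        truth_rows.append({**entry, "genome_id": gid, "chromosome_out": chrom})
    for gid, els in per_genome.items():
        els.sort(key=lambda e: (e.chromosome, e.start))
        for e1, e2 in zip(els, els[1:]):
            if e1.chromosome == e2.chromosome and e2.start < e1.end:
                raise ValueError(f"overlapping LTR elements in {gid}")
    return per_genome, pd.DataFrame(truth_rows)


def write_universe(outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Generate and write the full synthetic universe to ``outdir``.

    Writes ancestor and hybrid FASTA, paired FASTQ of the hybrid, RNA
    bedGraph tracks, the protein identity TSV, per-genome LTR pass lists,
    truth BED/TSVs and a manifest of parameters and file checksums.
    """
    import hashlib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    anc_a, anc_f = simulate_ancestors(config)
    hybrid, truth = simulate_hybrid(anc_a, anc_f, config)
    for g, key in ((anc_a, "ancestor_a"), (anc_f, "ancestor_f"), (hybrid, "hybrid")):
        paths[key] = outdir / f"{key}.fasta"
        g.to_fasta(paths[key])
    paths["hybrid_layout"] = outdir / "hybrid_layout.tsv"
    hybrid.layout().to_tsv(paths["hybrid_layout"])

    reads = simulate_reads(hybrid, config)
    paths["reads_1"] = outdir / "hybrid_R1.fastq"
    paths["reads_2"] = outdir / "hybrid_R2.fastq"
    reads.to_fastq(paths["reads_1"], paths["reads_2"])

    proteins, genes = simulate_proteins(anc_a, anc_f, hybrid, config, truth)
    truth.gene_table = genes
    paths["proteins"] = outdir / "proteins_iaa.tsv"
    proteins.to_csv(paths["proteins"], sep="\t", index=False)
    paths["genes_truth"] = outdir / "genes_truth.tsv"
    genes.to_csv(paths["genes_truth"], sep="\t", index=False)

    tracks = simulate_rna_tracks(hybrid, genes, config)
    grid = make_windows(hybrid.layout(), 250_000)
    for dataset, intervals in tracks.items():
        p = outdir / f"rna_{dataset}.bedgraph"
        with open(p, "w") as fh:
            for chrom in hybrid.names:
                for s, e in intervals.get(chrom, []):
                    fh.write(f"{chrom}\t{s}\t{e}\t1\n")
        paths[f"rna_{dataset}"] = p

    ltrs, ltr_truth = simulate_ltrs(config)
    truth.ltr_truth = ltr_truth
    for gid, els in ltrs.items():
        p = outdir / f"ltr_{gid}.pass.list"
        write_pass_list(els, p)
        paths[f"ltr_{gid}"] = p

    paths["he_truth"] = outdir / "he_truth.bed"
    truth.he_bed(paths["he_truth"])

    manifest = {
        "config": asdict(config),
        "checksums": {
            key: hashlib.sha256(p.read_bytes()).hexdigest()
            for key, p in sorted(paths.items())
        },
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = mpath
    return paths
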