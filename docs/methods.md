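# Methods

## Problem and model

A segmental allotetraploid carries two distinguishable subgenomes — here
labelled *a* (sweet-cherry derived) and *f* (ground-cherry derived) — but
parts of its genome behave autopolyploid-like because segments of one
subgenome have been replaced by the homoeologous copy from the other.
These homoeologous exchanges (HEs) arise through duplication–deletion
events: the replaced segment is lost and the donor segment is present in
two copies, one on each subgenome. `allohe` detects such segments by
requiring the agreement of three independent, windowed evidence tracks,
and separately dates LTR retrotransposon insertions to constrain when the
two ancestral gene pools last mixed.

### Genomic evidence (100-kb windows)

Paired short reads of the hybrid are mapped to both ancestral genomes,
filtered to properly paired primary alignments (SAM `-f 3 -F 2304`
semantics) and partitioned at fragment level into four classes:
unique-to-ancestor-A, unique-to-ancestor-F, both, neither. "Matching a
genome" requires both mates of a fragment to align in a proper pair,
consistent with the proper-pair filter; uniqueness is across genomes, not
loci. The two unique sets are re-mapped onto the hybrid and the fraction
of bases covered at depth ≥ 1 is computed per 100-kb window. A
subgenome-*a* window is flagged when coverage by the A-unique set
(intraspecific) is strictly lower than coverage by the F-unique set
(interspecific); mirrored for subgenome *f*. Equal coverages are not
flagged, and windows with zero coverage from both sets are marked no-data
rather than flagged.

### Transcriptomic evidence (250-kb windows)

RNA-seq of the hybrid species (several accessions pooled by base-level
union, i.e. a base counts as covered if covered in any accession) and of
each ancestral species is mapped onto the hybrid; fraction-covered at
depth ≥ 1 is computed per 250-kb window. Signed deltas
Δ_A = cov(hybrid) − cov(ancestor A) and Δ_F analogous are formed; in an
unexchanged subgenome-*a* window the intraspecific delta Δ_A sits near 0
while Δ_F is large. A window is flagged when the intraspecific delta
strictly exceeds the interspecific one.

### Protein evidence (250-kb windows, 1-Mb confirmation)

Each predicted hybrid protein carries a percent amino-acid identity to
its best homolog in each ancestral annotation (IAA). Per 250-kb window,
the percentages of proteins more similar to A, more similar to F, and
tied are computed over assigned proteins (they close to 100 %); a
subgenome-*a* window is flagged when the F-leaning percentage exceeds the
A-leaning one. A protein is anchored to the window containing its
coding-region start. As supplementary annotation, the 70 % quantile
(linear interpolation between order statistics at rank 0.7·(n−1)) of
identity to the homoeologous versus homologous ancestor is compared in
1-Mb windows; a call is "confirmed" when any overlapping 1-Mb window has
q70(homoeologous) > q70(homologous). Confirmation is annotation, not a
fourth AND-criterion, because windows shorter than ~1 Mb of exchange
cannot dominate the quantile.

### Intersection and calling

The 100-kb genomic flags are lifted to the 250-kb grid by overlap
("any overlapping flagged window" by default; "all" is available and
strictly more conservative). Windows flagged by all three tracks qualify;
maximal runs of adjacent qualifying windows merge into one directed HE
region (direction: replaced by the other subgenome). Calls are scored
against planted truth using ≥ 50 % reciprocal overlap.

### LTR insertion dating

The two long terminal repeats of a retrotransposon are identical at
insertion; their divergence K = 1 − identity dates the insertion as
T = K/(2µ) generations, with µ = 7.7×10⁻⁹ substitutions · site⁻¹ ·
generation⁻¹ (a *Prunus*-specific rate). Because generation time in
long-lived trees is uncertain, calendar ages are reported as a sweep over
10–60 years per generation (Mya = T · years / 10⁶). Shared elements
between two (sub)genomes are pairs of equal family whose identities agree
within a tolerance (default 10⁻⁴, ≈ 6,494 generations at the default µ)
and that occur in the same positional order; order is enforced as a
maximum-cardinality collinear matching per homoeologous chromosome pair,
computed by LCS-style dynamic programming over compatible pairs. With the
order constraint off, a maximum bipartite matching is used instead, so
relaxing the constraint never reduces the number of matches.

## Synthetic data generator

The generator emulates the inputs of a real analysis with exact ground
truth. A common random root sequence is substituted independently on two
branches at divergence/2 each (3 % total by default — substitutions only,
no indels, so coordinates remain shared). The hybrid takes subgenome *a*
from ancestor A and *f* from F, plants unidirectional duplication–
deletion HEs by copying the homoeologous ancestral segment in place, then
applies independent 0.2 % drift to every chromosome, so the two copies of
an exchanged segment subsequently diverge. Reads are error-free 150-bp
pairs with Normal(550, 50) inserts (truncated at two read lengths) at
20× coverage. Genes sit every 50 kb; each hybrid protein is translated
from its local (possibly HE-swapped) 300-nt stretch and aligned to the
corresponding ancestral translations, so identities follow from the
substitution process rather than being assigned. RNA tracks cover
expressed genes (90 % expressed; three hybrid accessions each capture an
expressed gene with probability 0.8) routed to the ancestor matching each
gene's local origin. LTR pass lists carry planted families, positions and
left–right identities; the shipped complement plants, per genome pair, a
youngest shared element whose identity matches the value observed in the
sour cherry study, plus older shared and private elements.

The shipped study configuration is two 5-Mb chromosomes per subgenome
with six HEs of 0.5–2 Mb snapped to 250-kb boundaries — scaled down from
a real ~600-Mb genome so a full run fits in about a minute of CPU while
every per-window statistic still operates at the real window sizes.
Snapping makes expected flagged-window sets exact; an off-grid breakpoint
would only smear the boundary window of each call.

What the generator does not model — and what passing tests therefore do
not show about real data: sequencing error, indels and structural
variants other than HEs, repeat-driven multi-mapping beyond the planted
duplications, annotation error in the protein tables, spliced RNA
alignment artefacts, and assembly error (a real signal mimicking HE).

## Numerical and design choices

- Coordinates are 0-based half-open everywhere internally; SAM input is
  converted at the boundary; BED/bedGraph output is 0-based half-open.
- Window sizes "250k/100k/1 Mb" are exactly 250,000 / 100,000 /
  1,000,000 bp. Trailing partial windows are kept, normalised by their
  true length, so chromosome ends are not blind.
- The built-in mapper is exact matching for error-free synthetic reads
  (31-mer seed + full-length verification; complete because a full-length
  match implies a matching seed). Real data enter as SAM/BAM. Primary
  placement is the lexicographically smallest (chromosome, forward-mate
  start) converging placement with insert between one read length and
  2,000 bp; only primaries contribute to coverage.
- Protein identity uses global alignment with match +1 / mismatch 0 /
  linear gap −1; identity = 100 · matches / alignment columns. Score ties
  are broken by maximal matches, then minimal alignment length, making
  the value deterministic; the DP packs the lexicographic objective into
  one integer per cell.
- Tie handling: IAA ties use an epsilon of 0 (exact equality) by default,
  configurable; strict inequalities everywhere a track is flagged.
- Degenerate inputs: empty windows are no-data and never flagged; empty
  pass lists return empty element sets with a warning; malformed
  pass-list rows are skipped and counted.

## Limitations

Breakpoints are resolved only to window granularity. The pipeline assumes
subgenome labels are known per chromosome. The equality of the published
regional counts cannot be checked without the original sequencing data;
the synthetic acceptance instead verifies that the method recovers
planted exchanges with recall and precision ≥ 0.9 under the shipped
configuration. Whether a called region reflects biology or assembly error
is out of scope.
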