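# Methods

## Model

The assembler treats haplotype reconstruction as read clustering under a
learned similarity kernel. Its assumptions: reads are aligned to a
reference and reduced to called heterozygous SNP columns; sequencing errors
are substitutions at SNP sites (indels are out of scope); the ploidy k is
known; and every adjacent pair of SNPs in a phasing block is bridged by at
least one fragment — where that fails the problem is split into blocks,
because no data constrains the relative phase across the gap.

The measured correlation `C_ij = (k_sim − k_dissim)/(k_sim + k_dissim)`
is only defined for overlapping pairs; the encoder's job is to produce a
complete kernel Σ that agrees with C on its support and extrapolates the
polarity to non-overlapping pairs through chains of overlaps. Three forces
shape Σ during training: the contrastive loss pulls same-cluster pairs
toward +1 and cross-cluster pairs toward −1 given the current assignment;
the consistency term `λ_r‖Ω_C(Σ−C)‖_F` anchors Σ to the data; the sparsity
term `λ_s Σ|Σ_ij|` damps spurious off-diagonal mass. Because Σ = Q̃Q̃ᵀ with
unit-norm rows, Σ is symmetric positive semi-definite with unit diagonal by
construction — a valid kernel for kernel k-means.

## Architecture and numerics

The encoder follows the fixed architecture: conv layers with kernels
(4,5)/(1,5)/(1,3) and filters (32,64,128) — the first kernel consumes the
4-channel nucleotide axis, so layers run as 1-D convolutions along the SNP
axis with "same" padding (keeping the flatten size at l × filters) — then
a dense layer to d_r=128, three transformer encoder layers (4 heads,
post-norm residual blocks, position-wise feed-forward of width 4·d_r,
ReLU), and a dense head to d_q = d_r/2. Reduced models scale the filter
counts as (d_r/4, d_r/2, d_r). No positional encodings are added: row
order in the fragment matrix is arbitrary and attention should stay
permutation-equivariant. Rows of the head output with L2 norm below 1e-8
are left at zero rather than normalized; the diagonal of Σ is pinned to
exactly 1 (it carries no training signal: the losses exclude it).

The network and its gradients run on a purpose-built reverse-mode autodiff
engine over numpy arrays (`_autodiff.py`) with fused primitives for the
convolution (im2col + GEMM), softmax, PReLU and layer normalization; every
primitive is validated against central finite differences in the test
suite, and an end-to-end gradient check on the full loss is part of the
acceptance tests. All computation is float64; determinism is exact for a
fixed master seed (two runs produce bit-identical haplotypes).

Loss conventions where the formulas leave latitude: the contrastive sum
runs over unordered pairs i<j (a factor of two is absorbed by the learning
rate); the consistency norm is Frobenius (a small 1e-24 floor inside the
square root keeps its gradient finite at zero); the sparsity sum counts
both orderings of each off-diagonal pair.

## Training schedule

Defaults follow the full-scale configuration: Adam (β₁=0.9, β₂=0.999,
ε=1e-8) at learning rate 1e-5, batch size ⌈n/5⌉, 2000 epochs, λ_r=100,
λ_s=10, 5 restarts selected by lowest MEC with ties broken by lower final
loss. Each epoch runs one pass of mini-batch updates with the pair
indicator frozen from the previous epoch (loss pairs restricted to reads
inside the same batch), then recomputes Σ on all reads and refreshes the
assignment by kernel k-means. The epoch-0 assignment comes from kernel
k-means on the measured correlations (a data-driven warm start; a purely
random initialization is available via `warm_start_clustering=False`).
Per-epoch clustering refreshes are warm-started from the previous
assignment plus two random restarts; the full 10-restart clustering is
used at initialization and after the final epoch, where it matters. The
final epoch's assignment is returned; the per-epoch history (loss, MEC)
is recorded so the best epoch remains inspectable.

Kernel k-means minimizes the within-cluster kernel distance
`K_ii − 2/|c|·Σ_{j∈c} K_ij + 1/|c|²·Σ_{j,j'∈c} K_jj'`; empty clusters are
reseeded with the point farthest from its current centroid; all restarts
iterate simultaneously (vectorised over a restart axis). Numerically
indefinite kernels (the measured C, or Σ after float round-off) are
repaired by clipping negative eigenvalues at zero before clustering.
Cluster labels are 0-based internally, following scikit-learn conventions.

Consensus calling: per cluster and column the majority allele among
covering reads wins; ties break by the allele's coverage across all reads,
then by lexicographic base order; columns a cluster does not cover are
imputed from the global majority. This choice makes consensus
deterministic and MEC-non-increasing relative to any haplotype matrix that
induced the assignment.

## Long-range assembly

Ranges longer than `block_len` (default 250 SNPs) are tiled with spans
stepping by `block_len − overlap` (default overlap 50). Each block is
assembled independently (fragments covering fewer than 2 of its columns
dropped) and consecutive blocks are joined by the row permutation
minimizing Hamming distance over the shared overlap columns (exhaustive
over k!, ties to the lexicographically smallest permutation). In overlap
regions the earlier block's alleles win — deterministic and order-stable.
A block with no informative fragments is imputed from the global consensus
and starts a new phase set. Blocks are processed sequentially.

## The simulator

`simulate` emulates the semi-experimental benchmark data end to end:

* **Haplotypes** — SNP positions by cumulative log-normal spacing
  (log-mean 3.03, log-sd 1.293 for the short-read setting: mean spacing
  ≈48 bp, ≈200 variants per 10 kb; log-mean 6.07 for the long-read
  setting: ≈1 kb spacing, ≈100 variants per 100 kb). Each site draws a
  reference and one alternative base; haplotypes pick one of the two
  independently, redrawn until the site is heterozygous.
* **Reads** — fragment count = coverage × region / bases-per-fragment
  (500 for 2×250 bp paired-end fragments, mean 9000 bp for long reads,
  log-normal lengths with CV 0.3 — only the mean is fixed by the
  benchmark setting). Paired-end inserts are Normal(550, 10) with the
  intervening gap uncovered; starts are uniform; each fragment samples one
  haplotype uniformly; substitution errors hit covered SNP cells i.i.d.
  (0.1% short, 5% long, uniform over the three alternative bases). Errors
  at non-SNP bases never reach the fragment matrix, so they are not
  simulated.
* **Variant calling** — columns are re-called from the simulated reads at
  VAF ≥ 0.2 among covering reads, and the ground truth is restricted to
  called columns. This mirrors the real pipeline (align, call, reduce) and
  removes edge columns that only one haplotype's reads sample — sites a
  variant caller could never see. No mapping- or base-quality filters are
  applied.
* **Bridgeability** — `make_dataset` caps individual spacing draws
  (450 bp short, half the mean read length long; rejection sampling) so
  every adjacent SNP pair can be bridged by some fragment. The benchmark
  datasets this emulates are single phasing blocks throughout; without the
  cap, a heavy-tailed spacing draw occasionally makes a scaled-down region
  unphaseable as one block, which measures data luck rather than assembly
  quality. `generate_haplotypes` keeps the raw, uncapped model, and the
  spacing-statistics checks are computed on it.

What the simulator does not model: alignment and mapping ambiguity (reads
are placed at their true positions), indels, quality scores, chimeric
reads, and non-uniform error profiles of real instruments. Tests passing
on this data show the optimization and metrics behave as specified under
the stated noise model; they do not certify performance on real libraries
with alignment artefacts.

## Problem sizes used in tests and the acceptance script

The full-scale configuration (10 kb / ~200 SNPs / 600 fragments, d_r=128,
2000 epochs) is the library default. The shipped end-to-end checks run a
scaled-down version of the diploid 30× short-read experiment — a ~2.4 kb
region (~50 SNPs, ~144 fragments), the d_r=32 encoder, 500 epochs —
chosen so a full 5-dataset × 5-restart replication completes in minutes on
one CPU while exercising every stage of the pipeline. On this
configuration the assembler reaches mean CPR ≥ 0.99 with SWER ≈ 0 at 0.1%
error, and exact recovery (MEC 0, CPR 1) on error-free data.

## Known limitations

* CPR and the stitch search are exhaustive over k! mappings and practical
  for k ≤ 6-8; higher ploidies need heuristic matching, which is out of
  scope.
* SWER/VER per-column alignment resolves ambiguous columns (homozygous or
  mismatching) by inheriting the previous column's permutation, the
  standard convention; other conventions can differ on pathological
  inputs.
* Across a gap no fragment bridges, the relative phase of blocks is
  unidentifiable; the long-range stitcher reports separate phase sets
  rather than guessing.
* The alternating optimization is non-convex; restarts mitigate but do not
  eliminate stalls (hence best-of-5 by MEC, as in the full-scale
  configuration).
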