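"""Long-range assembly: overlapping blocks reconstructed and phased together.

For long SNP ranges the full read-fragment matrix is too large to train on
at once. The column range is tiled into blocks of ``block_len`` SNPs with
consecutive blocks overlapping by ``overlap`` SNPs; each block is assembled
independently and successive blocks are phased together by matching the
haplotypes over the shared overlap columns (best row permutation by Hamming
distance). Earlier blocks take precedence in overlap regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from . import metrics
from .assembly import AssemblyResult, TrainConfig, assemble, consensus_haplotypes
from .corrmodel import EncoderConfig
from .fragments import ReadFragmentMatrix

__all__ = ["BlockPlan", "plan_blocks", "stitch", "assemble_longrange"]


@dataclass
class BlockPlan:
    """Tiling of ``l`` SNP columns into overlapping half-open spans."""

    block_len: int = 250
    overlap: int = 50
    spans: list[tuple[int, int]] = None

    def __post_init__(self):
        if self.spans is None:
            self.spans = []


def plan_blocks(l: int, block_len: int = 250, overlap: int = 50) -> BlockPlan:
    """Tile [0, l) into spans stepping by ``block_len - overlap``.

    Consecutive spans overlap by exactly ``overlap`` columns except the last,
    which is truncated at ``l``; the union of spans covers every column.
    """
    if overlap >= block_len:
        raise ValueError("overlap must be smaller than block_len")
    if overlap < 0 or l < 1:
        raise ValueError("invalid plan parameters")
    spans: list[tuple[int, int]] = []
    start = 0
    while True:
        end = min(start + block_len, l)
        spans.append((start, end))
        if end >= l:
            break
        start += block_len - overlap
    return BlockPlan(block_len, overlap, spans)


def stitch(prev_overlap: np.ndarray, next_overlap: np.ndarray) -> tuple[int, ...]:
    """Best row permutation matching the next block onto the previous one.

    Returns the permutation ``perm`` (applied as ``next_block[perm, :]``)
    minimising the total Hamming distance between matched rows over the
    overlap columns; exhaustive over k! with ties broken by lexicographically
    smallest permutation.
    """
    prev_overlap = np.asarray(prev_overlap)
    next_overlap = np.asarray(next_overlap)
    if prev_overlap.shape != next_overlap.shape:
        raise ValueError("overlap matrices must have identical shape")
    k = prev_overlap.shape[0]
    best_perm, best_cost = None, None
    for perm in permutations(range(k)):  # sorted order => lexicographic ties
        cost = int((prev_overlap != next_overlap[list(perm)]).sum())
        if best_cost is None or cost < best_cost:
            best_perm, best_cost = perm, cost
    return best_perm


def assemble_longrange(m: ReadFragmentMatrix, k: int,
                       tcfg: TrainConfig | None = None,
                       ecfg: EncoderConfig | None = None,
                       plan: BlockPlan | None = None) -> AssemblyResult:
    """Assemble a long SNP range block by block and stitch the blocks.

    Each block restricts the matrix to its column span, drops fragments
    covering fewer than 2 of its columns, and runs the best-of-restarts
    assembler; the stitch permutation is applied cumulatively so the output
    is one full-length haplotype matrix. A block with no informative
    fragments (or an empty overlap) starts a new phase set: its columns are
    filled with the global consensus and ``phase_sets`` records the split.
    """
    tcfg = tcfg or TrainConfig()
    if plan is None:
        plan = plan_blocks(m.l)
    if not plan.spans:
        raise ValueError("empty block plan")
    if plan.spans[-1][1] < m.l or plan.spans[0][0] != 0:
        raise ValueError("plan does not span the fragment matrix")
    if len(plan.spans) == 1:
        result = assemble(m, k, tcfg, ecfg)
        result.phase_sets = [(0, m.l)]
        return result

    seeds = np.random.SeedSequence(tcfg.seed).spawn(len(plan.spans))
    H = np.zeros((k, m.l), dtype=np.int8)
    phase_sets: list[list[int]] = []
    history: dict[str, list] = {"block_mec": []}
    prev_end = -1  # end column of the last *phased* block; -1 = none yet
    for b, (lo, hi) in enumerate(plan.spans):
        cols = np.arange(lo, hi)
        sub = m.restrict_columns(cols)
        keep = sub.covered().sum(axis=1) >= 2
        if not keep.any():
            # unphased block: impute its columns with the all-read consensus
            # and force a phase-set split on both sides
            imputed = consensus_haplotypes(sub, np.zeros(m.n, dtype=np.int64), 1)
            H[:, lo:hi] = imputed[0]
            phase_sets.append([lo, hi])
            history["block_mec"].append(None)
            prev_end = -1
            continue
        sub = ReadFragmentMatrix(sub.entries[keep],
                                 [r for r, kk in zip(sub.read_ids, keep) if kk],
                                 sub.snp_positions)
        block_tcfg = TrainConfig(
            epochs=tcfg.epochs, learning_rate=tcfg.learning_rate,
            batch_size=tcfg.batch_size, restarts=tcfg.restarts,
            lambda_r=tcfg.lambda_r, lambda_s=tcfg.lambda_s,
            seed=int(seeds[b].generate_state(1)[0] % (2**31)),
        )
        local = assemble(sub, k, block_tcfg, ecfg).haplotypes
        history["block_mec"].append(metrics.mec(sub, local))
        if prev_end <= lo:
            # no (usable) overlap with a phased predecessor: new phase set
            phase_sets.append([lo, hi])
            H[:, lo:hi] = local
        else:
            w = prev_end - lo  # overlap width
            perm = stitch(H[:, lo:prev_end], local[:, :w])
            aligned = local[list(perm)]
            H[:, prev_end:hi] = aligned[:, w:]  # earlier block wins the overlap
            phase_sets[-1][1] = hi
        prev_end = hi
    haplotypes = H
    # attribute each read to its closest stitched haplotype
    cov = m.covered()
    dists = np.array([((m.entries != h) & cov).sum(axis=1) for h in haplotypes])
    labels = dists.argmin(axis=0)
    result = AssemblyResult(
        haplotypes=haplotypes,
        labels=labels,
        sigma=None,
        mec=metrics.mec(m, haplotypes),
        loss=float("nan"),
        history=history,
        phase_sets=[(a, b) for a, b in phase_sets if b > a],
    )
    return result
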