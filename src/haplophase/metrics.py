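"""Haplotype assembly evaluation metrics.

* MEC — minimum error correction: number of read bases that must change for
  every read to match its closest reconstructed haplotype (computable without
  ground truth).
* CPR — correct phasing rate: fraction of alleles recovered under the best
  one-to-one mapping between true and reconstructed haplotypes.
* SWER / VER — switch / vector error rate: fraction of adjacent SNP pairs
  whose relative phasing flips between truth and reconstruction (diploid /
  polyploid).

Haplotype matrices are (k, l) int8 arrays of base codes as produced by the
assembler; read matrices are :class:`~haplophase.fragments.ReadFragmentMatrix`.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from .fragments import ReadFragmentMatrix

__all__ = ["mec", "cpr", "swer", "ver", "best_mapping"]

_MAX_EXHAUSTIVE_K = 8


def mec(m: ReadFragmentMatrix, haplotypes: np.ndarray) -> int:
    """Minimum error correction score of reconstructed haplotypes.

    Per read, the Hamming distance to each haplotype is computed over the
    read's covered columns only; the score sums each read's distance to its
    closest haplotype. Invariant under row permutations of ``haplotypes``.
    """
    H = np.asarray(haplotypes)
    if H.shape[1] != m.l:
        raise ValueError("column counts of reads and haplotypes differ")
    cov = m.covered()
    # (k, n): mismatches of every read against every haplotype
    dists = np.array([((m.entries != h) & cov).sum(axis=1) for h in H])
    return int(dists.min(axis=0).sum())


def best_mapping(truth: np.ndarray, pred: np.ndarray) -> tuple[tuple[int, ...], int]:
    """Best one-to-one row mapping of ``pred`` onto ``truth``.

    Returns ``(perm, distance)`` where ``pred[perm, :]`` minimises the total
    Hamming distance to ``truth`` over all k! mappings (exhaustive; k <= 8).
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("haplotype matrices must have identical shape")
    k = truth.shape[0]
    if k > _MAX_EXHAUSTIVE_K:
        raise ValueError("ploidy > 8: use heuristic matching (out of scope)")
    # pairwise Hamming distances between all (true, predicted) row pairs
    hd = np.array([[int((t != p).sum()) for p in pred] for t in truth])
    best_perm, best_cost = None, None
    for perm in permutations(range(k)):
        cost = sum(hd[i, perm[i]] for i in range(k))
        if best_cost is None or cost < best_cost:
            best_perm, best_cost = perm, cost
    return best_perm, int(best_cost)


def cpr(truth: np.ndarray, pred: np.ndarray) -> float:
    """Correct phasing rate: 1 - (best-mapping Hamming distance) / (k*l)."""
    truth = np.asarray(truth)
    _, dist = best_mapping(truth, pred)
    k, l = truth.shape
    return 1.0 - dist / (k * l)


def _column_permutations(truth: np.ndarray, pred: np.ndarray) -> list[tuple[int, ...]]:
    """Per-column alignment permutation of pred rows onto truth rows.

    For each column the permutation maximising allele agreement is chosen;
    columns where the best permutation is not unique (homozygous truth
    columns, or mismatching alleles) inherit the previous column's
    permutation so they can never register as switches.
    """
    k, l = truth.shape
    perms = list(permutations(range(k)))
    chosen: list[tuple[int, ...]] = []
    current = None
    for j in range(l):
        scores = [sum(truth[i, j] == pred[p[i], j] for i in range(k)) for p in perms]
        top = max(scores)
        best = [p for p, s in zip(perms, scores) if s == top]
        if len(best) == 1:
            current = best[0]
        elif current is None:
            current = best[0]  # leading ambiguous columns: lexicographic
        chosen.append(current)
    return chosen


def ver(truth: np.ndarray, pred: np.ndarray) -> float:
    """Vector error rate: adjacent-column changes of the aligning permutation.

    The per-column permutation matching predicted to true haplotypes is
    tracked along the columns; VER is the fraction of the l-1 adjacent
    column pairs at which it changes. For k=2 this is the switch error rate.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("haplotype matrices must have identical shape")
    k, l = truth.shape
    if l < 2:
        raise ValueError("need at least 2 SNP columns")
    if k > _MAX_EXHAUSTIVE_K:
        raise ValueError("ploidy > 8: use heuristic matching (out of scope)")
    perms = _column_permutations(truth, pred)
    switches = sum(perms[j] != perms[j - 1] for j in range(1, l))
    return switches / (l - 1)


def swer(truth: np.ndarray, pred: np.ndarray) -> float:
    """Diploid switch error rate (VER restricted to k=2)."""
    truth = np.asarray(truth)
    if truth.shape[0] != 2:
        raise ValueError("SWER is defined for diploids; use ver() for k > 2")
    return ver(truth, pred)
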