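"""Alternating optimization: train the correlation model, re-cluster, repeat.

Each epoch (1) runs one pass of Adam mini-batch updates on the encoder,
minimising the contrastive + consistency + sparsity loss with the pair
indicator frozen from the previous epoch's cluster assignment, then (2)
recomputes the learned kernel Sigma on all reads and refreshes the
assignment with kernel k-means. Haplotypes are the per-cluster consensus;
the run (or the best of several restarts, by MEC) is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics
from .cluster import KernelKMeans, psd_clip
from .corrmodel import (
    CorrelationEncoder,
    EncoderConfig,
    measured_correlations,
    pair_indicator,
    total_loss,
)
from .fragments import ReadFragmentMatrix, one_hot

__all__ = [
    "TrainConfig",
    "AssemblyResult",
    "HaplotypeAssembler",
    "consensus_haplotypes",
    "fit",
    "assemble",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults are the full-scale settings).

    ``batch_size=None`` resolves to ceil(n/5) at fit time. ``restarts`` is
    the number of independently initialised runs, of which the one with the
    lowest MEC is kept.
    """

    epochs: int = 2000
    learning_rate: float = 1e-5
    batch_size: int | None = None
    restarts: int = 5
    lambda_r: float = 100.0
    lambda_s: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        if self.epochs < 0 or self.learning_rate <= 0 or self.restarts < 1:
            raise ValueError("epochs, learning_rate and restarts must be positive")


@dataclass
class AssemblyResult:
    """Output of a (possibly multi-restart) assembly run."""

    haplotypes: np.ndarray            # (k, l) int8 base codes
    labels: np.ndarray                # (n,) cluster assignment in {0..k-1}
    sigma: np.ndarray | None          # learned read-correlation kernel
    mec: int
    loss: float
    history: dict[str, list] = field(default_factory=dict)
    phase_sets: list[tuple[int, int]] | None = None  # set by long-range assembly


def consensus_haplotypes(m: ReadFragmentMatrix, labels: np.ndarray,
                         k: int | None = None) -> np.ndarray:
    """Majority-vote consensus haplotype per cluster.

    Per cluster and column the majority allele among covering reads wins;
    ties go to the allele with the higher coverage across *all* reads, then
    to lexicographic base order. Columns with no covering read in a cluster
    are imputed with the global majority allele.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != m.n:
        raise ValueError("labels must cover every fragment row")
    if k is None:
        k = int(labels.max()) + 1
    counts = np.zeros((k, 4, m.l))
    gcounts = np.zeros((4, m.l))
    for b in range(4):
        hits = (m.entries == b)
        gcounts[b] = hits.sum(axis=0)
        for c in range(k):
            counts[c, b] = hits[labels == c].sum(axis=0)
    # lexicographic scoring: cluster count >> global count >> base order (A first)
    base_bonus = (3 - np.arange(4))[:, None] * 1e-3
    key = counts * 1e9 + gcounts[None] * 10.0 + base_bonus[None]
    return key.argmax(axis=1).astype(np.int8)


class HaplotypeAssembler(BaseEstimator):
    """Reconstruct k haplotypes from a read-fragment matrix.

    scikit-learn style estimator: ``fit`` runs ``n_restarts`` independent
    alternating-optimization runs and keeps the one with the lowest MEC
    (ties broken by lower final loss).

    Parameters
    ----------
    ploidy : int
        Number of haplotypes k (>= 2).
    epochs, learning_rate, batch_size, lambda_r, lambda_s :
        Training hyperparameters; see :class:`TrainConfig` for defaults and
        meaning. ``batch_size=None`` means ceil(n/5).
    n_restarts : int
        Independent random initialisations; best kept by MEC.
    encoder_config : EncoderConfig or None
        Architecture; None selects the full-size default.
    cluster_restarts : int
        Random restarts of the initial / final kernel k-means.
    epoch_cluster_restarts : int
        Random restarts added to the warm-started per-epoch clustering
        refresh during training.
    warm_start_clustering : bool
        If False, the epoch-0 assignment is random instead of kernel
        k-means on the measured correlations.
    random_state : int or None
        Master seed; every source of randomness derives from it.

    Attributes
    ----------
    haplotypes_ : (k, l) int8 array of reconstructed haplotype alleles.
    labels_ : (n,) read-to-haplotype assignment.
    sigma_ : (n, n) learned correlation kernel of the selected run.
    mec_ : int, MEC of the selected run.
    loss_ : float, final total loss of the selected run.
    history_ : dict with per-epoch "loss" and "mec" of the selected run.
    result_ : :class:`AssemblyResult` of the selected run.
    """

    def __init__(self, ploidy: int = 2, epochs: int = 2000,
                 learning_rate: float = 1e-5, batch_size: int | None = None,
                 n_restarts: int = 5, lambda_r: float = 100.0,
                 lambda_s: float = 10.0, encoder_config: EncoderConfig | None = None,
                 cluster_restarts: int = 10, epoch_cluster_restarts: int = 2,
                 warm_start_clustering: bool = True, random_state: int | None = None):
        self.ploidy = ploidy
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_restarts = n_restarts
        self.lambda_r = lambda_r
        self.lambda_s = lambda_s
        self.encoder_config = encoder_config
        self.cluster_restarts = cluster_restarts
        self.epoch_cluster_restarts = epoch_cluster_restarts
        self.warm_start_clustering = warm_start_clustering
        self.random_state = random_state

    # -- single alternating-optimization run ---------------------------------
    def _run_once(self, m: ReadFragmentMatrix, rng: np.random.Generator,
                  verbose: bool = False) -> AssemblyResult:
        k = self.ploidy
        n = m.n
        ecfg = self.encoder_config or EncoderConfig()
        reads = one_hot(m)
        C = measured_correlations(m)
        C_repaired = psd_clip(C)
        if self.warm_start_clustering:
            km = KernelKMeans(n_clusters=k, n_init=self.cluster_restarts,
                              random_state=rng)
            labels = km.fit(C_repaired).labels_
        else:
            labels = rng.integers(0, k, size=n)
            labels[rng.permutation(n)[:k]] = np.arange(k)
        model = CorrelationEncoder(ecfg, m.l, rng)
        opt = model.make_optimizer(lr=self.learning_rate)
        bs = self.batch_size or math.ceil(n / 5)
        history: dict[str, list] = {"loss": [], "mec": []}
        init_mec = metrics.mec(m, consensus_haplotypes(m, labels, k))
        sigma = None
        for epoch in range(self.epochs):
            p = pair_indicator(labels)
            order = rng.permutation(n)
            for lo in range(0, n, bs):
                batch = order[lo : lo + bs]
                if batch.size < 2:
                    continue
                sigma_b = model.forward(reads[batch])
                loss_t = total_loss(sigma_b, C[np.ix_(batch, batch)],
                                    p[np.ix_(batch, batch)],
                                    self.lambda_r, self.lambda_s)
                if not np.isfinite(loss_t.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                opt.zero_grad()
                loss_t.backward()
                opt.step()
            sigma = model.sigma(reads)
            last_restarts = epoch == self.epochs - 1
            n_extra = self.cluster_restarts if last_restarts else self.epoch_cluster_restarts
            km = KernelKMeans(n_clusters=k, n_init=1 + n_extra, random_state=rng)
            labels = km.fit(psd_clip(sigma), init_labels=labels).labels_
            epoch_loss = total_loss(sigma, C, pair_indicator(labels),
                                    self.lambda_r, self.lambda_s)
            epoch_mec = metrics.mec(m, consensus_haplotypes(m, labels, k))
            history["loss"].append(epoch_loss)
            history["mec"].append(epoch_mec)
            if verbose:
                print(f"epoch {epoch + 1}/{self.epochs}  loss={epoch_loss:.3f}  "
                      f"mec={epoch_mec}")
        if sigma is None:  # epochs == 0: clustering on measured correlations only
            sigma = C
        haplotypes = consensus_haplotypes(m, labels, k)
        final_mec = metrics.mec(m, haplotypes)
        final_loss = history["loss"][-1] if history["loss"] else float(
            total_loss(sigma, C, pair_indicator(labels), self.lambda_r, self.lambda_s))
        history["initial_mec"] = init_mec
        return AssemblyResult(haplotypes, labels, sigma, final_mec, final_loss, history)

    def fit(self, X, y=None, verbose: bool = False):
        """Assemble haplotypes from a fragment matrix (or raw int8 entries)."""
        m = X if isinstance(X, ReadFragmentMatrix) else ReadFragmentMatrix(
            np.asarray(X, dtype=np.int8),
            [f"read{i}" for i in range(np.asarray(X).shape[0])],
            np.arange(np.asarray(X).shape[1]),
        )
        if self.ploidy < 2:
            raise ValueError("ploidy must be >= 2")
        if self.ploidy > m.n:
            raise ValueError("more haplotypes than fragments")
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_restarts)
        best: AssemblyResult | None = None
        for i, ss in enumerate(seeds):
            result = self._run_once(m, np.random.default_rng(ss), verbose=verbose)
            if (best is None or result.mec < best.mec
                    or (result.mec == best.mec and result.loss < best.loss)):
                best = result
        self.result_ = best
        self.haplotypes_ = best.haplotypes
        self.labels_ = best.labels
        self.sigma_ = best.sigma
        self.mec_ = best.mec
        self.loss_ = best.loss
        self.history_ = best.history
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the read-to-haplotype assignment."""
        return self.fit(X).labels_


def _make_assembler(k: int, tcfg: TrainConfig | None, ecfg: EncoderConfig | None,
                    restarts: int) -> HaplotypeAssembler:
    tcfg = tcfg or TrainConfig()
    return HaplotypeAssembler(
        ploidy=k, epochs=tcfg.epochs, learning_rate=tcfg.learning_rate,
        batch_size=tcfg.batch_size, n_restarts=restarts,
        lambda_r=tcfg.lambda_r, lambda_s=tcfg.lambda_s,
        encoder_config=ecfg, random_state=tcfg.seed,
    )


def fit(m: ReadFragmentMatrix, k: int, tcfg: TrainConfig | None = None,
        ecfg: EncoderConfig | None = None) -> AssemblyResult:
    """Single alternating-optimization run (no restarts)."""
    return _make_assembler(k, tcfg, ecfg, restarts=1).fit(m).result_


def assemble(m: ReadFragmentMatrix, k: int, tcfg: TrainConfig | None = None,
             ecfg: EncoderConfig | None = None) -> AssemblyResult:
    """Best-of-restarts assembly: lowest MEC wins, ties by lower loss."""
    tcfg = tcfg or TrainConfig()
    return _make_assembler(k, tcfg, ecfg, restarts=tcfg.restarts).fit(m).result_
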