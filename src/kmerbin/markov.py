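"""Fixed-order Markov-chain read models and iterative bin refinement.

Microbial genomes have genus- and species-specific oligonucleotide
composition, well captured by a 5th-order Markov chain (base probability
conditioned on the preceding 5 bases, trained from 6-mer counts).  A
single 75 bp read is far too short to estimate a chain, but a bin of
reads that mostly share a genome is not: each bin's pooled 6-mer counts
define a chain, every read is scored under every bin's chain, and reads
are reassigned to their best-scoring bin if the score clears that bin's
beta-percentile cutoff.  Training/scoring alternate, with beta halved
each round, until the binning stops changing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._encode import encode_concat, revcomp, window_codes
from .assign import UNASSIGNED, ReadBinning, reconcile_pairs
from .em import MixtureModel
from .kmers import ReadSet, window_counts_per_read

DEFAULT_ORDER = 5
DEFAULT_PSEUDOCOUNT = 1.0
NEG_INF = -np.inf


@dataclass
class RefinementConfig:
    """Schedule for the percentile rejection cutoff."""

    beta: float = 0.10
    beta_halving: bool = True
    max_iter: int = 25

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class MarkovModel:
    """A fixed-order nucleotide Markov chain.

    ``transition`` has shape (4^order, 4): row c is the distribution of
    the next base given the packed length-``order`` context c.
    ``stationary`` (length 4^order) is the context distribution.  Both
    are strictly positive thanks to the training pseudocount.
    """

    order: int
    transition: np.ndarray = field(repr=False)
    stationary: np.ndarray = field(repr=False)
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        nctx = 4**self.order
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.stationary = np.asarray(self.stationary, dtype=np.float64)
        if self.transition.shape != (nctx, 4) or self.stationary.shape != (nctx,):
            raise ValueError("transition/stationary shape mismatch with order")
        if np.any(self.transition <= 0) or np.any(self.stationary <= 0):
            raise ValueError("probabilities must be strictly positive")
        if not (
            np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9)
            and math.isclose(self.stationary.sum(), 1.0, abs_tol=1e-9)
        ):
            raise ValueError("rows must sum to 1")

    @property
    def log_transition_flat(self) -> np.ndarray:
        """log transition indexed by packed (order+1)-mer code."""
        return np.log(self.transition).ravel()

    @property
    def log_stationary(self) -> np.ndarray:
        return np.log(self.stationary)


def _count_table(seqs: list[str], order: int) -> np.ndarray:
    """Pooled (order+1)-mer counts over sequences and their reverse
    complements, as a flat array of length 4^(order+1)."""
    w = order + 1
    both = list(seqs) + [revcomp(s) for s in seqs]
    codes, _, _ = encode_concat(both)
    km, valid = window_codes(codes, w)
    counts = np.zeros(4**w, dtype=np.int64)
    if km.size:
        counts = np.bincount(km[valid].astype(np.int64), minlength=4**w)
    return counts


def model_from_counts(
    counts: np.ndarray, order: int, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> MarkovModel:
    """Build a MarkovModel from flat (order+1)-mer counts."""
    table = counts.reshape(4**order, 4).astype(np.float64)
    ctx = table.sum(axis=1)
    transition = (table + pseudocount) / (ctx + 4.0 * pseudocount)[:, None]
    stat = ctx + pseudocount
    stationary = stat / stat.sum()
    return MarkovModel(
        order=order, transition=transition, stationary=stationary, pseudocount=pseudocount
    )


def train_markov(
    seqs: list[str],
    order: int = DEFAULT_ORDER,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> MarkovModel:
    """Train a chain from pooled (order+1)-mer counts of the sequences
    and their reverse complements (so the model is strand-neutral).

    Raises ``ValueError`` when no sequence yields a usable window.
    """
    if not seqs:
        raise ValueError("no sequences to train on")
    counts = _count_table(seqs, order)
    if counts.sum() == 0:
        raise ValueError(f"no N-free window of length {order + 1} in the input")
    return model_from_counts(counts, order, pseudocount)


def score_read(read: str, model: MarkovModel) -> float:
    """Length-normalised log-likelihood, maximised over strands.

    score = max over {read, revcomp} of
        [log π(first context) + Σ log t(context -> base)] / n_bases,
    where n_bases = order + number of valid transitions (the stationary
    term models the first `order` bases), so the score is an average
    per-base log-likelihood comparable across read lengths.  N-containing
    windows are skipped.  Returns -inf when the read has no usable window
    (such reads are unassignable).
    """
    scorer = MarkovScorer([read], order=model.order)
    return float(scorer.scores(model)[0])


class MarkovScorer:
    """Pre-encoded batch scorer: encode a read set once, score under any
    number of models of the same order."""

    def __init__(self, seqs: list[str], order: int = DEFAULT_ORDER):
        self.order = order
        self.n = len(seqs)
        w = order + 1
        self._strands = []
        for strand_seqs in (list(seqs), [revcomp(s) for s in seqs]):
            codes, starts, lengths = encode_concat(strand_seqs)
            km, valid = window_codes(codes, w)
            # per-read window ranges in the concatenated layout
            lo = starts
            hi = starts + np.maximum(lengths - w + 1, 0)
            km_idx = np.where(valid, km.astype(np.int64), 4**w)  # sentinel
            # first valid window per read (for the stationary term)
            first = np.full(self.n, -1, dtype=np.int64)
            nvalid = np.zeros(self.n, dtype=np.int64)
            for r in range(self.n):
                v = valid[lo[r] : hi[r]]
                nv = int(np.count_nonzero(v))
                nvalid[r] = nv
                if nv:
                    first[r] = lo[r] + int(np.argmax(v))
            # window -> owning read (sentinel self.n for separator windows)
            owner = np.full(km.size, self.n, dtype=np.int64)
            lens = hi - lo
            if lens.sum() > 0:
                pos = (
                    np.arange(lens.sum())
                    - np.repeat(np.cumsum(lens) - lens, lens)
                    + np.repeat(lo, lens)
                )
                owner[pos] = np.repeat(np.arange(self.n), lens)
            self._strands.append((km_idx, lo, hi, first, nvalid, owner))

    def scores(self, model: MarkovModel) -> np.ndarray:
        """Per-read score (max over strands); -inf for unusable reads."""
        if model.order != self.order:
            raise ValueError("model order mismatch")
        ltf = np.concatenate([model.log_transition_flat, [0.0]])  # sentinel -> 0
        lstat = model.log_stationary
        best = np.full(self.n, NEG_INF)
        for km_idx, lo, hi, first, nvalid, _ in self._strands:
            terms = ltf[km_idx]
            csum = np.concatenate(([0.0], np.cumsum(terms)))
            usable = nvalid > 0
            s = np.full(self.n, NEG_INF)
            tsum = csum[hi[usable]] - csum[lo[usable]]
            ctx = km_idx[first[usable]] >> 2  # context = top `order` bases
            s[usable] = (tsum + lstat[ctx]) / (nvalid[usable] + float(self.order))
            np.maximum(best, s, out=best)
        return best

    def bin_counts(self, members: np.ndarray) -> np.ndarray:
        """Pooled (order+1)-mer counts over the given read indices (both
        strands), identical to :func:`_count_table` on those reads."""
        w = self.order + 1
        counts = np.zeros(4**w + 1, dtype=np.int64)
        member_mask = np.zeros(self.n + 1, dtype=bool)
        member_mask[np.asarray(members, dtype=np.int64)] = True
        member_mask[self.n] = False
        for km_idx, _, _, _, _, owner in self._strands:
            sel = member_mask[owner]
            if sel.any():
                counts += np.bincount(km_idx[sel], minlength=4**w + 1)
        return counts[:-1]


def percentile_cutoff(scores, beta: float) -> float:
    """Nearest-rank beta-quantile: the smallest score s such that at least
    a fraction beta of the scores are <= s."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("empty score collection")
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    rank = max(int(math.ceil(beta * scores.size)), 1)
    return float(np.sort(scores)[rank - 1])


@dataclass
class RefinementResult:
    binning: ReadBinning
    models: dict[int, MarkovModel] = field(repr=False)
    n_iter: int
    converged: bool


def refine_assignments(
    reads: ReadSet,
    initial: ReadBinning,
    cfg: RefinementConfig | None = None,
    order: int = DEFAULT_ORDER,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RefinementResult:
    """Iterative Markov-chain retraining and reassignment.

    Per iteration: (a) train one chain per non-empty bin from its current
    members; (b) set each bin's cutoff to the beta-percentile of its own
    members' scores under its own chain; (c) rescore every read
    (including the currently unassigned) under all chains and move it to
    the best-scoring bin when the best score reaches that bin's cutoff,
    else unassign it (score ties break toward the lower bin index);
    (d) reconcile mates; (e) halve beta.  Stops when the labelling
    repeats or ``max_iter`` is hit.  Bins that empty out are dropped with
    a warning.
    """
    cfg = cfg or RefinementConfig()
    if not np.any(initial.labels != UNASSIGNED):
        raise ValueError("initial binning has no assigned read")
    scorer = MarkovScorer(reads.seqs, order=order)
    labels = initial.labels.copy()
    pairs = reads.pairs
    beta = cfg.beta
    models: dict[int, MarkovModel] = {}
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        active = [j for j in range(initial.m) if np.any(labels == j)]
        if not active:
            raise ValueError("all bins empty during refinement")
        models = {}
        cutoffs = {}
        score_mat = np.empty((len(reads), len(active)))
        for col, j in enumerate(active):
            members = np.nonzero(labels == j)[0]
            model = model_from_counts(scorer.bin_counts(members), order, pseudocount)
            models[j] = model
            s = scorer.scores(model)
            score_mat[:, col] = s
            finite = s[members][np.isfinite(s[members])]
            cutoffs[j] = percentile_cutoff(finite, beta) if finite.size else NEG_INF
        best_col = np.argmax(score_mat, axis=1)  # first max -> lower bin index
        best_score = score_mat[np.arange(len(reads)), best_col]
        best_bin = np.asarray(active, dtype=np.int64)[best_col]
        cut = np.array([cutoffs[j] for j in active])[best_col]
        # ties at the cutoff stay assigned: the nearest-rank percentile IS a
        # member's score, so a strict comparison would eject that member
        # every round and the labelling could never reach a fixed point
        new_labels = np.where(
            np.isfinite(best_score) & (best_score >= cut), best_bin, UNASSIGNED
        )
        new_labels = reconcile_pairs(new_labels, pairs, strength=best_score)
        dropped = [j for j in active if not np.any(new_labels == j)]
        if dropped:
            warnings.warn(
                f"bin(s) {dropped} emptied during refinement; species count reduced",
                RuntimeWarning,
                stacklevel=2,
            )
        if np.array_equal(new_labels, labels):
            labels = new_labels
            converged = True
            break
        labels = new_labels
        if cfg.beta_halving:
            beta = beta / 2.0
    return RefinementResult(
        binning=ReadBinning(labels=labels, m=initial.m),
        models=models,
        n_iter=it,
        converged=converged,
    )


def relative_entropy(a: MarkovModel, b: MarkovModel) -> float:
    """Symmetrised, stationary-weighted KL divergence of two chains.

    ½ Σ_c π_a(c) KL(t_a(c,·) || t_b(c,·)) + ½ Σ_c π_b(c) KL(t_b(c,·) || t_a(c,·));
    non-negative, 0 iff the transition matrices coincide on the support of
    the stationaries.
    """
    if a.order != b.order:
        raise ValueError("order mismatch")
    kl_ab = np.sum(a.stationary * np.sum(a.transition * np.log(a.transition / b.transition), axis=1))
    kl_ba = np.sum(b.stationary * np.sum(b.transition * np.log(b.transition / a.transition), axis=1))
    return float(0.5 * (kl_ab + kl_ba))


def final_genome_sizes(
    binning: ReadBinning,
    reads: ReadSet,
    model: MixtureModel,
    k: int,
) -> np.ndarray:
    """Per-species genome size from the final binning: the total number of
    k-mer occurrences in each bin's reads divided by the bin's k-mer
    coverage λ_j.  Empty bins get size 0 with a warning."""
    if binning.m != model.m:
        raise ValueError("binning and mixture model have different m")
    win = window_counts_per_read(reads, k)
    occ = np.zeros(model.m, dtype=np.float64)
    assigned = binning.labels != UNASSIGNED
    np.add.at(occ, binning.labels[assigned], win[assigned].astype(np.float64))
    if np.any(occ == 0):
        warnings.warn("empty bin(s); reporting genome size 0", RuntimeWarning, stacklevel=2)
    return occ / model.lambdas
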