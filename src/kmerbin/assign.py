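"""Initial read assignment from median k-mer frequencies.

A read is summarised by the median occurrence count x of its k-mers; the
evidence that it belongs to species j is the raw Poisson pmf p_j(λ_j, x)
(deliberately unweighted by α and unnormalised).  A read is assigned to
the best species only when the pmf gap between the best and second-best
species exceeds a cutoff C; C starts at 0.5 and is lowered in 0.01 steps
until more than half of the reads are assigned.  Paired mates are forced
to agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .em import MixtureModel
from .kmers import KmerSpectrum, ReadSet, median_frequencies, read_median_frequency

UNASSIGNED = -1


@dataclass
class AssignmentConfig:
    """Cutoff schedule for the probability-gap rule."""

    C: float = 0.5
    C_decrement: float = 0.01
    min_assigned_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.C <= 1.0:
            raise ValueError("C must lie in [0, 1]")
        if self.C_decrement <= 0:
            raise ValueError("C_decrement must be positive")


@dataclass
class ReadBinning:
    """Partition of reads into m species bins plus one unassigned group.

    ``labels[i]`` is the 0-based bin index of read i, or -1 (UNASSIGNED).
    """

    labels: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if np.any(self.labels < UNASSIGNED) or np.any(self.labels >= self.m):
            raise ValueError("labels out of range")

    @property
    def n_reads(self) -> int:
        return int(self.labels.size)

    @property
    def assigned_fraction(self) -> float:
        return float(np.mean(self.labels != UNASSIGNED))

    def bin_members(self, j: int) -> np.ndarray:
        return np.nonzero(self.labels == j)[0]

    def bin_sizes(self) -> np.ndarray:
        out = np.zeros(self.m, dtype=np.int64)
        assigned = self.labels[self.labels != UNASSIGNED]
        np.add.at(out, assigned, 1)
        return out


def reconcile_pairs(
    labels: np.ndarray, pairs: np.ndarray, strength: np.ndarray | None = None
) -> np.ndarray:
    """Enforce mate agreement: one assigned mate pulls in the other.

    Mates confidently assigned to different bins are a conflict.  Without
    ``strength`` (the initial, probability-gap phase) both are unassigned
    — the strict reading of requiring no conflict.  With ``strength`` (a
    per-read score, used by the Markov refinement phase) both mates
    follow the higher-scoring mate's bin, so duplicated groups that model
    the same genome do not bleed reads into the unassigned pool; ties go
    to the lower-indexed mate.
    """
    labels = labels.copy()
    if pairs.size == 0:
        return labels
    a, b = pairs[:, 0], pairs[:, 1]
    la, lb = labels[a], labels[b]
    conflict = (la != UNASSIGNED) & (lb != UNASSIGNED) & (la != lb)
    if strength is None:
        labels[a[conflict]] = UNASSIGNED
        labels[b[conflict]] = UNASSIGNED
    else:
        ca, cb = a[conflict], b[conflict]
        winner = np.where(strength[ca] >= strength[cb], labels[ca], labels[cb])
        labels[ca] = winner
        labels[cb] = winner
    only_a = (la != UNASSIGNED) & (lb == UNASSIGNED)
    labels[b[only_a]] = la[only_a]
    only_b = (lb != UNASSIGNED) & (la == UNASSIGNED)
    labels[a[only_b]] = lb[only_b]
    return labels


def read_bin_probabilities(
    read: str, spectrum: KmerSpectrum, model: MixtureModel
) -> np.ndarray:
    """(p_1(λ_1,x), ..., p_m(λ_m,x)) for one read's median frequency x."""
    x = read_median_frequency(read, spectrum)
    return np.exp(poisson.logpmf(x, model.lambdas))


def assign_reads_initial(
    reads: ReadSet,
    spectrum: KmerSpectrum,
    model: MixtureModel,
    cfg: AssignmentConfig | None = None,
) -> ReadBinning:
    """Gap-rule assignment of every read, with the adaptive C schedule.

    Reads shorter than k or without a usable window are unassigned.  The
    cutoff C is lowered by ``C_decrement`` (restarting the assignment from
    scratch) while the assigned fraction — counted over individual reads,
    after mate reconciliation — is at or below ``min_assigned_fraction``;
    at C <= 0 the strictly-positive-gap assignment is accepted as is.
    """
    if len(reads) == 0:
        raise ValueError("empty read set")
    cfg = cfg or AssignmentConfig()
    med = median_frequencies(reads, spectrum)
    usable = ~np.isnan(med)
    x = np.where(usable, med, 0.0).astype(np.int64)

    logp = poisson.logpmf(x[:, None], model.lambdas[None, :])
    probs = np.exp(logp)
    best = np.argmax(probs, axis=1)  # ties -> lower bin index
    top = probs[np.arange(probs.shape[0]), best]
    if model.m > 1:
        part = np.partition(probs, -2, axis=1)
        second = part[:, -2]
    else:
        second = np.zeros_like(top)  # implicit 0 second-best for m = 1
    gap = np.where(usable, top - second, -np.inf)

    pairs = reads.pairs
    C = cfg.C
    while True:
        labels = np.where(gap > C, best, UNASSIGNED)
        labels = reconcile_pairs(labels, pairs)
        frac = float(np.mean(labels != UNASSIGNED))
        if frac > cfg.min_assigned_fraction or C <= 0:
            break
        C = max(C - cfg.C_decrement, 0.0)
    return ReadBinning(labels=labels, m=model.m)
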