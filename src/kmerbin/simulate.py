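"""Synthetic shotgun metagenomes with known ground truth.

Emulates a simple multi-species sequencing experiment: each species'
genome is sampled from its own fixed-order Markov chain (standing in for
the distinct oligonucleotide composition of real microbial genomes),
then shotgun reads — 75 bp paired-end by default, or longer single-end —
are drawn uniformly from both strands at a prescribed genome coverage,
optionally with i.i.d. per-base substitution errors (~1% emulating a
short-read error profile; indels are not modelled).  Every read carries
its true species label for accuracy scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._encode import encode
from .assign import ReadBinning
from .kmers import ReadSet
from .markov import DEFAULT_ORDER, MarkovModel

DEFAULT_READ_LENGTH = 75
DEFAULT_INSERT_SIZE = 300
DEFAULT_ERROR_RATE = 0.0


def random_markov_model(
    order: int = DEFAULT_ORDER,
    seed: int | np.random.Generator = 0,
    concentration: float = 1.0,
) -> MarkovModel:
    """A random order-``order`` chain with Dirichlet(concentration) rows.

    Lower concentration gives more biased (more species-distinctive)
    composition; the stationary distribution is computed from the
    transition matrix by power iteration.
    """
    rng = np.random.default_rng(seed)
    nctx = 4**order
    transition = rng.dirichlet(np.full(4, concentration), size=nctx)
    transition = np.maximum(transition, 1e-12)
    transition /= transition.sum(axis=1, keepdims=True)
    stationary = _stationary_distribution(transition, order)
    stationary = np.maximum(stationary, 1e-15)
    stationary /= stationary.sum()
    return MarkovModel(
        order=order, transition=transition, stationary=stationary, pseudocount=1.0
    )


def _stationary_distribution(
    transition: np.ndarray, order: int, n_iter: int = 500, tol: float = 1e-13
) -> np.ndarray:
    """Stationary context distribution by power iteration on the induced
    4^order-state chain (context c, next base b -> context (c<<2 | b) mod 4^order)."""
    nctx = 4**order
    nxt = ((np.arange(nctx)[:, None] % (nctx // 4)) * 4 + np.arange(4)[None, :]).ravel()
    v = np.full(nctx, 1.0 / nctx)
    for _ in range(n_iter):
        flow = (v[:, None] * transition).ravel()
        new = np.bincount(nxt, weights=flow, minlength=nctx)
        if np.max(np.abs(new - v)) < tol:
            v = new
            break
        v = new
    return v / v.sum()


def generate_genome(length: int, chain: MarkovModel, seed: int | np.random.Generator) -> str:
    """Sample a genome of the given length from the chain.

    The initial context comes from the stationary distribution; the rest
    is extended base by base from the transition matrix.  Deterministic
    given the seed.
    """
    order = chain.order
    if length < order + 1:
        raise ValueError("genome length must exceed the chain order")
    rng = np.random.default_rng(seed)
    nctx = 4**order
    ctx = int(rng.choice(nctx, p=chain.stationary))
    cum = np.cumsum(chain.transition, axis=1)
    cum[:, -1] = 1.0
    mask = nctx // 4
    out = np.empty(length, dtype=np.uint8)
    for j in range(order):
        out[j] = (ctx >> (2 * (order - 1 - j))) & 3
    u = rng.random(length - order)
    for i in range(order, length):
        b = int(np.searchsorted(cum[ctx], u[i - order], side="right"))
        out[i] = b
        ctx = (ctx & (mask - 1)) * 4 + b if mask > 1 else b
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[out].tobytes().decode("ascii")


@dataclass
class SimulationSpec:
    """One species' slice of a simulated metagenome plus library settings."""

    genome_length: int
    coverage: float
    chain_seed: int | None = None
    chain: MarkovModel | None = None
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.chain is None and self.chain_seed is None:
            raise ValueError("either chain or chain_seed is required")


def _apply_errors(codes: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. substitution errors on a 2D (reads x positions) code array."""
    if error_rate <= 0:
        return codes
    hit = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=codes.shape)
    return np.where(hit, (codes + shift) % 4, codes)


def _codes_to_strings(codes: np.ndarray) -> list[str]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    block = bases[codes].tobytes().decode("ascii")
    n, L = codes.shape
    return [block[i * L : (i + 1) * L] for i in range(n)]


def simulate_reads(
    genome: str,
    coverage: float,
    read_length: int = DEFAULT_READ_LENGTH,
    paired: bool = True,
    insert_size: int = DEFAULT_INSERT_SIZE,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Shotgun reads from one genome at the given genome coverage.

    The number of reads is round(coverage * genome_length / read_length)
    (rounded to pairs when paired).  Paired mates come from the two ends
    of an insert_size fragment, on opposite strands; single-end reads get
    a random strand.  Start positions are uniform; no circular wraparound.
    Returns the read sequences in order (mates adjacent: 2i, 2i+1).
    """
    L = len(genome)
    if L < read_length:
        raise ValueError("genome shorter than the read length")
    if paired and L < insert_size:
        raise ValueError("genome shorter than the insert size")
    if paired and insert_size < read_length:
        raise ValueError("insert size smaller than the read length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * L / read_length))
    gcodes = encode(genome)

    if paired:
        n_pairs = max(int(round(n_reads / 2)), 1)
        starts = rng.integers(0, L - insert_size + 1, size=n_pairs)
        idx1 = starts[:, None] + np.arange(read_length)[None, :]
        m1 = gcodes[idx1]
        idx2 = (starts + insert_size - read_length)[:, None] + np.arange(read_length)[None, :]
        m2 = (3 - gcodes[idx2])[:, ::-1]  # opposite strand
        m1 = _apply_errors(m1, error_rate, rng)
        m2 = _apply_errors(m2, error_rate, rng)
        s1 = _codes_to_strings(m1)
        s2 = _codes_to_strings(m2)
        return [s for pair in zip(s1, s2) for s in pair]

    n_reads = max(n_reads, 1)
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    codes = gcodes[starts[:, None] + np.arange(read_length)[None, :]]
    flip = rng.random(n_reads) < 0.5
    codes[flip] = (3 - codes[flip])[:, ::-1]
    codes = _apply_errors(codes, error_rate, rng)
    return _codes_to_strings(codes)


@dataclass
class SimulatedMetagenome:
    """Reads pooled over species, with per-read ground-truth labels."""

    reads: ReadSet
    truth: np.ndarray  # species index per read
    genomes: list[str] = field(repr=False)
    chains: list[MarkovModel] = field(repr=False)


def simulate_metagenome(
    species: list[SimulationSpec],
    read_length: int = DEFAULT_READ_LENGTH,
    paired: bool = True,
    insert_size: int = DEFAULT_INSERT_SIZE,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
) -> SimulatedMetagenome:
    """Full multi-species simulation; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    genomes: list[str] = []
    chains: list[MarkovModel] = []
    seqs: list[str] = []
    truth: list[int] = []
    ids: list[str] = []
    for si, sp in enumerate(species):
        chain = sp.chain or random_markov_model(
            seed=sp.chain_seed, concentration=sp.concentration
        )
        chains.append(chain)
        genome = generate_genome(sp.genome_length, chain, seed=rng.integers(2**31))
        genomes.append(genome)
        rs = simulate_reads(
            genome,
            coverage=sp.coverage,
            read_length=read_length,
            paired=paired,
            insert_size=insert_size,
            error_rate=error_rate,
            seed=rng.integers(2**31),
        )
        if paired:
            for p in range(len(rs) // 2):
                ids.append(f"sp{si}_p{p}/1")
                ids.append(f"sp{si}_p{p}/2")
        else:
            ids.extend(f"sp{si}_r{i}" for i in range(len(rs)))
        seqs.extend(rs)
        truth.extend([si] * len(rs))
    reads = ReadSet.from_sequences(seqs, ids=ids, paired=paired)
    return SimulatedMetagenome(
        reads=reads,
        truth=np.asarray(truth, dtype=np.int64),
        genomes=genomes,
        chains=chains,
    )


def binning_accuracy(predicted: ReadBinning, truth: np.ndarray) -> float:
    """Majority-vote binning accuracy.

    Each predicted bin is identified with the true species holding the
    majority of its reads (ties toward the lower species index); the
    accuracy is the fraction of all reads whose bin maps to their true
    species.  Unassigned reads count as incorrect.
    """
    truth = np.asarray(truth, dtype=np.int64)
    if truth.shape != predicted.labels.shape:
        raise ValueError("predicted binning and truth cover different reads")
    n_species = int(truth.max()) + 1
    correct = 0
    for j in range(predicted.m):
        members = predicted.bin_members(j)
        if members.size == 0:
            continue
        votes = np.bincount(truth[members], minlength=n_species)
        majority = int(np.argmax(votes))  # ties -> lower species index
        correct += int(votes[majority])
    return correct / truth.size


def write_fasta(path, reads: ReadSet) -> None:
    """Plain FASTA dump of a read set."""
    with open(path, "w") as fh:
        for rid, seq in zip(reads.ids, reads.seqs):
            fh.write(f">{rid}\n{seq}\n")


def write_truth_tsv(path, reads: ReadSet, truth: np.ndarray) -> None:
    """TSV of read_id <tab> true species index."""
    with open(path, "w") as fh:
        fh.write("read_id\tspecies\n")
        for rid, t in zip(reads.ids, truth):
            fh.write(f"{rid}\t{int(t)}\n")
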