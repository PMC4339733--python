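"""Canonical k-mer counting and per-read k-mer frequency summaries.

The k-mer spectrum — how many times each distinct canonical k-mer occurs
across all reads — is the sole input to the Poisson mixture stage: under
uniform shotgun sampling, the occurrence count of a genomic k-mer from a
species sequenced at k-mer coverage λ is approximately Poisson(λ).
Counting is canonical (a k-mer and its reverse complement share one key)
because reads come from both strands of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._encode import canonical_window_codes, decode, encode, encode_concat, pack_kmer, revcomp

DEFAULT_K = 16
#: chunk size (in windows) for incremental spectrum accumulation
_CHUNK_WINDOWS = 8_000_000


@dataclass
class ReadSet:
    """An ordered collection of shotgun reads with optional mate pairing.

    Parameters
    ----------
    ids : list of str
        Unique read identifiers, in file order.
    seqs : list of str
        Read sequences over {A,C,G,T,N}; same order as `ids`.
    mate : ndarray of int or None
        ``mate[i]`` is the index of read i's mate, or -1 for unpaired
        reads.  Must be a symmetric perfect matching on the paired subset.
    read_type : str
        ``"single"`` or ``"paired"``.
    """

    ids: list[str]
    seqs: list[str]
    mate: np.ndarray | None = None
    read_type: str = "single"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("read ids must be unique")
        if any(len(s) == 0 for s in self.seqs):
            raise ValueError("empty read sequence")
        if self.read_type not in ("single", "paired"):
            raise ValueError("read_type must be 'single' or 'paired'")
        if self.mate is not None:
            self.mate = np.asarray(self.mate, dtype=np.int64)
            if self.mate.shape != (len(self.ids),):
                raise ValueError("mate array misaligned with reads")
            paired = np.nonzero(self.mate >= 0)[0]
            if not np.all(self.mate[self.mate[paired]] == paired) or np.any(
                self.mate[paired] == paired
            ):
                raise ValueError("mate links must form a perfect matching")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def pairs(self) -> np.ndarray:
        """(n_pairs, 2) array of mate index pairs (i < j), empty if unpaired."""
        if self.mate is None:
            return np.empty((0, 2), dtype=np.int64)
        i = np.nonzero(self.mate > np.arange(len(self.mate)))[0]
        return np.column_stack([i, self.mate[i]])

    @classmethod
    def from_sequences(
        cls, seqs: list[str], ids: list[str] | None = None, paired: bool = False
    ) -> "ReadSet":
        """Build a ReadSet from bare sequences; with ``paired=True``
        consecutive reads (0,1), (2,3), ... are mates."""
        if ids is None:
            ids = [f"read_{i}" for i in range(len(seqs))]
        mate = None
        read_type = "single"
        if paired:
            if len(seqs) % 2:
                raise ValueError("paired ReadSet needs an even number of reads")
            mate = np.arange(len(seqs), dtype=np.int64)
            mate[0::2] += 1
            mate[1::2] -= 1
            read_type = "paired"
        return cls(ids=list(ids), seqs=list(seqs), mate=mate, read_type=read_type)


@dataclass
class KmerSpectrum:
    """Occurrence counts of all distinct canonical k-mers in a read set.

    Stored columnar: ``codes`` are packed 2-bit canonical k-mers, sorted
    ascending, and ``counts[i]`` is the occurrence count of ``codes[i]``.
    """

    k: int
    codes: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes/counts misaligned")
        if np.any(self.counts < 1):
            raise ValueError("spectrum counts must be >= 1")

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def total_occurrences(self) -> int:
        return int(self.counts.sum())

    def lookup_codes(self, query: np.ndarray) -> np.ndarray:
        """Counts for packed canonical codes; absent codes count 0."""
        pos = np.searchsorted(self.codes, query)
        pos = np.minimum(pos, self.codes.size - 1) if self.codes.size else pos
        out = np.zeros(query.shape, dtype=np.int64)
        if self.codes.size:
            hit = self.codes[pos] == query
            out[hit] = self.counts[pos[hit]]
        return out

    def get(self, kmer: str) -> int:
        """Occurrence count of a k-mer string (canonicalized first)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        code = min(pack_kmer(kmer), pack_kmer(revcomp(kmer)))
        return int(self.lookup_codes(np.array([code], dtype=np.uint64))[0])

    def to_dict(self) -> dict[str, int]:
        """Spectrum as {canonical k-mer string: count}; small spectra only."""
        return {decode(c, self.k): int(n) for c, n in zip(self.codes, self.counts)}


def _as_seqs(reads) -> list[str]:
    return reads.seqs if isinstance(reads, ReadSet) else list(reads)


def count_kmers(reads, k: int = DEFAULT_K) -> KmerSpectrum:
    """Count canonical k-mers over all reads.

    Every length-k window over {A,C,G,T} contributes 1 to the count of the
    lexicographic minimum of itself and its reverse complement; windows
    containing N are skipped, and reads shorter than k contribute nothing.

    Raises
    ------
    ValueError
        if ``k < 1`` or no read is at least k long.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k > 31 is not supported")
    seqs = _as_seqs(reads)
    if not any(len(s) >= k for s in seqs):
        raise ValueError(f"no read of length >= k={k}; input unusable")

    partial: list[tuple[np.ndarray, np.ndarray]] = []
    batch: list[str] = []
    nbatch = 0

    def flush() -> None:
        nonlocal batch, nbatch
        if not batch:
            return
        codes, _, _ = encode_concat(batch)
        km, valid = canonical_window_codes(codes, k)
        partial.append(np.unique(km[valid], return_counts=True))
        batch = []
        nbatch = 0

    for s in seqs:
        if len(s) < k:
            continue
        batch.append(s)
        nbatch += len(s)
        if nbatch >= _CHUNK_WINDOWS:
            flush()
    flush()

    all_codes = np.concatenate([p[0] for p in partial])
    all_counts = np.concatenate([p[1] for p in partial])
    codes, inv = np.unique(all_codes, return_inverse=True)
    counts = np.bincount(inv, weights=all_counts).astype(np.int64)
    return KmerSpectrum(k=k, codes=codes, counts=counts)


def _lower_median(values: np.ndarray) -> int:
    """Median with the lower-middle convention for even sizes, so the
    statistic remains an observed integer count."""
    v = np.sort(values)
    return int(v[(v.size - 1) // 2])


def read_median_frequency(read: str, spectrum: KmerSpectrum) -> int:
    """Median spectrum count of the canonical k-mers of one read.

    Raises ``ValueError`` if the read is shorter than k or has no
    N-free window.
    """
    k = spectrum.k
    if len(read) < k:
        raise ValueError(f"read shorter than k={k}")
    km, valid = canonical_window_codes(encode(read), k)
    if not valid.any():
        raise ValueError("read has no N-free k-mer window")
    return _lower_median(spectrum.lookup_codes(km[valid]))


def median_frequencies(reads, spectrum: KmerSpectrum) -> np.ndarray:
    """Vectorised :func:`read_median_frequency` over a read set.

    Returns a float array with NaN for reads shorter than k or without a
    usable window (such reads are later left unassigned, never an error).
    """
    seqs = _as_seqs(reads)
    k = spectrum.k
    out = np.full(len(seqs), np.nan)
    codes, starts, lengths = encode_concat(seqs)
    km, valid = canonical_window_codes(codes, k)
    freqs = np.zeros(km.shape, dtype=np.int64)
    if km.size:
        freqs[valid] = spectrum.lookup_codes(km[valid])
    for r in range(len(seqs)):
        if lengths[r] < k:
            continue
        lo = starts[r]
        hi = lo + lengths[r] - k + 1
        v = valid[lo:hi]
        if v.any():
            out[r] = _lower_median(freqs[lo:hi][v])
    return out


def window_counts_per_read(reads, k: int = DEFAULT_K) -> np.ndarray:
    """Number of usable (N-free) length-k windows in each read."""
    seqs = _as_seqs(reads)
    codes, starts, lengths = encode_concat(seqs)
    bad = np.concatenate(([0], np.cumsum(codes == 4, dtype=np.int64)))
    out = np.zeros(len(seqs), dtype=np.int64)
    for r in range(len(seqs)):
        if lengths[r] < k:
            continue
        lo = starts[r]
        hi = lo + lengths[r] - k + 1
        out[r] = int(np.count_nonzero((bad[lo + k : hi + k] - bad[lo:hi]) == 0))
    return out
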