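"""The end-to-end binning model: `ReadBinner` and `BinningResults`.

`ReadBinner` holds the read data and the pipeline configuration;
`fit()` runs the four stages — canonical k-mer counting, Poisson-mixture
EM with low-count correction and genome-size pruning, median-frequency
read assignment, and Markov-chain refinement — and returns a
`BinningResults` carrying the estimated species number, per-species
relative abundances α, k-mer coverages λ, genome sizes, the per-read bin
labels, and a `summary()` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .assign import UNASSIGNED, AssignmentConfig, ReadBinning, assign_reads_initial
from .em import FrequencyHistogram
from .kmers import DEFAULT_K, KmerSpectrum, ReadSet, count_kmers
from .markov import (
    DEFAULT_ORDER,
    MarkovModel,
    RefinementConfig,
    RefinementResult,
    final_genome_sizes,
    refine_assignments,
)
from .species import DEFAULT_M_INIT, MIN_GENOME_SIZE, SpeciesEstimate, estimate_species_number

logger = logging.getLogger("kmerbin")


@dataclass
class BinningResults:
    """Estimates and diagnostics from a fitted `ReadBinner`."""

    model: "ReadBinner"
    spectrum: KmerSpectrum = field(repr=False)
    species: SpeciesEstimate = field(repr=False)
    initial_binning: ReadBinning = field(repr=False)
    refinement: RefinementResult = field(repr=False)
    genome_sizes: np.ndarray

    @property
    def n_species(self) -> int:
        """Predicted species number (surviving mixture components)."""
        return self.species.n_species

    @property
    def alphas(self) -> np.ndarray:
        """Relative abundance of each predicted species."""
        return self.species.model.alphas

    @property
    def lambdas(self) -> np.ndarray:
        """k-mer coverage of each predicted species."""
        return self.species.model.lambdas

    @property
    def binning(self) -> ReadBinning:
        """Final per-read bin labels (after Markov refinement)."""
        return self.refinement.binning

    @property
    def markov_models(self) -> dict[int, MarkovModel]:
        return self.refinement.models

    def to_frame(self) -> pd.DataFrame:
        """Per-species table of the headline estimates."""
        sizes = self.binning.bin_sizes()
        return pd.DataFrame(
            {
                "species": np.arange(self.n_species),
                "alpha": self.alphas,
                "kmer_coverage": self.lambdas,
                "genome_size_em": self.species.genome_sizes,
                "genome_size_final": self.genome_sizes,
                "n_reads": sizes,
            }
        )

    def labels_frame(self) -> pd.DataFrame:
        """Per-read table: read_id and final bin (-1 = unassigned)."""
        return pd.DataFrame(
            {"read_id": self.model.reads.ids, "bin": self.binning.labels}
        )

    def summary(self) -> str:
        """Human-readable report of the fit."""
        mdl = self.model
        frame = self.to_frame()
        unassigned = int(np.sum(self.binning.labels == UNASSIGNED))
        lines = [
            "Taxonomy-independent read binning results",
            "=" * 57,
            f"reads: {len(mdl.reads)} ({mdl.reads.read_type})    "
            f"k: {mdl.k}    initial m: {mdl.m_init}",
            f"distinct {mdl.k}-mers: {self.spectrum.n_distinct}    "
            f"occurrences: {self.spectrum.total_occurrences}",
            f"predicted species number: {self.n_species}",
            f"unassigned reads: {unassigned} "
            f"({unassigned / len(mdl.reads):.1%})",
            "",
            frame.to_string(
                index=False,
                formatters={
                    "alpha": "{:.4f}".format,
                    "kmer_coverage": "{:.2f}".format,
                    "genome_size_em": "{:,.0f}".format,
                    "genome_size_final": "{:,.0f}".format,
                },
            ),
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write the report, the per-read labels, and one read-id list per
        bin (plus `unassigned`) under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(self.summary() + "\n")
        self.to_frame().to_csv(out / "species.tsv", sep="\t", index=False)
        self.labels_frame().to_csv(out / "read_labels.tsv", sep="\t", index=False)
        ids = np.asarray(self.model.reads.ids, dtype=object)
        for j in range(self.n_species):
            members = ids[self.binning.labels == j]
            (out / f"bin_{j}.ids").write_text("\n".join(members) + ("\n" if members.size else ""))
        members = ids[self.binning.labels == UNASSIGNED]
        (out / "unassigned.ids").write_text(
            "\n".join(members) + ("\n" if members.size else "")
        )

    def plot_spectrum(self, ax=None, max_count: int | None = None):
        """Diagnostic plot: the k-mer count histogram with the fitted
        Poisson mixture overlaid."""
        import matplotlib.pyplot as plt
        from scipy.stats import poisson as _poisson

        hist = self.species.hist
        if ax is None:
            _, ax = plt.subplots()
        ax.bar(hist.xs, hist.weights, width=0.9, color="0.8", label="k-mer histogram")
        xmax = max_count or int(hist.xs.max())
        grid = np.arange(0, xmax + 1)
        dens = np.zeros_like(grid, dtype=float)
        for a, lam in zip(self.alphas, self.lambdas):
            dens = dens + a * _poisson.pmf(grid, lam)
        ax.plot(grid, dens * hist.total_weight, "r-", label="fitted mixture")
        ax.set_xlabel("k-mer occurrence count")
        ax.set_ylabel("number of distinct k-mers")
        ax.legend()
        return ax


class ReadBinner:
    """Taxonomy-independent metagenomic read binner.

    Parameters
    ----------
    reads : ReadSet
        The shotgun reads (single- or paired-end).
    k : int
        k-mer size for the frequency spectrum (default 16: long enough
        that a random k-mer rarely repeats within a microbial genome).
    m_init : int
        Initial (deliberately generous) species number for the mixture
        fit; surplus components are pruned by the genome-size rule.
    min_genome_size : float
        Pruning threshold in bp (default 400,000 — below the smallest
        sequenced free-living genome).
    cutoff_c, c_decrement : float
        Probability-gap cutoff schedule for the initial read assignment.
    order : int
        Markov chain order for refinement (default 5).
    beta : float
        Initial percentile rejection cutoff for refinement (default 0.10).
    """

    def __init__(
        self,
        reads: ReadSet,
        k: int = DEFAULT_K,
        m_init: int = DEFAULT_M_INIT,
        min_genome_size: float = MIN_GENOME_SIZE,
        cutoff_c: float = 0.5,
        c_decrement: float = 0.01,
        order: int = DEFAULT_ORDER,
        beta: float = 0.10,
        max_refine_iter: int = 25,
    ):
        self.reads = reads
        self.k = k
        self.m_init = m_init
        self.min_genome_size = min_genome_size
        self.assign_cfg = AssignmentConfig(C=cutoff_c, C_decrement=c_decrement)
        self.refine_cfg = RefinementConfig(beta=beta, max_iter=max_refine_iter)
        self.order = order

    @classmethod
    def from_files(
        cls,
        paths: list[str | Path],
        read_type: str = "single",
        interleaved: bool = False,
        **kwargs,
    ) -> "ReadBinner":
        """Construct directly from FASTA/FASTQ file(s)."""
        return cls(_io.load_reads(paths, read_type=read_type, interleaved=interleaved), **kwargs)

    def fit(self) -> BinningResults:
        """Run the full pipeline and return the results object."""
        logger.info("counting canonical %d-mers in %d reads", self.k, len(self.reads))
        spectrum = count_kmers(self.reads, self.k)
        logger.info(
            "spectrum: %d distinct k-mers, %d occurrences",
            spectrum.n_distinct,
            spectrum.total_occurrences,
        )
        raw_hist = FrequencyHistogram.from_spectrum(spectrum)
        species = estimate_species_number(
            raw_hist, m_init=self.m_init, min_genome_size=self.min_genome_size
        )
        logger.info(
            "species number: %d (pruned %d small group(s)); lambda=%s",
            species.n_species,
            self.m_init - species.kept.size,
            np.round(species.model.lambdas, 2).tolist(),
        )
        initial = assign_reads_initial(self.reads, spectrum, species.model, self.assign_cfg)
        logger.info("initial assignment: %.1f%% of reads", 100 * initial.assigned_fraction)
        refinement = refine_assignments(
            self.reads, initial, self.refine_cfg, order=self.order
        )
        logger.info(
            "refinement: %d iteration(s), converged=%s",
            refinement.n_iter,
            refinement.converged,
        )
        sizes = final_genome_sizes(refinement.binning, self.reads, species.model, self.k)
        return BinningResults(
            model=self,
            spectrum=spectrum,
            species=species,
            initial_binning=initial,
            refinement=refinement,
            genome_sizes=sizes,
        )
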