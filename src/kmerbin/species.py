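"""Species-number estimation by genome-size pruning of mixture components.

Each mixture component's implied genome size is the number of distinct
k-mers it explains: Σ_i Z_ij x_i / λ_j (occurrences attributed to the
component divided by its per-k-mer coverage).  Components implying a
genome smaller than 400 kb — below the smallest sequenced genome of a
free-living organism — are discarded as artifacts of over-specifying m;
the survivors are the predicted species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .em import FrequencyHistogram, MixtureModel, e_step
from .lowcount import AugmentedFit, iterate_em_with_low_counts

MIN_GENOME_SIZE = 400_000
DEFAULT_M_INIT = 10


def group_genome_sizes(
    hist: FrequencyHistogram, Z: np.ndarray, model: MixtureModel
) -> np.ndarray:
    """Implied genome size of every component: Σ_x w_x Z(x,j) x / λ_j (bp)."""
    occ = (hist.weights[:, None] * Z * hist.xs[:, None]).sum(axis=0)
    return occ / model.lambdas


def prune_small_groups(
    model: MixtureModel,
    sizes: np.ndarray,
    threshold: float = MIN_GENOME_SIZE,
) -> tuple[MixtureModel, np.ndarray]:
    """Drop components whose implied genome size is strictly below threshold.

    Returns the pruned model (surviving α renormalised to sum 1, λ
    unchanged) and the indices of the survivors.  Raises ``ValueError``
    when no component survives.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    if sizes.shape != (model.m,):
        raise ValueError("sizes misaligned with model components")
    keep = np.nonzero(sizes >= threshold)[0]
    if keep.size == 0:
        raise ValueError(
            "no group reaches the minimum genome size; no species-sized group "
            "found — try a larger initial species number or more data"
        )
    alphas = model.alphas[keep]
    total = alphas.sum()
    if total <= 0:
        alphas = np.full(keep.size, 1.0 / keep.size)
    else:
        alphas = alphas / total
    return MixtureModel(alphas=alphas, lambdas=model.lambdas[keep]), keep


def finalize_model(
    hist: FrequencyHistogram, pruned: MixtureModel
) -> tuple[MixtureModel, np.ndarray]:
    """One extra E-step with the pruned model, then the α-update only.

    Redistributes the k-mers formerly explained by pruned components over
    the surviving species; λ is left unchanged.
    """
    Z = e_step(hist, pruned)
    alphas = (hist.weights[:, None] * Z).sum(axis=0) / hist.total_weight
    alphas = alphas / alphas.sum()
    model = MixtureModel(alphas=alphas, lambdas=pruned.lambdas.copy())
    return model, e_step(hist, model)


@dataclass
class SpeciesEstimate:
    """First-phase result: the pruned mixture and its diagnostics."""

    model: MixtureModel
    responsibilities: np.ndarray = field(repr=False)
    hist: FrequencyHistogram
    genome_sizes: np.ndarray  # per surviving species, bp
    initial_sizes: np.ndarray  # per pre-pruning component, bp
    kept: np.ndarray  # surviving component indices
    low_counts: dict[int, float]
    augmented: AugmentedFit = field(repr=False)

    @property
    def n_species(self) -> int:
        return self.model.m


def estimate_species_number(
    raw_hist: FrequencyHistogram,
    m_init: int = DEFAULT_M_INIT,
    min_genome_size: float = MIN_GENOME_SIZE,
    **lowcount_kwargs,
) -> SpeciesEstimate:
    """Full first phase: augmented EM fit, size-based pruning, final E-step.

    ``m_init`` should exceed the expected species number so that the fit
    produces at least one prunable small group; if none is found a warning
    recommends retrying with a slightly larger ``m_init`` (e.g. 15).
    """
    if m_init < 1:
        raise ValueError("m_init must be >= 1")
    aug = iterate_em_with_low_counts(raw_hist, m=m_init, **lowcount_kwargs)
    initial_sizes = group_genome_sizes(aug.hist, aug.responsibilities, aug.model)
    pruned, kept = prune_small_groups(aug.model, initial_sizes, min_genome_size)
    if kept.size == aug.model.m:
        warnings.warn(
            f"no small group found with m_init={m_init}; the species number may "
            "be underestimated — consider a larger initial species number "
            f"(e.g. {m_init + 5})",
            RuntimeWarning,
            stacklevel=2,
        )
    model, Z = finalize_model(aug.hist, pruned)
    sizes = group_genome_sizes(aug.hist, Z, model)
    return SpeciesEstimate(
        model=model,
        responsibilities=Z,
        hist=aug.hist,
        genome_sizes=sizes,
        initial_sizes=initial_sizes,
        kept=kept,
        low_counts=aug.low_counts,
        augmented=aug,
    )
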