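"""Estimation of the unobserved / unreliable low-occurrence k-mer counts.

K-mers occurring 0 times are never observed, and the observed tallies at
1–3 occurrences are inflated by sequencing errors and low-abundance
species.  Both bias the mixture fit.  The correction replaces the weights
at counts 0..3 with model-based estimates from the zero-to-three-truncated
Poisson components, and alternates estimation with refitting until the
estimates stabilise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .em import EMResult, FrequencyHistogram, MixtureModel, e_step, run_em

LOW_COUNTS = (0, 1, 2, 3)
DEFAULT_TOL_COUNTS = 0.5
DEFAULT_MAX_OUTER = 100


def estimate_low_counts(
    hist: FrequencyHistogram,
    model: MixtureModel,
    Z: np.ndarray | None = None,
) -> dict[int, float]:
    """Estimate the number of k-mers occurring x = 0, 1, 2, 3 times.

    For each x < 4,

        N_x = Σ_j p_j(λ_j, x) · T_j / (1 − Σ_{s=0..3} p_j(λ_j, s)),

    where T_j = Σ_{i: x_i >= 4} Z_ij is component j's responsibility mass
    over the reliably observed tail.  Responsibilities over the tail are
    recomputed from the current model unless ``Z`` is supplied (aligned
    with ``hist``).  Components whose truncation denominator is below
    1e-12 (essentially all their mass at x <= 3) are skipped with a
    warning; if every component is degenerate this raises ``ValueError``.
    """
    tail = hist.xs >= hist.observed_cut
    if Z is None:
        Z = e_step(hist, model)
    T = (hist.weights[tail, None] * Z[tail]).sum(axis=0)

    low = np.array(LOW_COUNTS)
    p_low = np.exp(poisson.logpmf(low[:, None], model.lambdas[None, :]))  # (4, m)
    denom = 1.0 - p_low.sum(axis=0)
    usable = denom >= 1e-12
    if not usable.any():
        raise ValueError(
            "all mixture components are degenerate (truncation denominator ~ 0)"
        )
    if not usable.all():
        warnings.warn(
            "skipping component(s) with near-total mass below 4 occurrences",
            RuntimeWarning,
            stacklevel=2,
        )
    contrib = p_low[:, usable] * T[usable] / denom[usable]
    est = contrib.sum(axis=1)
    return {int(x): float(v) for x, v in zip(low, est)}


@dataclass
class AugmentedFit:
    """Converged state of the low-count augmentation loop."""

    hist: FrequencyHistogram
    model: MixtureModel
    responsibilities: np.ndarray = field(repr=False)
    low_counts: dict[int, float]
    n_outer: int
    converged: bool
    em_result: EMResult = field(repr=False)


def iterate_em_with_low_counts(
    raw_hist: FrequencyHistogram,
    m: int,
    tol_counts: float = DEFAULT_TOL_COUNTS,
    max_outer: int = DEFAULT_MAX_OUTER,
    init: MixtureModel | None = None,
    **em_kwargs,
) -> AugmentedFit:
    """Alternate EM fitting with low-count re-estimation until stable.

    ``raw_hist`` must contain raw tallies only (x >= 1).  Each outer
    iteration fits the mixture to the current histogram (warm-starting
    from the previous fit), re-estimates N_0..N_3 from the tail, and
    replaces the histogram's low-count weights with the estimates.
    Convergence: max absolute change of (N_0..N_3) < ``tol_counts``
    (default half a k-mer).
    """
    if np.any(raw_hist.xs < 1):
        raise ValueError("raw histogram may not contain an x = 0 entry")
    hist = raw_hist
    prev_est: dict[int, float] | None = None
    model = init
    converged = False
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        res = run_em(hist, m=None if model is not None else m, init=model, **em_kwargs)
        model = res.model
        est = estimate_low_counts(hist, model, Z=res.responsibilities)
        hist = raw_hist.with_low_counts(est)
        if prev_est is not None:
            delta = max(abs(est[x] - prev_est[x]) for x in LOW_COUNTS)
            if delta < tol_counts:
                converged = True
                break
        prev_est = est
    if not converged:
        warnings.warn(
            f"low-count estimates did not stabilise in {max_outer} outer iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    # refit once on the final augmented histogram so model/Z match it
    res = run_em(hist, init=model, **em_kwargs)
    return AugmentedFit(
        hist=hist,
        model=res.model,
        responsibilities=res.responsibilities,
        low_counts=est,
        n_outer=n_outer,
        converged=converged,
        em_result=res,
    )
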