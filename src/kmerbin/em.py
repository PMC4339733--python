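"""Poisson mixture fitting on the k-mer frequency histogram by EM.

The model: each distinct k-mer's occurrence count x_i is drawn from one of
m Poisson components; component j has mixing weight α_j (the relative
abundance of species j among distinct k-mers) and rate λ_j (the k-mer
coverage of species j).  Because the E-step responsibility of k-mer i
depends on i only through its count x_i, EM is run on the weighted
histogram of counts — mathematically identical to the per-k-mer fit but
O(#distinct count values × m) per iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

#: counts >= this value are raw tallies; 0..3 may carry estimated weights
OBSERVED_CUT = 4

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 10_000


@dataclass
class FrequencyHistogram:
    """Weighted histogram of k-mer occurrence counts.

    ``xs`` are the distinct count values (sorted, unique) and ``weights``
    the number of distinct k-mers at each count.  Weights at x >= 4 are
    integer raw tallies; entries at x = 0..3 may hold real-valued
    estimates of the unobserved/unreliable low-count k-mers.
    """

    xs: np.ndarray
    weights: np.ndarray
    observed_cut: int = OBSERVED_CUT

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.xs.shape != self.weights.shape:
            raise ValueError("xs/weights misaligned")
        if self.xs.size and (np.any(np.diff(self.xs) <= 0) or self.xs[0] < 0):
            raise ValueError("xs must be sorted, unique, non-negative")
        if np.any(self.weights < 0):
            raise ValueError("negative histogram weight")
        if self.total_weight <= 0:
            raise ValueError("histogram has no mass")

    @property
    def total_weight(self) -> float:
        """n' — the (possibly augmented) number of distinct k-mers."""
        return float(self.weights.sum())

    @property
    def entries(self) -> dict[int, float]:
        return {int(x): float(w) for x, w in zip(self.xs, self.weights)}

    @classmethod
    def from_entries(cls, entries: dict[int, float]) -> "FrequencyHistogram":
        xs = np.array(sorted(entries), dtype=np.int64)
        return cls(xs=xs, weights=np.array([entries[int(x)] for x in xs]))

    @classmethod
    def from_spectrum(cls, spectrum) -> "FrequencyHistogram":
        xs, tallies = np.unique(spectrum.counts, return_counts=True)
        return cls(xs=xs, weights=tallies.astype(np.float64))

    def observed_tail(self) -> "FrequencyHistogram":
        """The raw part of the histogram (x >= observed_cut)."""
        keep = self.xs >= self.observed_cut
        return FrequencyHistogram(xs=self.xs[keep], weights=self.weights[keep])

    def with_low_counts(self, estimates: dict[int, float]) -> "FrequencyHistogram":
        """Replace the weights at x = 0..3 with estimated values.

        Raw weights at x >= observed_cut are never altered; zero-weight
        low-count entries are dropped.
        """
        if any(x >= self.observed_cut or x < 0 for x in estimates):
            raise ValueError("estimates may only cover x = 0..3")
        ent = {x: w for x, w in self.entries.items() if x >= self.observed_cut}
        for x, w in estimates.items():
            if w > 0:
                ent[int(x)] = float(w)
        return FrequencyHistogram.from_entries(ent)


@dataclass
class MixtureModel:
    """θ = {α_1..α_m; λ_1..λ_m}: abundances and k-mer coverages."""

    alphas: np.ndarray
    lambdas: np.ndarray

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=np.float64)
        self.lambdas = np.asarray(self.lambdas, dtype=np.float64)
        if self.alphas.shape != self.lambdas.shape or self.alphas.ndim != 1:
            raise ValueError("alphas/lambdas must be equal-length vectors")
        if self.alphas.size < 1:
            raise ValueError("empty mixture")
        if np.any(self.alphas < 0) or abs(self.alphas.sum() - 1.0) > 1e-9:
            raise ValueError("alphas must be non-negative and sum to 1")
        if np.any(self.lambdas <= 0):
            raise ValueError("lambdas must be positive")

    @property
    def m(self) -> int:
        return int(self.alphas.size)

    def sorted_by_lambda(self) -> "MixtureModel":
        order = np.argsort(self.lambdas)
        return MixtureModel(alphas=self.alphas[order], lambdas=self.lambdas[order])


def default_init(m: int) -> MixtureModel:
    """Standard initialisation: α_j = 1/m, λ_j = 10 j + 10 for j = 1..m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    j = np.arange(1, m + 1, dtype=np.float64)
    return MixtureModel(alphas=np.full(m, 1.0 / m), lambdas=10.0 * j + 10.0)


def poisson_pmf(lam: float, x) -> float | np.ndarray:
    """Poisson pmf λ^x e^{-λ} / x!, evaluated in log space."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return np.exp(poisson.logpmf(x, lam))


def _log_component_matrix(hist: FrequencyHistogram, model: MixtureModel) -> np.ndarray:
    """log(α_j p_j(λ_j, x)) for every (x in support, component j).

    The Poisson log-pmf x ln λ − λ − ln Γ(x+1) is inlined (rather than
    calling scipy per iteration) because this sits in the EM hot loop.
    """
    x = hist.xs[:, None].astype(np.float64)
    lam = model.lambdas[None, :]
    with np.errstate(divide="ignore"):
        la = np.log(model.alphas)
    return la[None, :] + x * np.log(lam) - lam - gammaln(x + 1.0)


def _e_step_with_norm(
    hist: FrequencyHistogram, model: MixtureModel
) -> tuple[np.ndarray, np.ndarray]:
    """Responsibilities plus the per-x log mixture density."""
    logw = _log_component_matrix(hist, model)
    norm = logsumexp(logw, axis=1)
    dead = ~np.isfinite(norm)
    Z = np.empty_like(logw)
    with np.errstate(invalid="ignore"):
        Z[~dead] = np.exp(logw[~dead] - norm[~dead, None])
    if dead.any():
        warnings.warn(
            f"mixture density underflowed at counts {hist.xs[dead].tolist()}; "
            "assigning uniform responsibilities",
            RuntimeWarning,
            stacklevel=2,
        )
        Z[dead] = 1.0 / model.m
    return Z, norm


def e_step(hist: FrequencyHistogram, model: MixtureModel) -> np.ndarray:
    """Responsibilities Z(x, j) = α_j p_j(λ_j,x) / Σ_r α_r p_r(λ_r,x).

    Rows whose mixture density underflows in every component are set
    uniform (1/m) with a warning.
    """
    return _e_step_with_norm(hist, model)[0]


def m_step(
    hist: FrequencyHistogram, Z: np.ndarray, prev: MixtureModel | None = None
) -> MixtureModel:
    """Update α_j = Σ_x w_x Z(x,j) / n' and λ_j = Σ_x w_x Z(x,j) x / Σ_x w_x Z(x,j).

    A component with zero total responsibility keeps its previous λ (or
    1.0 if no previous model is supplied) and gets α = 0, with a warning.
    """
    wz = hist.weights[:, None] * Z
    mass = wz.sum(axis=0)
    alphas = mass / hist.total_weight
    lambdas = np.empty_like(mass)
    ok = mass > 0
    lambdas[ok] = (wz[:, ok] * hist.xs[:, None]).sum(axis=0) / mass[ok]
    if not ok.all():
        warnings.warn(
            "component(s) with zero responsibility; keeping previous lambda",
            RuntimeWarning,
            stacklevel=2,
        )
        lambdas[~ok] = prev.lambdas[~ok] if prev is not None else 1.0
    # λ = 0 can only arise if all mass sits at x = 0; floor it to stay valid
    lambdas = np.maximum(lambdas, 1e-12)
    alphas = alphas / alphas.sum()
    return MixtureModel(alphas=alphas, lambdas=lambdas)


def log_likelihood(hist: FrequencyHistogram, model: MixtureModel) -> float:
    """Observed-data log-likelihood Σ_x w_x log Σ_j α_j p_j(λ_j, x)."""
    _, norm = _e_step_with_norm(hist, model)
    return float(np.sum(hist.weights * norm))


@dataclass
class EMResult:
    """Outcome of one EM fit."""

    model: MixtureModel
    responsibilities: np.ndarray = field(repr=False)
    log_likelihood: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)


def run_em(
    hist: FrequencyHistogram,
    m: int | None = None,
    init: MixtureModel | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EMResult:
    """Fit an m-component Poisson mixture to the histogram.

    Starts from ``init`` if given, else from :func:`default_init`.
    Convergence: maximum absolute change over all 2m parameters < ``tol``.
    """
    if init is None:
        if m is None:
            raise ValueError("either m or init is required")
        init = default_init(m)
    elif m is not None and init.m != m:
        raise ValueError("init.m disagrees with m")
    model = init
    trace: list[float] = []
    converged = False
    Z, _ = _e_step_with_norm(hist, model)
    it = 0
    for it in range(1, max_iter + 1):
        new = m_step(hist, Z, prev=model)
        delta = max(
            np.max(np.abs(new.alphas - model.alphas)),
            np.max(np.abs(new.lambdas - model.lambdas)),
        )
        model = new
        Z, norm = _e_step_with_norm(hist, model)
        trace.append(float(np.sum(hist.weights * norm)))
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations", RuntimeWarning, stacklevel=2
        )
    return EMResult(
        model=model,
        responsibilities=Z,
        log_likelihood=trace[-1],
        n_iter=it,
        converged=converged,
        loglik_trace=trace,
    )
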