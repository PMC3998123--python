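"""Beta-binomial error kernel and cohort-based moment estimators.

The error model treats the count of a non-reference nucleotide at a site,
in a given read orientation, as beta-binomially distributed: the per-sample
error probability is Beta-distributed around a site-specific mean ``mu``
with intraclass correlation ``rho`` shared across samples.  ``rho = 0``
recovers the plain binomial.  Site error rates are estimated by pooling
counts over an aggregate control built from all other cohort samples whose
variant allele frequency falls below a threshold, and ``rho`` is estimated
per site and allele by the method of moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BetaBinParams",
    "ControlCounts",
    "SiteErrorModel",
    "betabinom_logpmf",
    "betabinom_pmf",
    "select_reference_set",
    "aggregate_controls",
    "estimate_error_rates",
    "estimate_sample_vaf",
    "estimate_rho",
    "fit_site_error_model",
]

# Below this dispersion the betaln-based pmf loses precision (alpha, beta
# grow like 1/rho and the log-gamma cancellation error exceeds the pmf
# itself); the binomial limit is then exact to O(n^2 rho) < 1e-8.
_RHO_BINOMIAL_EPS = 1e-10


@dataclass(frozen=True)
class BetaBinParams:
    """Mean/dispersion parameterization of the beta-binomial.

    alpha = mu * (1 - rho) / rho, beta = (1 - mu) * (1 - rho) / rho.
    """

    mu: float
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")


@dataclass(frozen=True)
class ControlCounts:
    """Aggregate variant counts and coverages of a reference sample set."""

    x_fwd: int
    x_rev: int
    n_fwd: int
    n_rev: int

    def __post_init__(self) -> None:
        for x, n, s in ((self.x_fwd, self.n_fwd, "fwd"), (self.x_rev, self.n_rev, "rev")):
            if not 0 <= x <= n:
                raise ValueError(f"require 0 <= x <= n on {s} strand, got x={x}, n={n}")


@dataclass
class SiteErrorModel:
    """Pooled per-(site, allele) error rates and dispersions for a cohort.

    ``mu_fwd``/``mu_rev`` have shape (n_sites, n_alleles); ``rho`` is shared
    across strands with the same shape.  ``n_controls`` counts the samples
    that passed the VAF filter at each (site, allele).
    """

    mu_fwd: np.ndarray
    mu_rev: np.ndarray
    rho: np.ndarray
    n_controls: np.ndarray


def _validate_pmf_args(x, n, mu, rho) -> None:
    if np.any(x < 0) or np.any(n < 0) or np.any(x > n):
        raise ValueError("require 0 <= x <= n")
    if np.any(mu < 0) or np.any(mu > 1):
        raise ValueError("mu must be in [0, 1]")
    if np.any(rho < 0) or np.any(rho >= 1):
        raise ValueError("rho must be in [0, 1)")


def betabinom_logpmf(x, n, mu, rho):
    """Log pmf of the beta-binomial in mean/dispersion form; vectorized.

    ``mu`` on the boundary is handled as the degenerate limit (all mass at
    0 or n); ``rho`` below 1e-10 is evaluated as the binomial it converges
    to, which is more accurate there than the log-beta route.
    """
    x, n, mu, rho = np.broadcast_arrays(
        np.asarray(x), np.asarray(n), np.asarray(mu, dtype=float), np.asarray(rho, dtype=float)
    )
    _validate_pmf_args(x, n, mu, rho)
    scalar = x.ndim == 0
    x = np.atleast_1d(x).astype(np.int64)
    n = np.atleast_1d(n).astype(np.int64)
    mu = np.atleast_1d(mu)
    rho = np.atleast_1d(rho)

    out = np.full(x.shape, -np.inf, dtype=float)
    lo = mu <= 0.0
    hi = mu >= 1.0
    interior = ~lo & ~hi
    out[lo & (x == 0)] = 0.0
    out[hi & (x == n)] = 0.0

    binom_like = interior & (rho < _RHO_BINOMIAL_EPS)
    if np.any(binom_like):
        m = binom_like
        out[m] = stats.binom.logpmf(x[m], n[m], mu[m])
    bb = interior & ~binom_like
    if np.any(bb):
        a = mu[bb] * (1.0 - rho[bb]) / rho[bb]
        b = (1.0 - mu[bb]) * (1.0 - rho[bb]) / rho[bb]
        out[bb] = stats.betabinom.logpmf(x[bb], n[bb], a, b)
    return out[0] if scalar else out


def betabinom_pmf(x, n, params: BetaBinParams | None = None, *, mu=None, rho=None):
    """Beta-binomial pmf; accepts a :class:`BetaBinParams` or mu/rho keywords."""
    if params is not None:
        mu, rho = params.mu, params.rho
    return np.exp(betabinom_logpmf(x, n, mu, rho))


def estimate_sample_vaf(x_fwd, n_fwd, x_rev=None, n_rev=None):
    """Per-strand variant allele frequencies x/n, defined as 0 at n = 0.

    With only the first two arguments it returns a single ratio; with all
    four it returns the (fwd, rev) pair.
    """
    def _ratio(x, n):
        x = np.asarray(x, dtype=float)
        n = np.asarray(n, dtype=float)
        return np.where(n > 0, x / np.maximum(n, 1.0), 0.0)[()]

    if x_rev is None:
        return _ratio(x_fwd, n_fwd)
    return _ratio(x_fwd, n_fwd), _ratio(x_rev, n_rev)


def select_reference_set(tensor, target: int, site: int, allele: int, vaf_threshold: float = 0.1) -> np.ndarray:
    """Indices of the aggregate-control samples for one hypothesis.

    All samples other than ``target`` whose combined-strand VAF at
    (site, allele) is strictly below ``vaf_threshold``; zero-coverage
    samples count as VAF 0 and are kept.
    """
    x = tensor.counts[:, site, allele, :].sum(axis=1)
    n = tensor.coverage[:, site, :].sum(axis=1)
    vaf = estimate_sample_vaf(x, n)
    mask = np.asarray(vaf) < vaf_threshold
    mask[target] = False
    return np.flatnonzero(mask)


def aggregate_controls(tensor, reference_set, site: int, allele: int) -> ControlCounts:
    """Element-wise sums of counts and coverages over the reference set."""
    ref = np.asarray(reference_set, dtype=np.int64)
    x = tensor.counts[ref, site, allele, :].sum(axis=0) if ref.size else np.zeros(2, dtype=np.int64)
    n = tensor.coverage[ref, site, :].sum(axis=0) if ref.size else np.zeros(2, dtype=np.int64)
    return ControlCounts(x_fwd=int(x[0]), x_rev=int(x[1]), n_fwd=int(n[0]), n_rev=int(n[1]))


def estimate_error_rates(
    control: ControlCounts,
    target_fwd: tuple[int, int],
    target_rev: tuple[int, int],
    pseudocount: float = 0.5,
    pool_target: bool = True,
):
    """Method-of-moments strand-specific error rates of the null model.

    The null pools the target sample with its aggregate control at a single
    rate per strand: mu = (X + x + c) / (N + n + 2c) with pseudocount c > 0,
    which keeps the estimate strictly inside (0, 1) even at zero coverage.
    ``pool_target=False`` gives the leave-one-out variant (controls only).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    c = pseudocount

    def _rate(big_x, big_n, x, n):
        if pool_target:
            return (big_x + x + c) / (big_n + n + 2.0 * c)
        return (big_x + c) / (big_n + 2.0 * c)

    mu_fwd = _rate(control.x_fwd, control.n_fwd, *target_fwd)
    mu_rev = _rate(control.x_rev, control.n_rev, *target_rev)
    return mu_fwd, mu_rev


def estimate_rho(vafs, coverages, bounds: tuple[float, float] = (1e-4, 0.1)) -> float:
    """Method-of-moments intraclass-correlation (dispersion) estimate.

    With nu_i the combined-strand VAFs and n_i the combined coverages of
    the reference-set samples, mu the coverage-weighted mean VAF, s^2 the
    sample variance of nu_i and m = mean(1/n_i):

        rho = (s^2 - mu (1 - mu) m) / (mu (1 - mu) (1 - m))

    clamped to ``bounds``.  Degenerate inputs (fewer than 2 covered
    samples, mu on the boundary, zero variance) return the lower bound.
    """
    rho_min, rho_max = bounds
    if not 0.0 <= rho_min <= rho_max < 1.0:
        raise ValueError(f"invalid rho bounds {bounds}")
    v = np.asarray(vafs, dtype=float)
    n = np.asarray(coverages, dtype=float)
    usable = n > 0
    if usable.sum() < 2:
        return rho_min
    v, n = v[usable], n[usable]
    mu = float(np.sum(v * n) / np.sum(n))
    if mu <= 0.0 or mu >= 1.0:
        return rho_min
    s2 = float(np.var(v, ddof=1))
    m = float(np.mean(1.0 / n))
    denom = mu * (1.0 - mu) * (1.0 - m)
    if denom <= 0.0:
        return rho_min
    rho = (s2 - mu * (1.0 - mu) * m) / denom
    return float(min(max(rho, rho_min), rho_max))


def fit_site_error_model(tensor, config=None) -> SiteErrorModel:
    """Pooled error-rate and dispersion tracks over the whole cohort.

    Diagnostic summary (the per-target calling path re-derives its own
    leave-one-out quantities): for each (site, allele) the samples with
    combined VAF below the threshold are pooled into mu per strand, and
    rho is estimated from their combined-strand VAFs.
    """
    from .calling import CallConfig  # local import to avoid a cycle

    config = config or CallConfig()
    n_sites = len(tensor.sites)
    n_alleles = tensor.counts.shape[2]
    mu_fwd = np.empty((n_sites, n_alleles))
    mu_rev = np.empty((n_sites, n_alleles))
    rho = np.empty((n_sites, n_alleles))
    n_controls = np.empty((n_sites, n_alleles), dtype=np.int64)
    c = config.pseudocount
    tot_n = tensor.coverage.sum(axis=2)  # (S, J)
    for j in range(n_sites):
        for k in range(n_alleles):
            x = tensor.counts[:, j, k, :]
            vaf = estimate_sample_vaf(x.sum(axis=1), tot_n[:, j])
            passing = np.asarray(vaf) < config.vaf_threshold
            X = x[passing].sum(axis=0)
            N = tensor.coverage[passing, j, :].sum(axis=0)
            mu_fwd[j, k] = (X[0] + c) / (N[0] + 2 * c)
            mu_rev[j, k] = (X[1] + c) / (N[1] + 2 * c)
            if config.rho_fixed is not None:
                rho[j, k] = config.rho_fixed
            else:
                rho[j, k] = estimate_rho(
                    np.asarray(vaf)[passing], tot_n[passing, j], (config.rho_min, config.rho_max)
                )
            n_controls[j, k] = int(passing.sum())
    return SiteErrorModel(mu_fwd=mu_fwd, mu_rev=mu_rev, rho=rho, n_controls=n_controls)
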