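"""Synthetic cohorts and power/AUC benchmarks for the caller.

The generator mirrors the structure of deep targeted resequencing of a
cohort: per-site, per-strand coverages (fixed or lognormal, calibrated to
a deeply sequenced normal sample with median ~128x), strand-specific
background error reads drawn beta-binomially with dispersion ``rho_true``,
and implanted true variants adding binomial reads at a chosen VAF on both
strands on top of the background.  A Dirichlet mode draws the whole
per-site VAF vector across samples instead of fixed implants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CallConfig, bf_cutoff_for_posterior, score_hypotheses
from .count_data import ALLELE_INDEX, ALLELES, CountTensor

__all__ = [
    "CoverageModel",
    "ErrorRateModel",
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "evaluate_power",
    "evaluate_auc",
    "benchmark_power_grid",
    "benchmark_auc",
]


@dataclass(frozen=True)
class CoverageModel:
    """Per-(sample, site) total coverage distribution and strand split.

    ``fixed`` uses ``value`` everywhere with a deterministic strand split;
    ``lognormal`` draws totals with the given median and log-scale sigma
    (defaults calibrated to a deep panel normal: median 128x with a long
    right tail) and splits strands binomially at ``strand_frac``.
    """

    kind: str = "lognormal"
    value: int = 250
    median: float = 128.0
    sigma: float = 1.02
    strand_frac: float = 0.5

    def __post_init__(self):
        if self.kind not in ("fixed", "lognormal"):
            raise ValueError(f"unknown coverage model {self.kind!r}")
        if not 0.0 <= self.strand_frac <= 1.0:
            raise ValueError("strand_frac must be in [0, 1]")

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        """Per-strand coverages with trailing axis (fwd, rev)."""
        if self.kind == "fixed":
            total = np.full(shape, int(self.value), dtype=np.int64)
            fwd = np.full(shape, int(round(self.value * self.strand_frac)), dtype=np.int64)
        else:
            total = np.rint(rng.lognormal(np.log(self.median), self.sigma, size=shape)).astype(np.int64)
            fwd = rng.binomial(total, self.strand_frac)
        return np.stack([fwd, total - fwd], axis=-1)


@dataclass(frozen=True)
class ErrorRateModel:
    """Per-site, per-strand baseline error rates.

    A constant ``rate`` by default; with ``high_fraction > 0`` each
    (site, strand) independently becomes a high-error slot at
    ``high_rate``, emulating the recurrent strand-specific artifacts of
    real panels.
    """

    rate: float = 1e-3
    high_fraction: float = 0.0
    high_rate: float = 1e-2

    def __post_init__(self):
        for p in (self.rate, self.high_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error rates must be in [0, 1]")
        if not 0.0 <= self.high_fraction <= 1.0:
            raise ValueError("high_fraction must be in [0, 1]")

    def draw(self, rng: np.random.Generator, n_sites: int) -> np.ndarray:
        rates = np.full((n_sites, 2), self.rate, dtype=float)
        if self.high_fraction > 0.0:
            hi = rng.random((n_sites, 2)) < self.high_fraction
            rates[hi] = self.high_rate
        return rates

    @property
    def max_rate(self) -> float:
        return max(self.rate, self.high_rate if self.high_fraction > 0 else self.rate)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``implant_vafs`` are cycled over the implanted sites (a fraction
    ``implant_fraction`` of all sites, ``carriers_per_site`` random
    carriers each).  ``germline_fraction`` of sites instead receive a
    polymorphism at ``germline_vaf`` in ``germline_carrier_frac`` of the
    samples.  ``dirichlet_alpha`` switches the implant scheme to the
    per-site Dirichlet VAF draw across samples.  ``seed`` is mandatory:
    the cohort is a deterministic function of the config.
    """

    n_samples: int = 500
    n_sites: int = 50
    coverage: CoverageModel = field(default_factory=CoverageModel)
    error: ErrorRateModel = field(default_factory=ErrorRateModel)
    rho_true: float = 1e-4
    implant_vafs: tuple[float, ...] = ()
    implant_fraction: float = 1.0
    carriers_per_site: int = 1
    germline_fraction: float = 0.0
    germline_vaf: float = 0.5
    germline_carrier_frac: float = 0.0
    dirichlet_alpha: float | None = None
    seed: int | None = None
    ref_base: str = "A"
    chrom: str = "sim1"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory for reproducibility")
        if not 0.0 <= self.rho_true < 1.0:
            raise ValueError("rho_true must be in [0, 1)")
        for v in self.implant_vafs:
            if not 0.0 < v <= 1.0:
                raise ValueError(f"implant VAF must be in (0, 1], got {v}")
            if v + self.error.max_rate > 1.0:
                raise ValueError(f"VAF {v} plus error rate exceeds 1")
        if self.germline_fraction > 0 and self.germline_vaf + self.error.max_rate > 1.0:
            raise ValueError("germline VAF plus error rate exceeds 1")


@dataclass
class SimTruth:
    """Implanted ground truth for benchmark evaluation.

    ``implanted`` maps (sample index, site index, allele) to true VAF for
    somatic implants; ``germline`` likewise for polymorphism carriers.
    """

    implanted: dict[tuple[int, int, str], float]
    germline: dict[tuple[int, int, str], float] = field(default_factory=dict)
    site_alt: dict[int, str] = field(default_factory=dict)

    def hypotheses(self, alleles=ALLELES):
        """(sample, site, allele-index) triples for the somatic implants."""
        return [(i, j, ALLELE_INDEX[a]) for (i, j, a) in self.implanted]


def _betabin_draw(rng, n, p, rho):
    """Beta-binomial sample with intraclass correlation rho (0 = binomial)."""
    p = np.broadcast_to(np.asarray(p, dtype=float), n.shape)
    if rho < 1e-10:
        return rng.binomial(n, p)
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    pp = np.empty(n.shape, dtype=float)
    pos = (a > 0) & (b > 0)
    pp[pos] = rng.beta(a[pos], b[pos])
    pp[~pos] = p[~pos]  # degenerate rate 0 or 1
    return rng.binomial(n, pp)


def simulate_cohort(config: SimConfig):
    """Generate a cohort count tensor and its ground truth.

    Each site gets one designated alternative allele; background error
    reads for it are drawn beta-binomially per strand, implanted variants
    add binomial(coverage, VAF) reads on both strands on top, capped at
    coverage, and the reference allele absorbs the remaining coverage.
    """
    rng = np.random.default_rng(config.seed)
    S, J = config.n_samples, config.n_sites

    alt_choices = [a for a in "ACGT" if a != config.ref_base]
    site_alt = {j: alt_choices[rng.integers(len(alt_choices))] for j in range(J)}
    rates = config.error.draw(rng, J)  # (J, 2)
    cov = config.coverage.draw(rng, (S, J))  # (S, J, 2)

    bg = np.empty((S, J, 2), dtype=np.int64)
    for s in range(2):
        bg[:, :, s] = _betabin_draw(rng, cov[:, :, s], rates[None, :, s], config.rho_true)

    var = np.zeros((S, J, 2), dtype=np.int64)
    implanted: dict[tuple[int, int, str], float] = {}
    germline: dict[tuple[int, int, str], float] = {}

    if config.dirichlet_alpha is not None:
        # one Dirichlet draw of the VAF vector across samples per site; the
        # extra component is the unassigned (reference) mass
        alpha = np.full(S + 1, config.dirichlet_alpha, dtype=float)
        for j in range(J):
            nu = rng.dirichlet(alpha)[:S]
            var[:, j, 0] = rng.binomial(cov[:, j, 0], np.minimum(nu, 1.0))
            var[:, j, 1] = rng.binomial(cov[:, j, 1], np.minimum(nu, 1.0))
            for i in np.flatnonzero(nu > 0):
                implanted[(int(i), j, site_alt[j])] = float(nu[i])
    else:
        n_germ = int(round(config.germline_fraction * J))
        sites_perm = rng.permutation(J)
        germ_sites = set(sites_perm[:n_germ].tolist())
        somatic_pool = [j for j in sites_perm.tolist() if j not in germ_sites]
        n_implant = int(round(config.implant_fraction * len(somatic_pool)))
        implant_sites = somatic_pool[:n_implant] if config.implant_vafs else []

        for j in sorted(germ_sites):
            n_carriers = int(round(config.germline_carrier_frac * S))
            carriers = rng.choice(S, size=n_carriers, replace=False)
            for i in carriers:
                for s in range(2):
                    var[i, j, s] += rng.binomial(cov[i, j, s], config.germline_vaf)
                germline[(int(i), j, site_alt[j])] = config.germline_vaf

        for idx, j in enumerate(implant_sites):
            vaf = config.implant_vafs[idx % len(config.implant_vafs)]
            carriers = rng.choice(S, size=config.carriers_per_site, replace=False)
            for i in carriers:
                for s in range(2):
                    var[i, j, s] += rng.binomial(cov[i, j, s], vaf)
                implanted[(int(i), j, site_alt[j])] = float(vaf)

    alt_total = np.minimum(bg + var, cov)

    counts = np.zeros((S, J, len(ALLELES), 2), dtype=np.int64)
    for j in range(J):
        k = ALLELE_INDEX[site_alt[j]]
        counts[:, j, k, :] = alt_total[:, j, :]
    counts[:, :, ALLELE_INDEX[config.ref_base], :] = cov - alt_total

    sites = [(config.chrom, j) for j in range(J)]
    tensor = CountTensor(
        sample_ids=[f"S{i:04d}" for i in range(S)],
        sites=sites,
        counts=counts,
        coverage=cov,
        ref_allele=[config.ref_base] * J,
    )
    return tensor, SimTruth(implanted=implanted, germline=germline, site_alt=site_alt)


def evaluate_power(scores, cutoff: float, strata=None) -> pd.DataFrame:
    """Fraction of truth-positive hypotheses scoring below ``cutoff``.

    ``scores`` are Bayes factors (or posteriors) of implanted variants;
    rows are per stratum when ``strata`` labels are given, with exact
    (Clopper-Pearson) binomial confidence intervals.  Empty strata are
    omitted with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    strata = np.zeros(len(scores), dtype=int) if strata is None else np.asarray(strata)
    rows = []
    for stratum in pd.unique(strata):
        sel = scores[strata == stratum]
        sel = sel[~np.isnan(sel)]
        if len(sel) == 0:
            warnings.warn(f"stratum {stratum!r} has no scored hypotheses; omitted")
            continue
        k = int(np.sum(sel < cutoff))
        ci = stats.binomtest(k, len(sel)).proportion_ci(confidence_level=0.95, method="exact")
        rows.append(
            {"stratum": stratum, "n": len(sel), "power": k / len(sel),
             "ci_low": ci.low, "ci_high": ci.high}
        )
    return pd.DataFrame(rows, columns=["stratum", "n", "power", "ci_low", "ci_high"])


def evaluate_auc(scores, labels) -> float:
    """Rank-based AUC of (-score) against binary truth, mid-rank ties.

    Small scores (Bayes factors) should mark positives.  Equivalent to
    the Mann-Whitney statistic normalized by n1 * n0.
    """
    scores = -np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both positive and negative hypotheses")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _cell_seed(seed: int, *key) -> int:
    return int(np.random.SeedSequence([int(seed), *[int(k) for k in key]]).generate_state(1)[0] % (2**31))


def benchmark_power_grid(
    vaf_grid,
    coverage_grid,
    *,
    seed: int,
    n_samples: int = 500,
    sites_per_cell: int = 200,
    n_reps: int = 1,
    error: ErrorRateModel | None = None,
    rho_true: float = 1e-4,
    call_config: CallConfig | None = None,
    bf_cutoff: float | None = None,
    out_path=None,
) -> pd.DataFrame:
    """Detection power over a (VAF, coverage) grid of simulated cohorts.

    Each cell simulates ``n_reps`` cohorts of ``n_samples`` samples with
    fixed per-site coverage, one implanted carrier per site, scores the
    implanted hypotheses through the full caller and reports the fraction
    whose Bayes factor falls below ``bf_cutoff`` (by default the cutoff
    matching the call config's posterior cutoff at its default prior).
    Dispersion handling follows ``call_config``: a fixed rho or the
    per-site moment estimate.
    """
    vaf_grid = list(vaf_grid)
    coverage_grid = list(coverage_grid)
    if not vaf_grid or not coverage_grid:
        raise ValueError("vaf_grid and coverage_grid must be non-empty")
    error = error or ErrorRateModel()
    call_config = call_config or CallConfig(rho_fixed=1e-4)
    if bf_cutoff is None:
        bf_cutoff = bf_cutoff_for_posterior(call_config.posterior_cutoff, call_config.pi0)

    rows = []
    for vi, vaf in enumerate(vaf_grid):
        for ci, cov in enumerate(coverage_grid):
            scores = []
            for rep in range(n_reps):
                cfg = SimConfig(
                    n_samples=n_samples,
                    n_sites=sites_per_cell,
                    coverage=CoverageModel(kind="fixed", value=int(cov)),
                    error=error,
                    rho_true=rho_true,
                    implant_vafs=(float(vaf),),
                    seed=_cell_seed(seed, vi, ci, rep),
                )
                tensor, truth = simulate_cohort(cfg)
                scores.append(score_hypotheses(tensor, truth.hypotheses(), call_config))
            power = evaluate_power(np.concatenate(scores), bf_cutoff)
            rows.append(
                {"vaf": vaf, "coverage": cov, "n": int(power.loc[0, "n"]),
                 "power": float(power.loc[0, "power"]),
                 "ci_low": float(power.loc[0, "ci_low"]), "ci_high": float(power.loc[0, "ci_high"])}
            )
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def benchmark_auc(
    vaf: float,
    *,
    seed: int,
    n_samples: int = 500,
    n_sites: int = 2000,
    coverage: CoverageModel | None = None,
    error: ErrorRateModel | None = None,
    rho_true: float = 1e-4,
    call_config: CallConfig | None = None,
) -> float:
    """AUC for separating implanted variants from null hypotheses.

    Implants one carrier at ``vaf`` at half the sites under the (default
    lognormal, median 128x) coverage profile, scores the carrier
    hypotheses and one matched null hypothesis per non-implanted site
    (same machinery, random sample), and returns the rank-based AUC of
    the negated Bayes factors.  Unscorable hypotheses count as BF = 1.
    """
    coverage = coverage or CoverageModel(kind="lognormal")
    error = error or ErrorRateModel()
    call_config = call_config or CallConfig(rho_fixed=1e-4)
    cfg = SimConfig(
        n_samples=n_samples,
        n_sites=n_sites,
        coverage=coverage,
        error=error,
        rho_true=rho_true,
        implant_vafs=(float(vaf),),
        implant_fraction=0.5,
        seed=seed,
    )
    tensor, truth = simulate_cohort(cfg)
    pos = truth.hypotheses()
    implanted_sites = {j for (_, j, _) in truth.implanted}
    rng = np.random.default_rng(_cell_seed(cfg.seed, 1))
    neg = [
        (int(rng.integers(n_samples)), j, ALLELE_INDEX[truth.site_alt[j]])
        for j in range(n_sites)
        if j not in implanted_sites
    ]
    scores = score_hypotheses(tensor, pos + neg, call_config)
    scores = np.where(np.isnan(scores), 1.0, scores)
    labels = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    return evaluate_auc(scores, labels)
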