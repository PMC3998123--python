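"""Bayes-factor model selection, hotspot priors and cohort-wide calling.

For each (sample, site, non-reference allele) the null model M0 states
that the sample's allele rate equals the pooled error rate on the forward
OR on the reverse strand — so a signal confined to one strand stays null —
while the alternative M1 allows rates above the error rate on both
strands.  The Bayes factor BF = P(D|M0)/P(D|M1) is approximated with
beta-binomial plug-in point estimates and combined with a per-site,
per-allele prior (from a mutation-hotspot catalogue, or a default) into
the posterior null probability; calls are made below a posterior cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .error_model import betabinom_logpmf, estimate_rho, estimate_sample_vaf

logger = logging.getLogger(__name__)

__all__ = [
    "CallConfig",
    "PriorTrack",
    "VariantCall",
    "bayes_factor",
    "posterior_null",
    "bf_cutoff_for_posterior",
    "build_mutation_histogram",
    "build_prior_track",
    "read_hotspot_catalogue",
    "read_gene_probabilities",
    "read_exclusion_list",
    "call_variants",
    "score_hypotheses",
]


@dataclass(frozen=True)
class CallConfig:
    """Thresholds and model switches for the caller.

    vaf_threshold    reference-set VAF cutoff (samples below it form the
                     aggregate control), default 0.1
    pseudocount      Jeffreys-like pseudocount in the error-rate estimate
    rho_min/rho_max  clamp bounds for the estimated dispersion
    rho_fixed        bypass estimation with a fixed dispersion
    strand_mode      "both" (OR-structured null) or "agnostic" (pooled
                     strands, single comparison)
    numerator        "inclusion_exclusion" subtracts the double-counted
                     both-strands-null term (floored at 0); "additive"
                     keeps the plain two-term sum
    nu_mode          "raw" plugs in nu = x/n under M1; "excess" subtracts
                     the estimated error rate first
    posterior_cutoff call when P(M0|D) <= this value
    pi0              default prior for sites absent from the catalogue
    pool_target      pool the target sample into the error-rate estimate
                     (the null puts all samples at one rate); False gives
                     strict leave-one-out rates
    """

    vaf_threshold: float = 0.1
    pseudocount: float = 0.5
    rho_min: float = 1e-4
    rho_max: float = 0.1
    rho_fixed: float | None = None
    strand_mode: str = "both"
    numerator: str = "inclusion_exclusion"
    nu_mode: str = "raw"
    posterior_cutoff: float = 0.5
    pi0: float = 1e-4
    pool_target: bool = True
    exclusion: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.strand_mode not in ("both", "agnostic"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")
        if self.numerator not in ("inclusion_exclusion", "additive"):
            raise ValueError(f"unknown numerator mode {self.numerator!r}")
        if self.nu_mode not in ("raw", "excess"):
            raise ValueError(f"unknown nu_mode {self.nu_mode!r}")
        if not 0.0 < self.pi0 < 1.0:
            raise ValueError("pi0 must be in (0, 1)")
        if not 0.0 <= self.rho_min <= self.rho_max < 1.0:
            raise ValueError("require 0 <= rho_min <= rho_max < 1")

    @classmethod
    def from_yaml(cls, path) -> "CallConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "exclusion" in data:
            data["exclusion"] = frozenset(tuple(e) for e in data["exclusion"])
        return cls(**data)

    def with_overrides(self, **kwargs) -> "CallConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass
class PriorTrack:
    """Per-(site, allele) prior variant probabilities with a default.

    Keys are (chrom, pos0, alt) with 0-based positions; sites absent from
    the track fall back to ``pi0``.
    """

    pi: dict[tuple[str, int, str], float]
    pi0: float = 1e-4

    def __post_init__(self):
        if not 0.0 < self.pi0 < 1.0:
            raise ValueError("pi0 must be in (0, 1)")
        for key, value in self.pi.items():
            if not 0.0 < value < 1.0:
                raise ValueError(f"prior for {key} must be in (0, 1), got {value}")

    def get(self, chrom: str, pos: int, alt: str) -> float:
        return self.pi.get((chrom, pos, alt), self.pi0)


@dataclass
class VariantCall:
    """One (sample, site, allele) candidate with its evidence."""

    sample: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    bf: float
    posterior_m0: float
    pi: float
    vaf_fwd: float
    vaf_rev: float
    vaf_combined: float
    x_fwd: int
    x_rev: int
    n_fwd: int
    n_rev: int
    rho_used: float
    mu_fwd: float
    mu_rev: float


def bayes_factor(
    x_fwd,
    n_fwd,
    x_rev,
    n_rev,
    mu_fwd,
    mu_rev,
    nu_fwd,
    nu_rev,
    rho,
    strand_mode: str = "both",
    numerator: str = "inclusion_exclusion",
):
    """Plug-in Bayes factor P(D|M0)/P(D|M1); vectorized, log-space inside.

    With L_s(theta) the beta-binomial pmf of strand s at rate theta, the
    OR-structured null gives (inclusion–exclusion over the two ways of
    being null, third term subtracted and the result floored at 0):

        BF = [L_f(mu_f) L_r(nu_r) + L_f(nu_f) L_r(mu_r)
              - L_f(mu_f) L_r(mu_r)] / [L_f(nu_f) L_r(nu_r)]

    Strands with zero coverage contribute factor 1, so a hypothesis with
    no coverage anywhere (or one uncovered strand under the OR null) has
    BF = 1: no evidence either way.
    """
    x_fwd, n_fwd, x_rev, n_rev = (np.asarray(a) for a in (x_fwd, n_fwd, x_rev, n_rev))
    if strand_mode == "agnostic":
        x = x_fwd + x_rev
        n = n_fwd + n_rev
        n_safe = np.maximum(n, 1)
        mu = np.where(n > 0, (np.asarray(mu_fwd) * n_fwd + np.asarray(mu_rev) * n_rev) / n_safe, 0.5)
        nu = np.where(n > 0, (np.asarray(nu_fwd) * n_fwd + np.asarray(nu_rev) * n_rev) / n_safe, 0.0)
        log_bf = betabinom_logpmf(x, n, mu, rho) - betabinom_logpmf(x, n, nu, rho)
        bf = np.exp(log_bf)
        return np.where(n > 0, bf, 1.0)[()]

    log_rf = betabinom_logpmf(x_fwd, n_fwd, mu_fwd, rho) - betabinom_logpmf(x_fwd, n_fwd, nu_fwd, rho)
    log_rr = betabinom_logpmf(x_rev, n_rev, mu_rev, rho) - betabinom_logpmf(x_rev, n_rev, nu_rev, rho)
    rf, rr = np.exp(log_rf), np.exp(log_rr)
    if numerator == "inclusion_exclusion":
        bf = rf + rr - np.exp(log_rf + log_rr)
    else:
        bf = rf + rr
    bf = np.maximum(bf, 0.0)
    # both terms underflown (log ratios -inf -> nan): no usable evidence
    bf = np.where(np.isnan(bf), 1.0, bf)
    return bf[()]


def posterior_null(bf, pi):
    """P(M0|D) by Bayes' formula: bf (1 - pi) / (bf (1 - pi) + pi)."""
    bf = np.asarray(bf, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(bf < 0):
        raise ValueError("Bayes factors must be non-negative")
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("pi must be in (0, 1)")
    odds = bf * (1.0 - pi)
    return (odds / (odds + pi))[()]


def bf_cutoff_for_posterior(posterior_cutoff: float, pi: float) -> float:
    """The BF below which the posterior falls below ``posterior_cutoff``.

    Inverts the posterior formula: at posterior_cutoff 0.5 (posterior
    odds 1) this is pi / (1 - pi).
    """
    if not 0.0 < posterior_cutoff < 1.0 or not 0.0 < pi < 1.0:
        raise ValueError("posterior_cutoff and pi must be in (0, 1)")
    return pi * posterior_cutoff / ((1.0 - pi) * (1.0 - posterior_cutoff))


def build_mutation_histogram(records) -> dict[tuple, float]:
    """Relative mutation frequencies within one gene.

    ``records`` are (site, allele, observation count) for a single gene;
    duplicate (site, allele) rows are summed before normalizing so the
    histogram sums to 1 over the gene.
    """
    totals: dict[tuple, float] = {}
    for site, allele, count in records:
        if count < 1:
            raise ValueError(f"observation count must be >= 1 at {site} {allele}")
        key = (site, allele)
        totals[key] = totals.get(key, 0.0) + count
    grand = sum(totals.values())
    return {key: value / grand for key, value in totals.items()}


def build_prior_track(
    histograms: dict[str, dict],
    gene_probs,
    pi0: float = 1e-4,
    eps: float = 1e-9,
) -> PriorTrack:
    """Combine per-gene histograms with gene mutation probabilities.

    pi_jk = P(gene mutated) * h_jk for catalogued sites, clipped to
    1 - eps; everything else falls back to ``pi0``.  ``gene_probs`` is a
    float applied uniformly, or a per-gene mapping (a gene missing from
    the mapping is an error).
    """
    pi: dict[tuple, float] = {}
    for gene, hist in histograms.items():
        if isinstance(gene_probs, dict):
            if gene not in gene_probs:
                raise ValueError(f"no gene probability for {gene!r}")
            gp = gene_probs[gene]
        else:
            gp = float(gene_probs)
        if not 0.0 < gp < 1.0:
            raise ValueError(f"gene probability for {gene!r} must be in (0, 1)")
        for (site, allele), h in hist.items():
            chrom, pos = site
            value = min(gp * h, 1.0 - eps)
            pi[(chrom, pos, allele)] = max(value, eps)
    return PriorTrack(pi=pi, pi0=pi0)


def read_hotspot_catalogue(path) -> dict[str, list]:
    """Read a hotspot TSV: gene, chrom, pos (1-based), ref, alt, count.

    Rows whose alt equals ref are dropped (the reference allele never
    receives a prior entry).  Returns per-gene record lists suitable for
    :func:`build_mutation_histogram`.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene", "chrom", "pos", "ref", "alt", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    genes: dict[str, list] = {}
    for idx, row in df.iterrows():
        try:
            pos = int(row["pos"]) - 1
            count = int(row["count"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {idx + 2}") from exc
        if row["alt"] == row["ref"]:
            continue
        genes.setdefault(str(row["gene"]), []).append(((str(row["chrom"]), pos), str(row["alt"]), count))
    return genes


def read_gene_probabilities(path) -> dict[str, float]:
    """Read a per-gene mutation-probability TSV with columns gene, prob."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "prob": float})
    if "gene" not in df.columns or "prob" not in df.columns:
        raise ValueError(f"{path}: expected columns gene, prob")
    return dict(zip(df["gene"], df["prob"]))


def read_exclusion_list(path) -> frozenset:
    """Read a polymorphism exclusion TSV: chrom, pos (1-based), alt."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["chrom", "pos", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return frozenset((str(r["chrom"]), int(r["pos"]) - 1, str(r["alt"])) for _, r in df.iterrows())


def _site_allele_evidence(tensor, j: int, k: int, config: CallConfig):
    """Vectorized per-target evidence for one (site, allele) hypothesis set.

    Returns (valid, mu_f, mu_r, nu_f, nu_r, rho, x, n) with per-sample
    arrays; ``valid`` is False where the reference set is empty.
    """
    x = tensor.counts[:, j, k, :]  # (S, 2)
    n = tensor.coverage[:, j, :]
    tot_x = x.sum(axis=1)
    tot_n = n.sum(axis=1)
    vaf = np.asarray(estimate_sample_vaf(tot_x, tot_n))
    passing = vaf < config.vaf_threshold
    n_pass = int(passing.sum())
    valid = (n_pass - passing.astype(int)) > 0  # J(i) nonempty

    X = x[passing].sum(axis=0).astype(float)  # aggregate over passing samples
    N = n[passing].sum(axis=0).astype(float)
    c = config.pseudocount
    if config.pool_target:
        # pooled rate: for passing targets the control-plus-target sum is the
        # full passing aggregate, independent of the target
        num_f = np.where(passing, X[0] + c, X[0] + x[:, 0] + c)
        den_f = np.where(passing, N[0] + 2 * c, N[0] + n[:, 0] + 2 * c)
        num_r = np.where(passing, X[1] + c, X[1] + x[:, 1] + c)
        den_r = np.where(passing, N[1] + 2 * c, N[1] + n[:, 1] + 2 * c)
    else:
        num_f = np.where(passing, X[0] - x[:, 0] + c, X[0] + c)
        den_f = np.where(passing, N[0] - n[:, 0] + 2 * c, N[0] + 2 * c)
        num_r = np.where(passing, X[1] - x[:, 1] + c, X[1] + c)
        den_r = np.where(passing, N[1] - n[:, 1] + 2 * c, N[1] + 2 * c)
    mu_f = num_f / den_f
    mu_r = num_r / den_r

    nu_f, nu_r = estimate_sample_vaf(x[:, 0], n[:, 0], x[:, 1], n[:, 1])
    if config.nu_mode == "excess":
        nu_f = np.clip(nu_f - mu_f, 0.0, 1.0)
        nu_r = np.clip(nu_r - mu_r, 0.0, 1.0)

    if config.rho_fixed is not None:
        rho = float(config.rho_fixed)
    else:
        rho = estimate_rho(vaf[passing], tot_n[passing], (config.rho_min, config.rho_max))
    return valid, mu_f, mu_r, nu_f, nu_r, rho, x, n


def score_hypotheses(tensor, hypotheses, config: CallConfig | None = None):
    """Bayes factors for explicit (sample, site, allele) index triples.

    Runs the same aggregate-control / error-rate / Bayes-factor machinery
    as :func:`call_variants` but only for the requested hypotheses
    (benchmarks score implanted variants without sweeping the whole
    cohort).  Hypotheses with an empty reference set get BF = NaN.
    """
    config = config or CallConfig()
    hyps = [(int(i), int(j), int(k)) for i, j, k in hypotheses]
    order: dict[tuple[int, int], list[int]] = {}
    for idx, (i, j, k) in enumerate(hyps):
        order.setdefault((j, k), []).append(idx)

    m = len(hyps)
    xf = np.empty(m, dtype=np.int64)
    xr = np.empty(m, dtype=np.int64)
    nf = np.empty(m, dtype=np.int64)
    nr = np.empty(m, dtype=np.int64)
    muf = np.empty(m)
    mur = np.empty(m)
    nuf = np.empty(m)
    nur = np.empty(m)
    rho_arr = np.empty(m)
    ok = np.ones(m, dtype=bool)
    for (j, k), idxs in order.items():
        valid, mu_f, mu_r, nu_f, nu_r, rho, x, n = _site_allele_evidence(tensor, j, k, config)
        for idx in idxs:
            i = hyps[idx][0]
            ok[idx] = bool(valid[i])
            xf[idx], xr[idx] = x[i, 0], x[i, 1]
            nf[idx], nr[idx] = n[i, 0], n[i, 1]
            muf[idx], mur[idx] = mu_f[i], mu_r[i]
            nuf[idx], nur[idx] = nu_f[i], nu_r[i]
            rho_arr[idx] = rho
    bf = bayes_factor(
        xf, nf, xr, nr, muf, mur, nuf, nur, rho_arr,
        strand_mode=config.strand_mode, numerator=config.numerator,
    )
    bf = np.where(ok, bf, np.nan)
    return np.atleast_1d(bf)


def call_variants(tensor, prior: PriorTrack | None = None, config: CallConfig | None = None):
    """Test every (sample, site, non-reference allele) and emit calls.

    For each hypothesis: build the leave-one-out reference set, aggregate
    its counts, estimate strand-specific error rates (method of moments
    with pseudocount), estimate or fix the dispersion, compute the Bayes
    factor and combine it with the site/allele prior into P(M0|D).  A
    call is emitted when the posterior falls at or below the cutoff and
    the (site, allele) is not on the exclusion list.  Deterministic given
    inputs and config.
    """
    from .count_data import ALLELES

    config = config or CallConfig()
    prior = prior or PriorTrack(pi={}, pi0=config.pi0)
    if tensor.n_samples == 0 or tensor.n_sites == 0:
        raise ValueError("empty cohort tensor")
    if tensor.ref_allele is None:
        raise ValueError("tensor has no reference alleles; attach_reference() first")

    calls: list[VariantCall] = []
    for j, (chrom, pos) in enumerate(tensor.sites):
        ref = tensor.ref_allele[j]
        for k, alt in enumerate(ALLELES):
            if alt == ref:
                continue
            valid, mu_f, mu_r, nu_f, nu_r, rho, x, n = _site_allele_evidence(tensor, j, k, config)
            if not np.any(valid):
                logger.info("empty reference set at %s:%d %s; no test", chrom, pos + 1, alt)
                continue
            bf = bayes_factor(
                x[:, 0], n[:, 0], x[:, 1], n[:, 1],
                mu_f, mu_r, nu_f, nu_r, rho,
                strand_mode=config.strand_mode, numerator=config.numerator,
            )
            pi = prior.get(chrom, pos, alt)
            post = posterior_null(bf, pi)
            excluded = (chrom, pos, alt) in config.exclusion
            for i in np.flatnonzero(valid & (post <= config.posterior_cutoff)):
                if not valid[i]:
                    logger.info(
                        "empty reference set for %s at %s:%d %s", tensor.sample_ids[i], chrom, pos + 1, alt
                    )
                    continue
                if excluded:
                    logger.info(
                        "call at excluded polymorphism %s:%d %s (sample %s) dropped",
                        chrom, pos + 1, alt, tensor.sample_ids[i],
                    )
                    continue
                tot_n = n[i].sum()
                calls.append(
                    VariantCall(
                        sample=tensor.sample_ids[i],
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        bf=float(bf[i]),
                        posterior_m0=float(post[i]),
                        pi=float(pi),
                        vaf_fwd=float(nu_f[i]) if config.nu_mode == "raw" else float(x[i, 0] / max(n[i, 0], 1)),
                        vaf_rev=float(nu_r[i]) if config.nu_mode == "raw" else float(x[i, 1] / max(n[i, 1], 1)),
                        vaf_combined=float(x[i].sum() / tot_n) if tot_n > 0 else 0.0,
                        x_fwd=int(x[i, 0]),
                        x_rev=int(x[i, 1]),
                        n_fwd=int(n[i, 0]),
                        n_rev=int(n[i, 1]),
                        rho_used=float(rho),
                        mu_fwd=float(mu_f[i]),
                        mu_rev=float(mu_r[i]),
                    )
                )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.sample, c.alt))
    return calls
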