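"""Pairwise Bayesian colocalization from per-variant approximate Bayes factors.

For each variant the evidence of association with a trait is summarized by an
asymptotic Bayes factor computed from the marginal (beta, se) under a
N(0, W^2) effect prior:

    r = W^2 / (se^2 + W^2),   log ABF = 0.5*log(1 - r) + r*z^2/2

Assuming at most one causal variant per trait in the region, the five causal
configurations are

    H0: neither trait associated        H1 / H2: only trait 1 / trait 2
    H3: both, two distinct variants     H4: both, one shared variant

and their (unnormalized) likelihoods are sums of products of per-variant ABFs
weighted by the per-variant priors p1, p2, p12. All sums are carried out in
log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import EmptyIntersectionError
from .sumstats import AssocSet

__all__ = [
    "ColocPriors",
    "ColocResult",
    "log_abf",
    "prior_sd_for_trait",
    "coloc_abf",
    "coloc_from_abf",
]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of causal configurations.

    p1 / p2: variant causal for trait 1 / trait 2 only; p12: causal for both.
    Defaults are the canonical single-causal-variant colocalization priors.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def validate(self, n_variants: int) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("require 0 < p12 <= p1, p2 < 1")
        if n_variants * (self.p1 + self.p2 + self.p12) >= 1:
            raise ValueError(
                "priors too large for region size: n*(p1+p2+p12) >= 1")


@dataclass
class ColocResult:
    """Posterior probabilities over the five pairwise configurations."""

    pp: np.ndarray  # length 5, ordered H0..H4
    n_snps: int
    priors: ColocPriors

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("pp must have length 5")
        if abs(self.pp.sum() - 1.0) > 1e-10:
            raise ValueError("posteriors must sum to 1")

    def __getitem__(self, h: str) -> float:
        return float(self.pp[HYPOTHESES.index(h)])

    @property
    def ppa(self) -> float:
        """Posterior probability of a shared causal variant (H4)."""
        return float(self.pp[4])

    def as_dict(self) -> dict[str, float]:
        return {h: float(p) for h, p in zip(HYPOTHESES, self.pp)}


def log_abf(beta, se, prior_sd: float):
    """Log asymptotic Bayes factor for association at one variant.

    ``prior_sd`` (W) is the SD of the normal effect prior; W = 0 gives a
    point-null prior and a Bayes factor of exactly 1.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be >= 0")
    z2 = (beta / se) ** 2
    r = prior_sd**2 / (se**2 + prior_sd**2)
    out = 0.5 * np.log1p(-r) + r * z2 / 2.0
    if out.ndim == 0:
        return float(out)
    return out


def prior_sd_for_trait(trait_type: str, sd_y: float | None = None) -> float:
    """Effect-scale prior SD: 0.15*sd_y per SD outcome, 0.2 on log-odds."""
    if trait_type == "binary":
        return 0.2
    if trait_type == "quantitative":
        return 0.15 * (1.0 if sd_y is None else sd_y)
    raise ValueError(f"unknown trait_type {trait_type!r}")


def _log_config_likelihoods(l1: np.ndarray, l2: np.ndarray,
                            priors: ColocPriors) -> np.ndarray:
    """Unnormalized log likelihood of H0..H4 from per-variant log ABFs."""
    s1 = logsumexp(l1)           # sum_i ABF1_i
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)     # sum_i ABF1_i * ABF2_i (coincident variant)
    # H3 sums over ordered distinct pairs: s1*s2 minus the diagonal, kept in
    # the log domain with a signed correction to avoid cancellation.
    if len(l1) == 1:
        log_h3_sum = -np.inf  # no second variant available
    else:
        diff = s12 - (s1 + s2)
        if diff >= 0:  # numerically degenerate: diagonal holds all the mass
            log_h3_sum = -np.inf
        else:
            log_h3_sum = s1 + s2 + np.log1p(-np.exp(diff))
    return np.array([
        0.0,
        np.log(priors.p1) + s1,
        np.log(priors.p2) + s2,
        np.log(priors.p1) + np.log(priors.p2) + log_h3_sum,
        np.log(priors.p12) + s12,
    ])


def coloc_from_abf(l1: np.ndarray, l2: np.ndarray,
                   priors: ColocPriors | None = None) -> ColocResult:
    """Colocalization posteriors from precomputed per-variant log ABFs."""
    priors = priors or ColocPriors()
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1 or len(l1) == 0:
        raise ValueError("need equal-length nonempty ABF vectors")
    priors.validate(len(l1))
    logL = _log_config_likelihoods(l1, l2, priors)
    pp = np.exp(logL - logsumexp(logL))
    pp = pp / pp.sum()
    return ColocResult(pp, len(l1), priors)


def coloc_abf(assoc1: AssocSet, assoc2: AssocSet,
              priors: ColocPriors | None = None,
              prior_sd1: float | None = None,
              prior_sd2: float | None = None) -> ColocResult:
    """Pairwise colocalization of two traits over their shared variants.

    Variants are intersected on id (assumed pre-harmonized: ABFs depend on z
    only through z^2, so allele orientation does not matter here). Effect
    priors default to :func:`prior_sd_for_trait` per trait.
    """
    ids = sorted(set(assoc1.variant_ids) & set(assoc2.variant_ids))
    if not ids:
        raise EmptyIntersectionError(
            f"no shared variants between {assoc1.trait_id} and {assoc2.trait_id}")
    a1 = assoc1.subset(ids).records
    a2 = assoc2.subset(ids).records
    W1 = prior_sd1 if prior_sd1 is not None else prior_sd_for_trait(
        assoc1.trait_type, assoc1.sd_y)
    W2 = prior_sd2 if prior_sd2 is not None else prior_sd_for_trait(
        assoc2.trait_type, assoc2.sd_y)
    l1 = log_abf(a1["beta"].to_numpy(), a1["se"].to_numpy(), W1)
    l2 = log_abf(a2["beta"].to_numpy(), a2["se"].to_numpy(), W2)
    return coloc_from_abf(l1, l2, priors)
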