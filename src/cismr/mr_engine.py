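"""Two-sample Mendelian randomization estimators and scan machinery.

With summary statistics for an exposure (gene expression instrumented by
cis-QTLs) and an outcome (a GWAS trait), the causal effect of the exposure is
estimated by the Wald ratio for a single instrument and by the fixed-effect
inverse-variance-weighted (IVW) mean of per-instrument ratios for two or
more. A transcriptome-wide scan applies this per gene and Bonferroni-corrects
over the number of genes actually instrumented for the outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyIntersectionError, UndefinedRatioError
from .sumstats import AssocSet, harmonize, two_sided_p

__all__ = [
    "MRResult",
    "WeakInstrumentWarning",
    "wald_ratio",
    "ivw",
    "bonferroni_threshold",
    "transcriptome_scan",
    "results_to_frame",
]

logger = logging.getLogger(__name__)


class WeakInstrumentWarning(UserWarning):
    """Exposure association too weak for a reliable ratio estimate."""


@dataclass
class MRResult:
    """A single exposure -> outcome causal-effect estimate."""

    exposure_id: str
    outcome_id: str
    method: str  # "wald" or "ivw"
    n_snps: int
    beta: float
    se: float
    pval: float
    passes_bonferroni: bool = False
    bonferroni_threshold: float = float("nan")
    warnings: list = field(default_factory=list, compare=False)

    @property
    def z(self) -> float:
        return self.beta / self.se

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        q = norm.ppf(0.5 + level / 2.0)
        return self.beta - q * self.se, self.beta + q * self.se


def wald_ratio(b_exp: float, se_exp: float, b_out: float, se_out: float,
               exposure_id: str = "exposure", outcome_id: str = "outcome",
               second_order: bool = False) -> MRResult:
    """Single-instrument Wald ratio estimate b_out / b_exp.

    The default standard error is the first-order delta method
    ``se_out / |b_exp|``; ``second_order=True`` adds the exposure-uncertainty
    term ``sqrt(se_out^2/b_exp^2 + b_out^2 se_exp^2 / b_exp^4)``.
    """
    if b_exp == 0:
        raise UndefinedRatioError("Wald ratio undefined for b_exp = 0")
    warns = []
    if abs(b_exp / se_exp) < 1:
        msg = f"weak instrument: |b_exp/se_exp| = {abs(b_exp/se_exp):.3f} < 1"
        warnings.warn(msg, WeakInstrumentWarning, stacklevel=2)
        warns.append(msg)
    beta = b_out / b_exp
    if second_order:
        se = np.sqrt(se_out**2 / b_exp**2 + b_out**2 * se_exp**2 / b_exp**4)
    else:
        se = se_out / abs(b_exp)
    return MRResult(exposure_id, outcome_id, "wald", 1, beta, float(se),
                    two_sided_p(beta / se), warnings=warns)


def ivw(ratio_estimates, exposure_id: str = "exposure",
        outcome_id: str = "outcome") -> MRResult:
    """Fixed-effect inverse-variance-weighted mean of ratio estimates.

    ``ratio_estimates`` is a sequence of (beta_i, se_i). With a single
    estimate the output equals that estimate exactly.
    """
    est = list(ratio_estimates)
    if not est:
        raise ValueError("ivw requires at least one ratio estimate")
    betas = np.array([b for b, _ in est], dtype=float)
    ses = np.array([s for _, s in est], dtype=float)
    if not (ses > 0).all():
        raise ValueError("all standard errors must be positive")
    w = ses**-2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return MRResult(exposure_id, outcome_id, "ivw", len(est), beta, se,
                    two_sided_p(beta / se))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise error threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def mr_from_harmonized(pairs: pd.DataFrame, exposure_id: str,
                       outcome_id: str) -> MRResult:
    """Wald ratio (one instrument) or IVW over per-SNP ratios (>= 2)."""
    if len(pairs) == 1:
        r = pairs.iloc[0]
        return wald_ratio(r.beta_exp, r.se_exp, r.beta_out, r.se_out,
                          exposure_id, outcome_id)
    ratios = [(r.beta_out / r.beta_exp, r.se_out / abs(r.beta_exp))
              for r in pairs.itertuples(index=False)]
    res = ivw(ratios, exposure_id, outcome_id)
    return res


def transcriptome_scan(exposures: dict[str, AssocSet], outcome: AssocSet,
                       alpha: float = 0.05) -> list[MRResult]:
    """MR of every instrumented exposure against one outcome.

    ``exposures`` maps exposure id -> AssocSet restricted to its clumped
    instruments. Each exposure is harmonized with the outcome and estimated
    by Wald ratio or IVW; exposures with no harmonizable instrument are
    skipped and logged. The Bonferroni threshold divides ``alpha`` by the
    number of exposures that yielded an estimate. Results are sorted by p.
    """
    results: list[MRResult] = []
    for exp_id, assoc in exposures.items():
        try:
            pairs = harmonize(assoc, outcome)
        except EmptyIntersectionError:
            logger.info("exposure %s: no harmonizable instrument; skipped",
                        exp_id)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", WeakInstrumentWarning)
            results.append(mr_from_harmonized(pairs, exp_id, outcome.trait_id))
    thr = bonferroni_threshold(len(results), alpha) if results else float("nan")
    for r in results:
        r.bonferroni_threshold = thr
        r.passes_bonferroni = r.pval < thr
    results.sort(key=lambda r: (r.pval, r.exposure_id))
    return results


def results_to_frame(results: list[MRResult]) -> pd.DataFrame:
    """Flatten MR results to a TSV-ready DataFrame (one row per test)."""
    return pd.DataFrame([{
        "exposure_id": r.exposure_id, "outcome_id": r.outcome_id,
        "method": r.method, "n_snps": r.n_snps, "beta": r.beta, "se": r.se,
        "pval": r.pval, "passes_bonferroni": r.passes_bonferroni,
        "bonferroni_threshold": r.bonferroni_threshold,
    } for r in results])
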