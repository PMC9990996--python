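"""Downstream analyses of a transcriptome-wide MR scan.

Covers four follow-ups: clustering genes by their effect profiles across
outcomes (Euclidean distance, complete linkage), hypergeometric gene-set
enrichment, a phenome-wide scan of one gene's instruments against an outcome
catalogue, and a brain-vs-blood style replication comparison between a
primary and a proxy tissue at a nominal p < 0.05 heuristic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .exceptions import (CismrError, DuplicateKeyError, EmptyInputError,
                         EmptyIntersectionError)
from .mr_engine import MRResult, bonferroni_threshold, mr_from_harmonized
from .sumstats import AssocSet, harmonize

__all__ = [
    "EffectMatrix",
    "PhewasTable",
    "build_effect_matrix",
    "euclidean_cluster",
    "hypergeometric_enrichment",
    "phewas_scan",
    "cross_tissue_compare",
    "binomial_sign_test",
]

logger = logging.getLogger(__name__)


@dataclass
class EffectMatrix:
    """Genes x traits matrix of MR effect estimates.

    ``values`` holds per-column standardized betas with missing cells imputed
    as 0 (for distance computation only); ``mask`` records which cells were
    observed; ``raw`` keeps the unstandardized betas with NaN for missing.
    """

    gene_ids: list[str]
    trait_ids: list[str]
    values: np.ndarray
    mask: np.ndarray
    raw: np.ndarray = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self, raw: bool = False) -> pd.DataFrame:
        data = self.raw if raw else self.values
        return pd.DataFrame(data, index=self.gene_ids, columns=self.trait_ids)


def build_effect_matrix(results: list[MRResult],
                        standardize: bool = True) -> EffectMatrix:
    """Pivot MR results into a genes x traits effect matrix.

    Each column (trait) is z-scored over its non-missing cells so that
    log-odds and per-SD effects are comparable across outcomes; missing cells
    are imputed as 0 after standardization (i.e. at the column mean) and
    recorded in the mask. ``standardize=False`` keeps raw betas (missing
    still imputed 0).
    """
    if not results:
        raise EmptyInputError("no MR results to pivot")
    seen = set()
    for r in results:
        key = (r.exposure_id, r.outcome_id)
        if key in seen:
            raise DuplicateKeyError(f"duplicate (gene, trait) pair {key}")
        seen.add(key)
    genes = sorted({r.exposure_id for r in results})
    traits = sorted({r.outcome_id for r in results})
    raw = np.full((len(genes), len(traits)), np.nan)
    gi = {g: i for i, g in enumerate(genes)}
    ti = {t: j for j, t in enumerate(traits)}
    for r in results:
        raw[gi[r.exposure_id], ti[r.outcome_id]] = r.beta
    mask = ~np.isnan(raw)
    keep_rows = mask.any(axis=1)
    raw, mask = raw[keep_rows], mask[keep_rows]
    genes = [g for g, k in zip(genes, keep_rows) if k]

    values = raw.copy()
    if standardize:
        for j in range(values.shape[1]):
            col = values[:, j]
            obs = mask[:, j]
            if obs.sum() == 0:
                continue
            mu = col[obs].mean()
            sd = col[obs].std()
            if sd == 0:
                warnings.warn(f"constant effect column {traits[j]!r}; "
                              "standardized to zero", stacklevel=2)
                values[obs, j] = 0.0
            else:
                values[obs, j] = (col[obs] - mu) / sd
    values[~mask] = 0.0
    return EffectMatrix(genes, traits, values, mask, raw)


def euclidean_cluster(matrix: EffectMatrix,
                      ) -> tuple[np.ndarray, list[str], list[str]]:
    """Hierarchical clustering of the effect matrix.

    Returns (pairwise gene distance matrix, gene leaf order, trait leaf
    order). Complete linkage on Euclidean distances; rows/columns are sorted
    by id before clustering so the leaf order is deterministic and invariant
    to input order.
    """
    if len(matrix.gene_ids) < 2:
        raise ValueError("need at least 2 rows to cluster")
    row_sort = np.argsort(matrix.gene_ids)
    col_sort = np.argsort(matrix.trait_ids)
    X = matrix.values[np.ix_(row_sort, col_sort)]
    genes = [matrix.gene_ids[i] for i in row_sort]
    traits = [matrix.trait_ids[j] for j in col_sort]

    d_rows = pdist(X, metric="euclidean")
    row_order = [genes[i] for i in leaves_list(linkage(d_rows, "complete"))]
    if len(traits) >= 2:
        d_cols = pdist(X.T, metric="euclidean")
        col_order = [traits[j] for j in leaves_list(linkage(d_cols, "complete"))]
    else:
        col_order = list(traits)
    return squareform(d_rows), row_order, col_order


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    n = len(labels)

    def node(i: int) -> tuple[str, float]:
        if i < n:
            return labels[i], 0.0
        a, b, h, _ = Z[i - n]
        la, ha = node(int(a))
        lb, hb = node(int(b))
        return f"({la}:{h - ha:.6g},{lb}:{h - hb:.6g})", h

    tree, _ = node(2 * n - 2)
    return tree + ";"


def hypergeometric_enrichment(hit_genes: set, annotation_set: set,
                              universe: set) -> tuple[int, float]:
    """Over-representation of an annotation among hit genes.

    Returns (overlap k, upper-tail p = P(X >= k)) for X hypergeometric with
    population |universe|, |annotation_set| successes and |hit_genes| draws.
    The tail is summed exactly from log-factorials.
    """
    universe = set(universe)
    if not universe:
        raise EmptyInputError("empty gene universe")
    hits = set(hit_genes) & universe
    annot = set(annotation_set) & universe
    N, K, n = len(universe), len(annot), len(hits)
    k = len(hits & annot)

    def log_comb(a: int, b: int) -> float:
        if b < 0 or b > a:
            return -math.inf
        return (math.lgamma(a + 1) - math.lgamma(b + 1)
                - math.lgamma(a - b + 1))

    denom = log_comb(N, n)
    terms = [log_comb(K, x) + log_comb(N - K, n - x) - denom
             for x in range(k, min(K, n) + 1)]
    terms = [t for t in terms if t > -math.inf]
    if not terms:
        return k, 0.0 if k > min(K, n) else 1.0
    mx = max(terms)
    p = math.exp(mx) * sum(math.exp(t - mx) for t in terms)
    return k, min(p, 1.0)


@dataclass
class PhewasTable:
    """Phenome-wide MR results for one gene across an outcome catalogue."""

    gene_id: str
    rows: pd.DataFrame  # outcome_id, method, n_snps, beta, se, pval, pp_h4, flagged
    bonferroni_threshold: float
    n_outcomes_scanned: int

    @property
    def pleiotropy_count(self) -> int:
        """Number of outcomes with p below the phenome-wide threshold."""
        return int(self.rows["flagged"].sum())


def phewas_scan(instruments: AssocSet,
                outcome_catalogue: dict[str, AssocSet],
                alpha: float = 0.05,
                coloc_regions: dict | None = None) -> PhewasTable:
    """Scan one gene's instruments against a catalogue of outcomes.

    Per outcome: harmonize, Wald ratio / IVW, flag results with p below
    ``alpha / n_outcomes``. Optionally attach pairwise colocalization PPAs
    computed from full-region statistics supplied in ``coloc_regions`` (maps
    outcome_id -> (region AssocSet for the exposure, region AssocSet for the
    outcome)). Outcomes with no shared variants are skipped and logged.
    """
    if len(instruments) == 0:
        raise EmptyInputError("gene has no instruments")
    if not outcome_catalogue:
        raise EmptyInputError("outcome catalogue is empty")
    thr = bonferroni_threshold(len(outcome_catalogue), alpha)
    rows = []
    for outcome_id in sorted(outcome_catalogue):
        outcome = outcome_catalogue[outcome_id]
        try:
            pairs = harmonize(instruments, outcome)
            res = mr_from_harmonized(pairs, instruments.trait_id, outcome_id)
        except (EmptyIntersectionError, CismrError) as exc:
            logger.info("phewas %s vs %s skipped: %s",
                        instruments.trait_id, outcome_id, exc)
            continue
        pp_h4 = np.nan
        if coloc_regions and outcome_id in coloc_regions:
            from .coloc_engine import coloc_abf
            exp_region, out_region = coloc_regions[outcome_id]
            pp_h4 = coloc_abf(exp_region, out_region).ppa
        rows.append({"gene_id": instruments.trait_id,
                     "outcome_id": outcome_id, "method": res.method,
                     "n_snps": res.n_snps, "beta": res.beta, "se": res.se,
                     "pval": res.pval, "pp_h4": pp_h4,
                     "flagged": res.pval < thr})
    return PhewasTable(instruments.trait_id, pd.DataFrame(rows), thr,
                       len(outcome_catalogue))


def cross_tissue_compare(primary_results: list[MRResult],
                         proxy_results: list[MRResult],
                         heuristic_p: float = 0.05) -> dict:
    """Replication of primary-tissue MR effects in a proxy tissue.

    Results are matched on (exposure, outcome). The replication percentage is
    the share of primary effects whose proxy-tissue p-value falls below
    ``heuristic_p`` (1 d.p.), together with its complement (effects that
    would be overlooked in the proxy tissue), the reverse comparison, and
    sign concordance among replicated pairs.
    """
    proxy = {(r.exposure_id, r.outcome_id): r for r in proxy_results}
    primary = {(r.exposure_id, r.outcome_id): r for r in primary_results}
    shared = [k for k in primary if k in proxy]
    report: dict = {
        "n_primary": len(primary_results),
        "n_proxy": len(proxy_results),
        "n_compared": len(shared),
        "heuristic_p": heuristic_p,
    }
    if not shared:
        report.update(replicated=0, replication_pct=None,
                      overlooked_pct=None, sign_concordance_pct=None,
                      reverse_replicated=0, reverse_replication_pct=None,
                      reason="no overlapping (gene, outcome) keys")
        return report
    replicated = [k for k in shared if proxy[k].pval < heuristic_p]
    report["replicated"] = len(replicated)
    pct = 100.0 * len(replicated) / len(primary_results)
    report["replication_pct"] = round(pct, 1)
    report["overlooked_pct"] = round(100.0 - pct, 1)
    concordant = [k for k in replicated
                  if np.sign(primary[k].beta) == np.sign(proxy[k].beta)]
    report["sign_concordance_pct"] = (
        round(100.0 * len(concordant) / len(replicated), 1)
        if replicated else None)
    # reverse direction: proxy effects nominally supported in the primary tissue
    rev_shared = [k for k in proxy if k in primary]
    rev = [k for k in rev_shared if primary[k].pval < heuristic_p]
    report["reverse_replicated"] = len(rev)
    report["reverse_replication_pct"] = (
        round(100.0 * len(rev) / len(proxy_results), 1) if proxy_results else None)
    return report


def binomial_sign_test(n_negative: int, n_total: int) -> float:
    """Two-sided exact binomial test of sign balance (p = 0.5).

    A transparent surrogate for judging an excess of inverse relationships
    between two traits' gene effects; not a replacement for model-based
    enrichment.
    """
    from scipy.stats import binomtest
    return float(binomtest(n_negative, n_total, 0.5).pvalue)
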