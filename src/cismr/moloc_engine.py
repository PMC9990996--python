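"""Multiple-trait colocalization over expression, methylation and outcome.

With three traits (E = gene expression, M = DNA methylation at a CpG, G = a
GWAS outcome) and at most one causal variant per trait in the region, the
causal configurations are the ways of choosing which traits are associated
and how the associated traits group onto shared causal variants: 15 in total
for three traits (1 null + 3 single-trait + 6 two-trait + 5 three-trait
patterns). Each configuration's likelihood is a sum over assignments of
distinct variants to its groups of products of per-variant Bayes factors;
the sums are evaluated exactly by signed inclusion-exclusion over partitions
of the groups, entirely in log space.

The quantity of interest mirrors the pairwise PPA: the posterior of the
single configuration in which E, M and G all share one causal variant
(``ppa_full``), scanned over the CpGs within 100 kb of the gene and, at
multi-signal loci, per conditionally isolated eQTL signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import CollinearityError, EmptyIntersectionError
from .coloc_engine import log_abf, prior_sd_for_trait
from .ld_tools import LDMatrix, clump, conditional_assoc
from .sumstats import AssocSet, GenomicWindow

__all__ = [
    "MolocConfig",
    "MolocResult",
    "MolocScanResult",
    "enumerate_configs",
    "moloc_from_abf",
    "moloc",
    "scan_cpgs",
    "decompose_and_moloc",
    "DEFAULT_PRIOR_WEIGHTS",
]

logger = logging.getLogger(__name__)

#: Prior probability that a variant is causal for exactly 1 / 2 / 3 / 4 traits.
DEFAULT_PRIOR_WEIGHTS = (1e-4, 1e-6, 1e-7, 1e-8)


@dataclass(frozen=True)
class MolocConfig:
    """One causal configuration: a partition of a subset of traits.

    ``groups`` is a tuple of tuples of trait indices; traits absent from all
    groups are unassociated. Each group shares one causal variant and
    distinct groups have distinct variants.
    """

    groups: tuple[tuple[int, ...], ...]

    def label(self, trait_labels) -> str:
        if not self.groups:
            return "null"
        return ".".join("".join(trait_labels[t] for t in g)
                        for g in self.groups)

    @property
    def n_traits(self) -> int:
        return sum(len(g) for g in self.groups)


def _set_partitions(items: tuple):
    """All partitions of ``items`` into nonempty blocks (canonical order)."""
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        # first in its own block
        yield ((first,),) + part
        # first joins each existing block
        for i, block in enumerate(part):
            yield part[:i] + ((first,) + block,) + part[i + 1:]


def _canonical(groups) -> tuple[tuple[int, ...], ...]:
    groups = tuple(tuple(sorted(g)) for g in groups)
    return tuple(sorted(groups, key=lambda g: (g[0], len(g), g)))


def enumerate_configs(k: int) -> list[MolocConfig]:
    """All causal configurations for ``k`` traits (k = 3 gives 15).

    Every way to pick a subset S of the traits and partition S into causal
    groups, plus the null configuration, in a deterministic order (by number
    of associated traits, then lexicographically).
    """
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    from itertools import combinations
    configs = [MolocConfig(())]
    for size in range(1, k + 1):
        for subset in combinations(range(k), size):
            for part in _set_partitions(subset):
                configs.append(MolocConfig(_canonical(part)))
    # dedupe (partition generator emits each partition once, but keep safe)
    seen, out = set(), []
    for c in configs:
        if c.groups not in seen:
            seen.add(c.groups)
            out.append(c)
    out.sort(key=lambda c: (c.n_traits, len(c.groups), c.groups))
    return out


@dataclass
class MolocResult:
    """Posterior over all causal configurations for one (gene, CpG) run."""

    posteriors: dict[str, float]
    ppa_full: float
    n_snps: int
    cpg_id: str | None = None
    signal_index: int | None = None
    priors: tuple = DEFAULT_PRIOR_WEIGHTS[:3]

    def __post_init__(self) -> None:
        total = sum(self.posteriors.values())
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"posteriors sum to {total}, not 1")


def _log_distinct_assignment_sum(group_lbfs: list[np.ndarray]) -> float:
    """log of sum over assignments of *distinct* variants to groups of the
    product of per-group Bayes factors.

    Evaluated by inclusion-exclusion over partitions of the group set:
    merging a block of groups forces them onto one variant, with Moebius
    coefficient (-1)^(|B|-1) (|B|-1)! per block. Exact and O(#partitions * m).
    """
    kg = len(group_lbfs)
    if kg == 0:
        return 0.0
    terms, signs = [], []
    for part in _set_partitions(tuple(range(kg))):
        log_term, sign = 0.0, 1.0
        for block in part:
            merged = sum(group_lbfs[g] for g in block)
            log_term += float(logsumexp(merged))
            if (len(block) - 1) % 2 == 1:
                sign = -sign
            log_term += math.lgamma(len(block))  # (|B|-1)!
        terms.append(log_term)
        signs.append(sign)
    total, sign = logsumexp(terms, b=signs, return_sign=True)
    if sign <= 0 or not np.isfinite(total):
        return -np.inf  # cancellation: no valid distinct assignment mass
    return float(total)


def moloc_from_abf(lbfs: list[np.ndarray],
                   prior_weights=DEFAULT_PRIOR_WEIGHTS,
                   trait_labels=("E", "M", "G", "F")) -> MolocResult:
    """Configuration posteriors from per-trait, per-variant log ABF vectors."""
    k = len(lbfs)
    lbfs = [np.asarray(v, dtype=float) for v in lbfs]
    m = len(lbfs[0])
    if any(len(v) != m for v in lbfs) or m == 0:
        raise ValueError("all traits need ABFs for the same nonempty variant set")
    configs = enumerate_configs(k)
    labels, logls = [], []
    for cfg in configs:
        log_prior = sum(math.log(prior_weights[len(g) - 1]) for g in cfg.groups)
        group_lbfs = [sum(lbfs[t] for t in g) for g in cfg.groups]
        logls.append(log_prior + _log_distinct_assignment_sum(group_lbfs))
        labels.append(cfg.label(trait_labels))
    logls = np.asarray(logls)
    pp = np.exp(logls - logsumexp(logls))
    pp = pp / pp.sum()
    posteriors = dict(zip(labels, pp.tolist()))
    full_label = "".join(trait_labels[:k])
    return MolocResult(posteriors, posteriors.get(full_label, 0.0), m,
                       priors=tuple(prior_weights[:k]))


def moloc(assoc_e: AssocSet, assoc_m: AssocSet, assoc_g: AssocSet,
          prior_weights=DEFAULT_PRIOR_WEIGHTS) -> MolocResult:
    """Three-trait colocalization of expression, methylation and outcome.

    Variants are intersected across the three sets (Bayes factors depend on
    z^2 only, so pre-harmonized allele orientation is not required here).
    """
    traits = (assoc_e, assoc_m, assoc_g)
    ids = set(traits[0].variant_ids)
    for t in traits[1:]:
        ids &= set(t.variant_ids)
    ids = sorted(ids)
    if not ids:
        raise EmptyIntersectionError("no variants shared by all three traits")
    lbfs = []
    for t in traits:
        sub = t.subset(ids).records
        W = prior_sd_for_trait(t.trait_type, t.sd_y)
        lbfs.append(log_abf(sub["beta"].to_numpy(), sub["se"].to_numpy(), W))
    res = moloc_from_abf(lbfs, prior_weights)
    res.cpg_id = assoc_m.trait_id
    return res


@dataclass
class MolocScanResult:
    """Best-CpG result for one gene (or one conditional signal)."""

    gene_id: str
    best: MolocResult | None
    per_cpg: pd.DataFrame = field(default_factory=pd.DataFrame)
    reason: str | None = None  # set when no CpG was eligible
    index_variant: str | None = None  # the eQTL signal this run isolates


def scan_cpgs(gene_id: str, assoc_e: AssocSet,
              cpg_table: dict[str, AssocSet], assoc_g: AssocSet,
              gene_window: GenomicWindow,
              cpg_positions: dict[str, tuple[str, int]],
              window_bp: int = 100_000,
              prior_weights=DEFAULT_PRIOR_WEIGHTS) -> MolocScanResult:
    """Run three-trait colocalization per CpG near a gene; keep the best.

    A CpG is eligible when its position lies within ``window_bp`` of the
    gene's coordinates (inclusive). Returns the result with maximal
    ``ppa_full`` plus the full per-CpG table.
    """
    eligible = []
    for cpg_id in sorted(cpg_table):
        if cpg_id not in cpg_positions:
            continue
        chrom, pos = cpg_positions[cpg_id]
        if (str(chrom) == str(gene_window.chrom)
                and gene_window.start - window_bp <= pos
                <= gene_window.end + window_bp):
            eligible.append(cpg_id)
    if not eligible:
        return MolocScanResult(gene_id, None, reason="no CpG within window")
    rows, best = [], None
    for cpg_id in eligible:
        try:
            res = moloc(assoc_e, cpg_table[cpg_id], assoc_g, prior_weights)
        except EmptyIntersectionError:
            logger.info("gene %s CpG %s: no shared variants", gene_id, cpg_id)
            continue
        res.cpg_id = cpg_id
        rows.append({"gene_id": gene_id, "cpg_id": cpg_id,
                     "ppa_full": res.ppa_full, "n_snps": res.n_snps,
                     **res.posteriors})
        if best is None or res.ppa_full > best.ppa_full:
            best = res
    if best is None:
        return MolocScanResult(gene_id, None,
                               reason="no CpG shared variants with region")
    return MolocScanResult(gene_id, best, pd.DataFrame(rows))


def decompose_and_moloc(gene_id: str, assoc_e: AssocSet,
                        cpg_table: dict[str, AssocSet], assoc_g: AssocSet,
                        ld: LDMatrix, gene_window: GenomicWindow,
                        cpg_positions: dict[str, tuple[str, int]],
                        window_bp: int = 100_000,
                        p_index: float = 5e-8, r2_thresh: float = 0.01,
                        prior_weights=DEFAULT_PRIOR_WEIGHTS,
                        ) -> list[MolocScanResult]:
    """Per-signal colocalization at loci with multiple independent eQTLs.

    The eQTL associations are clumped; with a single index variant this
    reduces to :func:`scan_cpgs` on the unconditioned statistics. With two or
    more, each signal is isolated in turn by conditioning all three traits'
    statistics on the other index variants before scanning the CpGs.
    """
    cl = clump(assoc_e, ld, p_index=p_index, r2_thresh=r2_thresh)
    if len(cl.index_variants) <= 1:
        res = scan_cpgs(gene_id, assoc_e, cpg_table, assoc_g, gene_window,
                        cpg_positions, window_bp, prior_weights)
        if res.best is not None:
            res.best.signal_index = 0
        if cl.index_variants:
            res.index_variant = cl.index_variants[0]
        return [res]
    out = []
    for i, index_variant in enumerate(cl.index_variants):
        others = [v for v in cl.index_variants if v != index_variant]
        try:
            e_c = conditional_assoc(assoc_e, ld, others)
            g_c = conditional_assoc(assoc_g, ld, others)
            cpg_c = {}
            for cpg_id, a in cpg_table.items():
                present = [v for v in others if v in set(a.variant_ids)]
                cpg_c[cpg_id] = conditional_assoc(a, ld, present)
        except CollinearityError as exc:
            logger.warning("gene %s signal %d (%s): %s; skipped",
                           gene_id, i, index_variant, exc)
            continue
        res = scan_cpgs(gene_id, e_c, cpg_c, g_c, gene_window,
                        cpg_positions, window_bp, prior_weights)
        res.index_variant = index_variant
        if res.best is not None:
            res.best.signal_index = i
        out.append(res)
    return out
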