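"""Synthetic cis-regions with known causal structure.

Generates LD-structured marginal summary statistics for one to three traits
over a cis-region, plus (optionally) a matching reference genotype panel, so
that instrument selection, MR, conditional analysis and colocalization can
all be exercised against ground truth without external data.

The default generator samples marginal z-scores directly from their
asymptotic distribution: with LD matrix R and standardized causal effects
b~ (per-allele effect times sqrt(2 f (1-f)) / sd_y), the marginal z-vector is

    z ~ MVN( sqrt(n) * R * b~ ,  R )

and beta_j = z_j * se_j with se_j = 1 / sqrt(2 f_j (1-f_j) n). This is
exactly the sampling model the approximate-Bayes-factor machinery assumes
and is orders of magnitude faster than individual-level simulation; a small
individual-level mode (phenotype regression on simulated genotypes) is kept
for cross-validation of the shortcut.

Shipped scenarios mirror the study conditions: a brain-scale eQTL trait
(n = 1194), a brain-scale mQTL trait (n = 500), GWAS outcomes at biobank
scale, and a whole-blood-scale mediation scenario with a known causal ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .ld_tools import LDMatrix
from .sumstats import AssocSet, GenomicWindow, two_sided_p

__all__ = [
    "TraitSpec",
    "CoverageFilter",
    "ScenarioConfig",
    "SimulatedRegion",
    "make_ld_matrix",
    "simulate_reference_panel",
    "simulate_summary_stats",
    "simulate_individual_level",
    "scenario_library",
    "beta_for_z",
]

#: Region layout: 1-based positions BASE_POS + i * SPACING_BP on chromosome 1.
BASE_POS = 1_000_000
SPACING_BP = 2_000
CAUSAL_MAF = 0.30  # frequency pinned at causal sites so expected z is exact


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait's sample size and causal assignment."""

    trait_id: str
    trait_type: str  # "quantitative" or "binary" (binary n = effective n)
    n: int
    causal_positions: tuple[int, ...] = ()
    causal_betas: tuple[float, ...] = ()  # per-allele effects (log-odds if binary)
    sd_y: float = 1.0

    def __post_init__(self):
        if len(self.causal_positions) != len(self.causal_betas):
            raise ConfigError("causal_positions and causal_betas differ in length")
        if self.n <= 0:
            raise ConfigError("n must be positive")


@dataclass(frozen=True)
class CoverageFilter:
    """Per-trait variant-coverage truncation, emulating probe-centred QTL
    releases that only report SNPs near the probe and/or below a p cut."""

    center_pos: int | None = None
    window_bp: int | None = None
    p_max: float | None = None


@dataclass
class ScenarioConfig:
    """Full specification of a simulated cis-region."""

    m: int
    ld_rho: float
    traits: tuple[TraitSpec, ...]
    maf_range: tuple[float, float] = (0.05, 0.5)
    mediation_theta: float | None = None
    coverage_truncation: dict = field(default_factory=dict)  # trait_id -> CoverageFilter
    n_ref: int = 0  # individuals in the reference panel (0 = skip)
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.ld_rho < 1):
            raise ConfigError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for t in self.traits:
            for p in t.causal_positions:
                if not 0 <= p < self.m:
                    raise ConfigError(
                        f"causal position {p} outside region of {self.m} variants")

    @property
    def sharing(self) -> dict[int, list[str]]:
        """Map causal variant index -> trait ids it affects."""
        out: dict[int, list[str]] = {}
        for t in self.traits:
            for p in t.causal_positions:
                out.setdefault(p, []).append(t.trait_id)
        return out


@dataclass
class SimulatedRegion:
    """A realized region: true LD, optional panel, per-trait statistics, truth."""

    ld: LDMatrix
    panel: np.ndarray | None
    assoc: dict[str, AssocSet]
    truth: dict

    @property
    def variant_ids(self) -> list[str]:
        return self.ld.variant_ids


def make_ld_matrix(m: int, ld_rho: float) -> LDMatrix:
    """AR(1) LD: r_ij = ld_rho^|i-j|, positive definite by construction."""
    if m < 1:
        raise ConfigError("m must be >= 1")
    idx = np.arange(m)
    r = float(ld_rho) ** np.abs(idx[:, None] - idx[None, :])
    ids = [f"rs{i + 1}" for i in range(m)]
    positions = {v: BASE_POS + i * SPACING_BP for i, v in enumerate(ids)}
    return LDMatrix(ids, r, positions)


def simulate_reference_panel(n_ref: int, ld: LDMatrix, mafs: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """Dosage matrix (n_ref x m) via Gaussian-copula haplotype thresholding.

    Each haplotype is a latent MVN(0, R) draw thresholded at the per-variant
    maf quantile; an individual's dosage is the sum of two haplotypes.
    """
    if n_ref < 2:
        raise ConfigError("n_ref must be >= 2")
    m = len(ld)
    L = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))
    latent = rng.standard_normal((2 * n_ref, m)) @ L.T
    cuts = stats.norm.ppf(np.asarray(mafs))
    haps = (latent < cuts).astype(np.int8)
    return (haps[0::2] + haps[1::2]).astype(float)


def _standardized_effects(trait: TraitSpec, mafs: np.ndarray, m: int,
                          ) -> np.ndarray:
    b = np.zeros(m)
    for p, beta in zip(trait.causal_positions, trait.causal_betas):
        b[p] = beta
    scale = np.sqrt(2.0 * mafs * (1.0 - mafs))
    if trait.trait_type == "quantitative":
        scale = scale / trait.sd_y
    return b * scale


def simulate_summary_stats(scenario: ScenarioConfig,
                           rng: np.random.Generator | None = None,
                           ) -> SimulatedRegion:
    """Draw marginal summary statistics for every trait in a scenario.

    Deterministic given the scenario's seed (or a supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    m = scenario.m
    ld = make_ld_matrix(m, scenario.ld_rho)
    lo, hi = scenario.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    for p in scenario.sharing:
        mafs[p] = CAUSAL_MAF
    L = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))
    positions = np.array([ld.positions[v] for v in ld.variant_ids])

    panel = None
    if scenario.n_ref > 0:
        panel = simulate_reference_panel(scenario.n_ref, ld, mafs, rng)

    assoc: dict[str, AssocSet] = {}
    for trait in scenario.traits:
        btilde = _standardized_effects(trait, mafs, m)
        ez = np.sqrt(trait.n) * (ld.r @ btilde)
        z = ez + L @ rng.standard_normal(m)
        se = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs) * trait.n)
        beta = z * se
        df = pd.DataFrame({
            "variant_id": ld.variant_ids,
            "chrom": "1",
            "pos": positions,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": mafs,
            "beta": beta,
            "se": se,
            "pval": two_sided_p(z),
            "n": float(trait.n),
        })
        filt = scenario.coverage_truncation.get(trait.trait_id)
        if filt is not None:
            keep = np.ones(m, dtype=bool)
            if filt.window_bp is not None:
                center = filt.center_pos
                if center is None and trait.causal_positions:
                    center = int(positions[trait.causal_positions[0]])
                if center is not None:
                    keep &= np.abs(positions - center) <= filt.window_bp
            if filt.p_max is not None:
                keep &= df["pval"].to_numpy() <= filt.p_max
            df = df[keep]
        assoc[trait.trait_id] = AssocSet(trait.trait_id, df.reset_index(drop=True),
                                         trait.trait_type, trait.sd_y)

    truth = {
        "sharing": scenario.sharing,
        "mediation_theta": scenario.mediation_theta,
        "mafs": mafs,
        "traits": {t.trait_id: {"causal_positions": list(t.causal_positions),
                                "causal_betas": list(t.causal_betas),
                                "n": t.n}
                   for t in scenario.traits},
    }
    return SimulatedRegion(ld, panel, assoc, truth)


def simulate_individual_level(trait: TraitSpec, panel_dosages: np.ndarray,
                              rng: np.random.Generator) -> AssocSet:
    """Individual-level validation mode for quantitative traits.

    Draws phenotype = dosage . beta + noise (noise scaled so Var(y) = sd_y^2)
    and runs per-variant marginal OLS — the slow route the MVN shortcut
    approximates.
    """
    if trait.trait_type != "quantitative":
        raise ConfigError("individual-level mode supports quantitative traits")
    n, m = panel_dosages.shape
    b = np.zeros(m)
    for p, beta in zip(trait.causal_positions, trait.causal_betas):
        b[p] = beta
    g = panel_dosages - panel_dosages.mean(axis=0)
    signal = g @ b
    noise_var = max(trait.sd_y**2 - signal.var(), 1e-6)
    y = signal + rng.standard_normal(n) * np.sqrt(noise_var)
    y = y - y.mean()
    gvar = (g**2).sum(axis=0)
    beta_hat = (g.T @ y) / gvar
    resid_var = np.array([np.var(y - beta_hat[j] * g[:, j]) for j in range(m)])
    se = np.sqrt(resid_var * n / (n - 2) / gvar)
    z = beta_hat / se
    maf = panel_dosages.mean(axis=0) / 2.0
    df = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(m)],
        "chrom": "1",
        "pos": [BASE_POS + i * SPACING_BP for i in range(m)],
        "effect_allele": "A", "other_allele": "G",
        "eaf": maf, "beta": beta_hat, "se": se,
        "pval": two_sided_p(z), "n": float(n),
    })
    return AssocSet(trait.trait_id, df, "quantitative", trait.sd_y)


def beta_for_z(z_target: float, n: int, maf: float = CAUSAL_MAF,
               sd_y: float = 1.0) -> float:
    """Per-allele effect giving expected marginal |z| = z_target at the causal
    variant (where the LD row is 1)."""
    return z_target * sd_y / (np.sqrt(n) * np.sqrt(2.0 * maf * (1.0 - maf)))


# ---------------------------------------------------------------------------
# Canonical scenarios

N_BRAIN_EQTL = 1194     # brain eQTL meta-analysis effective n
N_BRAIN_MQTL = 500      # brain mQTL cohort scale
N_BLOOD_EQTL = 31_684   # whole-blood eQTL consortium n
N_GWAS = 50_000         # effective n of a well-powered GWAS outcome


def scenario_library(seed: int = 0) -> dict[str, ScenarioConfig]:
    """Named canonical scenarios with known causal structure.

    All use m = 200 variants, AR(1) LD with rho = 0.9 and causal effects
    sized for expected |z| ~ 8 at the causal variant (|z| ~ 12 for the
    mediation exposure), i.e. comfortably past the genome-wide instrument
    threshold, matching the strong cis-QTL signals the pipeline targets.
    """
    m, rho = 200, 0.9

    def eqtl(positions, z=8.0, n=N_BRAIN_EQTL, trait_id="expression"):
        betas = tuple(beta_for_z(z, n) for _ in positions)
        return TraitSpec(trait_id, "quantitative", n, tuple(positions), betas)

    def mqtl(positions, z=8.0):
        betas = tuple(beta_for_z(z, N_BRAIN_MQTL) for _ in positions)
        return TraitSpec("methylation", "quantitative", N_BRAIN_MQTL,
                         tuple(positions), betas)

    def gwas(positions, z=8.0, trait_id="trait"):
        betas = tuple(beta_for_z(z, N_GWAS) for _ in positions)
        return TraitSpec(trait_id, "binary", N_GWAS, tuple(positions), betas)

    lib = {}
    lib["H4-shared"] = ScenarioConfig(
        m, rho, traits=(eqtl([100]), gwas([100])), seed=seed, name="H4-shared")
    # causal sites 80 variants apart: r^2 = 0.9^160 << 0.01
    lib["H3-distinct"] = ScenarioConfig(
        m, rho, traits=(eqtl([60]), gwas([140])), seed=seed, name="H3-distinct")
    lib["three-way-shared"] = ScenarioConfig(
        m, rho, traits=(eqtl([100]), mqtl([100]), gwas([100])), seed=seed,
        name="three-way-shared")
    lib["two-independent-eQTL-signals"] = ScenarioConfig(
        m, rho, traits=(eqtl([60, 140]), mqtl([60]), gwas([60])), seed=seed,
        name="two-independent-eQTL-signals")
    lib["null"] = ScenarioConfig(
        m, rho, traits=(eqtl([]), gwas([])), seed=seed, name="null")

    theta = 0.3
    exp_positions = (30, 100, 170)
    exp_betas = tuple(beta_for_z(12.0, N_BLOOD_EQTL) for _ in exp_positions)
    out_betas = tuple(theta * b for b in exp_betas)
    lib["mediation"] = ScenarioConfig(
        m, rho,
        traits=(
            TraitSpec("expression", "quantitative", N_BLOOD_EQTL,
                      exp_positions, exp_betas),
            TraitSpec("trait", "quantitative", N_GWAS, exp_positions,
                      out_betas),
        ),
        mediation_theta=theta, seed=seed, name="mediation")

    lib["truncated-mQTL-coverage"] = ScenarioConfig(
        m, rho, traits=(eqtl([100]), mqtl([100]), gwas([100])),
        coverage_truncation={
            "methylation": CoverageFilter(window_bp=20_000),
        },
        seed=seed, name="truncated-mQTL-coverage")
    return lib


def simulate_null_scan_inputs(seed: int, n_exposures: int = 10, m: int = 12,
                              ) -> tuple[dict[str, AssocSet], AssocSet]:
    """Instrumented exposures with a null outcome, for error-rate studies.

    Each exposure occupies its own region (chromosome-labelled, variant ids
    prefixed) with one strong causal eQTL; the outcome has no causal variant
    anywhere. Exposures are clumped and returned restricted to their index
    variants, ready for a transcriptome-wide scan whose family-wise error
    under this null can be measured.
    """
    from .ld_tools import clump

    rng = np.random.default_rng(seed)
    exposures: dict[str, AssocSet] = {}
    out_frames = []
    for g in range(n_exposures):
        gene_id = f"gene{g}"
        scen = ScenarioConfig(
            m, 0.9,
            traits=(TraitSpec(gene_id, "quantitative", N_BRAIN_EQTL,
                              (m // 2,),
                              (beta_for_z(9.0, N_BRAIN_EQTL),)),
                    TraitSpec("outcome", "binary", N_GWAS)),
            seed=int(rng.integers(2**31)))
        region = simulate_summary_stats(scen)

        def relabel(df):
            df = df.copy()
            df["variant_id"] = [f"g{g}_{v}" for v in df["variant_id"]]
            df["chrom"] = str(g + 1)
            return df

        cl = clump(region.assoc[gene_id], region.ld)
        if not cl.index_variants:
            continue
        instr_ids = [f"g{g}_{v}" for v in cl.index_variants]
        exposures[gene_id] = AssocSet(
            gene_id, relabel(region.assoc[gene_id].records)).subset(instr_ids)
        out_frames.append(relabel(region.assoc["outcome"].records))
    outcome = AssocSet("outcome", pd.concat(out_frames, ignore_index=True),
                       "binary")
    return exposures, outcome
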