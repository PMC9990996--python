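"""End-to-end orchestration: instrument selection -> MR -> colocalization.

The pipeline runs from plain files (per-gene cis summary statistics, outcome
GWAS tables, a dosage reference panel, a BED-like feature table) so a run is
fully reproducible from its config and seed. ``simulate_study`` materializes
a synthetic multi-gene study in the same layout for end-to-end testing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import downstream, simdata
from .coloc_engine import ColocPriors, coloc_abf
from .exceptions import CismrError, ConfigError, EmptyIntersectionError
from .ld_tools import estimate_ld, read_panel_tsv
from .mr_engine import (MRResult, bonferroni_threshold, mr_from_harmonized,
                        results_to_frame)
from .ld_tools import clump
from .sumstats import (AssocSet, GenomicWindow, extract_cis_window, harmonize,
                       read_feature_table, read_sumstats, write_sumstats)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_scan", "run_phewas", "simulate_study"]


@dataclass
class RunConfig:
    """Thresholds and paths for a full scan.

    Threshold defaults are the analysis constants used throughout the
    package: genome-wide instrument significance 5e-8, clump r^2 0.01,
    colocalization PPA 0.8, nominal replication heuristic 0.05, family-wise
    alpha 0.05, cis flank 1 Mb and CpG window 100 kb.
    """

    exposure_dir: str = ""
    outcome_paths: tuple = ()
    panel_path: str = ""
    feature_path: str = ""
    out_dir: str = "results"
    mqtl_dir: str | None = None
    p_instrument: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: int = 1000
    ppa_threshold: float = 0.8
    heuristic_p: float = 0.05
    alpha: float = 0.05
    cis_flank_bp: int = 1_000_000
    cpg_window_bp: int = 100_000
    seed: int = 0
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)

    def __post_init__(self) -> None:
        checks = [
            (0 < self.p_instrument < 1, "p_instrument must be in (0,1)"),
            (0 < self.clump_r2 < 1, "clump_r2 must be in (0,1)"),
            (0 < self.ppa_threshold <= 1, "ppa_threshold must be in (0,1]"),
            (0 < self.heuristic_p < 1, "heuristic_p must be in (0,1)"),
            (0 < self.alpha < 1, "alpha must be in (0,1)"),
            (self.cis_flank_bp >= 0, "cis_flank_bp must be >= 0"),
            (self.cpg_window_bp >= 0, "cpg_window_bp must be >= 0"),
            (self.clump_window_kb > 0, "clump_window_kb must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outcome_paths" in raw:
            raw["outcome_paths"] = tuple(raw["outcome_paths"])
        return cls(**raw)

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["coloc_priors"] = dataclasses.asdict(self.coloc_priors)
        return d


def _load_panel_ld(panel_path: str):
    """Per-chromosome LD matrices from a dosage TSV panel."""
    dosages, ids, positions = read_panel_tsv(panel_path)
    df = pd.read_csv(panel_path, sep="\t", usecols=["variant_id", "chrom"])
    by_chrom = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        ld = estimate_ld(dosages[:, idx], [ids[i] for i in idx])
        ld.positions = {v: positions[v] for v in ld.variant_ids}
        by_chrom[str(chrom)] = ld
    return by_chrom


def run_scan(config: RunConfig) -> dict:
    """Instrument selection -> MR scan -> colocalization filter -> report.

    Per gene and outcome: extract the cis window, clump the eQTL p-values,
    harmonize the clumped instruments with the outcome and estimate the MR
    effect; genes passing the per-outcome Bonferroni threshold are assessed
    for colocalization over the full cis window. All intermediate tables are
    persisted under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    features = read_feature_table(config.feature_path)
    ld_by_chrom = _load_panel_ld(config.panel_path)
    outcomes = {}
    for path in config.outcome_paths:
        a = read_sumstats(path, trait_id=Path(path).stem)
        outcomes[a.trait_id] = a

    instruments: dict[str, AssocSet] = {}
    gene_windows: dict[str, GenomicWindow] = {}
    cis_stats: dict[str, AssocSet] = {}
    for path in sorted(Path(config.exposure_dir).glob("*.tsv")):
        gene_id = path.stem
        if gene_id not in features:
            logger.warning("gene %s has no feature coordinates; skipped", gene_id)
            continue
        window = features[gene_id]
        assoc = read_sumstats(path, trait_id=gene_id)
        assoc = extract_cis_window(assoc, window, config.cis_flank_bp)
        if len(assoc) == 0:
            continue
        ld = ld_by_chrom.get(str(window.chrom))
        if ld is None:
            logger.warning("no panel LD for chrom %s; gene %s skipped",
                           window.chrom, gene_id)
            continue
        cl = clump(assoc, ld, p_index=config.p_instrument,
                   r2_thresh=config.clump_r2,
                   window_kb=config.clump_window_kb)
        if not cl.index_variants:
            continue
        instruments[gene_id] = assoc.subset(cl.index_variants)
        gene_windows[gene_id] = window
        cis_stats[gene_id] = assoc

    all_mr: list[MRResult] = []
    coloc_rows = []
    for outcome_id, outcome in outcomes.items():
        per_outcome: list[MRResult] = []
        for gene_id, instr in instruments.items():
            try:
                pairs = harmonize(instr, outcome)
            except EmptyIntersectionError:
                continue
            per_outcome.append(mr_from_harmonized(pairs, gene_id, outcome_id))
        thr = (bonferroni_threshold(len(per_outcome), config.alpha)
               if per_outcome else float("nan"))
        for res in per_outcome:
            res.bonferroni_threshold = thr
            res.passes_bonferroni = res.pval < thr
            if res.passes_bonferroni:
                region_out = extract_cis_window(
                    outcome, gene_windows[res.exposure_id], config.cis_flank_bp)
                try:
                    cres = coloc_abf(cis_stats[res.exposure_id], region_out,
                                     config.coloc_priors)
                except CismrError as exc:
                    logger.warning("coloc %s/%s failed: %s",
                                   res.exposure_id, outcome_id, exc)
                    continue
                coloc_rows.append({
                    "gene_id": res.exposure_id, "outcome_id": outcome_id,
                    "n_snps": cres.n_snps, **cres.as_dict(),
                    "passes_ppa": cres.ppa > config.ppa_threshold})
        all_mr.extend(per_outcome)

    mr_df = results_to_frame(all_mr) if all_mr else pd.DataFrame()
    coloc_df = pd.DataFrame(coloc_rows)
    mr_df.to_csv(out_dir / "mr_results.tsv", sep="\t", index=False)
    coloc_df.to_csv(out_dir / "coloc_results.tsv", sep="\t", index=False)

    passing = []
    if not coloc_df.empty:
        passing = coloc_df.loc[coloc_df["passes_ppa"],
                               ["gene_id", "outcome_id"]].to_records(index=False)
        passing = [(str(g), str(o)) for g, o in passing]
    report = {
        "config": config.to_json(),
        "n_genes_instrumented": len(instruments),
        "n_outcomes": len(outcomes),
        "n_tests": len(all_mr),
        "n_passing_bonferroni": int(mr_df["passes_bonferroni"].sum())
        if not mr_df.empty else 0,
        "n_passing_ppa": len(passing),
        "passing": [{"gene_id": g, "outcome_id": o} for g, o in passing],
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_phewas(config: RunConfig, gene_id: str,
               outcome_dir: str) -> downstream.PhewasTable:
    """Phenome-wide MR of one gene's instruments against an outcome catalogue."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    features = read_feature_table(config.feature_path)
    if gene_id not in features:
        raise ConfigError(f"gene {gene_id} absent from feature table")
    window = features[gene_id]
    assoc = read_sumstats(Path(config.exposure_dir) / f"{gene_id}.tsv",
                          trait_id=gene_id)
    assoc = extract_cis_window(assoc, window, config.cis_flank_bp)
    ld = _load_panel_ld(config.panel_path)[str(window.chrom)]
    cl = clump(assoc, ld, p_index=config.p_instrument,
               r2_thresh=config.clump_r2, window_kb=config.clump_window_kb)
    if not cl.index_variants:
        raise ConfigError(f"gene {gene_id} has no instruments at "
                          f"p <= {config.p_instrument}")
    instruments = assoc.subset(cl.index_variants)
    catalogue = {}
    paths = sorted(Path(outcome_dir).glob("*.tsv"))
    if not paths:
        raise ConfigError(f"no outcome tables in {outcome_dir}")
    for path in paths:
        catalogue[path.stem] = read_sumstats(path, trait_id=path.stem)
    table = downstream.phewas_scan(instruments, catalogue, config.alpha)
    table.rows.to_csv(out_dir / f"phewas_{gene_id}.tsv", sep="\t", index=False)
    with open(out_dir / f"phewas_{gene_id}.json", "w") as fh:
        json.dump({"gene_id": gene_id,
                   "bonferroni_threshold": table.bonferroni_threshold,
                   "n_outcomes_scanned": table.n_outcomes_scanned,
                   "pleiotropy_count": table.pleiotropy_count}, fh, indent=2)
    return table


def simulate_study(out_dir, n_genes: int = 20,
                   outcome_ids: tuple = ("trait_A", "trait_B"),
                   seed: int = 0, m: int = 60, n_ref: int = 400,
                   effect_fraction: float = 0.5) -> dict:
    """Materialize a synthetic multi-gene study on disk.

    Each gene occupies its own chromosome-labelled region of ``m`` variants.
    A fraction of genes share their causal eQTL variant with the first
    outcome (true effects, expected to colocalize); the rest are null.
    Writes per-gene exposure TSVs, outcome TSVs, a dosage panel TSV, a
    feature BED and a truth JSON; returns the truth record.
    """
    out_dir = Path(out_dir)
    (out_dir / "exposures").mkdir(parents=True, exist_ok=True)
    (out_dir / "outcomes").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    causal_idx = m // 2
    n_effect = int(round(effect_fraction * n_genes))

    outcome_frames = {o: [] for o in outcome_ids}
    panel_frames = []
    features = []
    truth = {"genes": {}, "seed": seed}
    for g in range(n_genes):
        gene_id = f"gene{g:03d}"
        chrom = str(g + 1)
        has_effect = g < n_effect
        traits = [simdata.TraitSpec(
            gene_id, "quantitative", simdata.N_BRAIN_EQTL, (causal_idx,),
            (simdata.beta_for_z(9.0, simdata.N_BRAIN_EQTL),))]
        for j, o in enumerate(outcome_ids):
            shared = has_effect and j == 0
            traits.append(simdata.TraitSpec(
                o, "binary", simdata.N_GWAS,
                (causal_idx,) if shared else (),
                (simdata.beta_for_z(8.0, simdata.N_GWAS),) if shared else ()))
        scen = simdata.ScenarioConfig(
            m, 0.9, tuple(traits), n_ref=n_ref,
            seed=int(rng.integers(2**31)), name=gene_id)
        region = simdata.simulate_summary_stats(scen)

        def relabel(df: pd.DataFrame) -> pd.DataFrame:
            df = df.copy()
            df["variant_id"] = [f"g{g}_{v}" for v in df["variant_id"]]
            df["chrom"] = chrom
            return df

        exp = region.assoc[gene_id]
        exp_df = relabel(exp.records)
        AssocSet(gene_id, exp_df).records  # validate
        write_sumstats(AssocSet(gene_id, exp_df), out_dir / "exposures" / f"{gene_id}.tsv")
        for o in outcome_ids:
            outcome_frames[o].append(relabel(region.assoc[o].records))
        pframe = pd.DataFrame(
            region.panel.T,
            columns=[f"ind{i}" for i in range(region.panel.shape[0])])
        pframe.insert(0, "pos", [region.ld.positions[v]
                                 for v in region.ld.variant_ids])
        pframe.insert(0, "chrom", chrom)
        pframe.insert(0, "variant_id", [f"g{g}_{v}"
                                        for v in region.ld.variant_ids])
        panel_frames.append(pframe)
        causal_pos = region.ld.positions[region.ld.variant_ids[causal_idx]]
        features.append((chrom, causal_pos - 5000, causal_pos + 5000, gene_id))
        truth["genes"][gene_id] = {"chrom": chrom, "has_effect": has_effect,
                                   "causal_variant": f"g{g}_rs{causal_idx + 1}"}

    for o, frames in outcome_frames.items():
        write_sumstats(AssocSet(o, pd.concat(frames, ignore_index=True),
                                "binary"), out_dir / "outcomes" / f"{o}.tsv")
    pd.concat(panel_frames, ignore_index=True).to_csv(
        out_dir / "panel.tsv", sep="\t", index=False)
    pd.DataFrame(features).to_csv(out_dir / "features.bed", sep="\t",
                                  index=False, header=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
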