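"""Marginal summary statistics: data model, I/O, harmonization, cis windows.

A trait's association evidence over a region is held as an :class:`AssocSet`
wrapping a pandas DataFrame with one row per variant. Effect sizes are on the
log-odds scale for binary traits and per-SD (or per unit stated by the source
GWAS) for quantitative traits; ``beta`` and ``se`` are authoritative and
p-values are recomputed from them whenever the two disagree.

Coordinates are 1-based and inclusive throughout, matching the convention of
GWAS summary-statistics files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyInputError, EmptyIntersectionError, FormatError

__all__ = [
    "COLUMNS",
    "DEFAULT_DIALECT",
    "SumStatRecord",
    "AssocSet",
    "GenomicWindow",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "extract_cis_window",
    "two_sided_p",
    "log_two_sided_p",
    "read_feature_table",
]

#: Canonical internal column order for an AssocSet table.
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: Default file-column names (PLINK/GWAS-catalog style) -> canonical names.
DEFAULT_DIALECT = {
    "SNP": "variant_id", "CHR": "chrom", "BP": "pos", "EA": "effect_allele",
    "OA": "other_allele", "EAF": "eaf", "BETA": "beta", "SE": "se",
    "P": "pval", "N": "n",
}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# Smallest positive double; two_sided_p never returns exactly zero.
_TINY = 5e-324


def log_two_sided_p(z: float) -> float:
    """Natural log of the two-sided normal p-value, 2*Phi(-|z|), exact for any z."""
    return math.log(2.0) + stats.norm.logsf(abs(z))


def two_sided_p(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal p-value ``2*Phi(-|z|)``.

    Computed in log space for large ``|z|`` and floored at the smallest
    positive double so the result is never exactly zero.
    """
    z = np.abs(z)
    logp = np.log(2.0) + stats.norm.logsf(z)
    p = np.exp(logp)
    p = np.maximum(p, _TINY)
    if np.ndim(z) == 0:
        return float(p)
    return p


@dataclass(frozen=True)
class SumStatRecord:
    """One variant's marginal association statistics for one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float  # effect-allele frequency; NaN when unreported
    beta: float
    se: float
    pval: float
    n: float  # sample (or effective sample) size; NaN when unreported

    @property
    def z(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        """A/T or C/G variants cannot be strand-checked from alleles alone."""
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass
class GenomicWindow:
    """1-based inclusive genomic interval [start, end] on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} > end {self.end}")


@dataclass
class AssocSet:
    """A trait's marginal summary statistics over a set of variants.

    Parameters
    ----------
    trait_id
        Identifier for the trait (gene probe, CpG probe, or outcome name).
    records
        DataFrame with the canonical :data:`COLUMNS`; sorted by (chrom, pos)
        on construction, variant ids must be unique.
    trait_type
        ``"quantitative"`` (beta per SD) or ``"binary"`` (beta = log odds).
    sd_y
        Phenotype SD for quantitative traits, used to scale the effect prior
        in colocalization; ``None`` means unknown (treated as 1).
    """

    trait_id: str
    records: pd.DataFrame
    trait_type: str = "quantitative"
    sd_y: float | None = None
    load_report: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"AssocSet missing columns: {missing}")
        if df["variant_id"].duplicated().any():
            dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
            raise FormatError(f"duplicate variant ids: {dups[:5]}")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.records = df[COLUMNS + [c for c in df.columns if c not in COLUMNS]]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return self.records["variant_id"].tolist()

    def zscores(self) -> np.ndarray:
        return (self.records["beta"] / self.records["se"]).to_numpy()

    def subset(self, variant_ids) -> "AssocSet":
        """Restrict to the given variants (order re-imposed by position)."""
        keep = self.records["variant_id"].isin(set(variant_ids))
        return AssocSet(self.trait_id, self.records[keep].copy(),
                        self.trait_type, self.sd_y)

    def record(self, variant_id: str) -> SumStatRecord:
        row = self.records.loc[self.records["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        r = row.iloc[0]
        return SumStatRecord(r.variant_id, str(r.chrom), int(r.pos),
                             r.effect_allele, r.other_allele, float(r.eaf),
                             float(r.beta), float(r.se), float(r.pval),
                             float(r.n))

    def iter_records(self):
        for r in self.records.itertuples(index=False):
            yield SumStatRecord(r.variant_id, str(r.chrom), int(r.pos),
                                r.effect_allele, r.other_allele, float(r.eaf),
                                float(r.beta), float(r.se), float(r.pval),
                                float(r.n))


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply per-row invariants; drop structural violations, fix p-values.

    beta/se are authoritative: a p-value disagreeing with 2*Phi(-|beta/se|)
    by more than 10% relative is recomputed rather than the row dropped.
    """
    report = {"n_read": len(df)}
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chrom"] = df["chrom"].astype(str)

    bad_se = ~(df["se"] > 0)
    bad_alleles = (
        ~df["effect_allele"].isin(_VALID_ALLELES)
        | ~df["other_allele"].isin(_VALID_ALLELES)
        | (df["effect_allele"] == df["other_allele"])
    )
    bad_p = ~((df["pval"] > 0) & (df["pval"] <= 1))
    bad_core = df["beta"].isna() | df["pos"].isna()
    bad_eaf = df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1))
    bad_n = df["n"].notna() & ~(df["n"] > 0)
    drop = bad_se | bad_alleles | bad_p | bad_core | bad_eaf | bad_n
    report["drop_count"] = int(drop.sum())
    report["drop_reasons"] = {
        "se_nonpositive": int(bad_se.sum()),
        "invalid_alleles": int(bad_alleles.sum()),
        "pval_out_of_range": int((bad_p & ~bad_se & ~bad_alleles).sum()),
        "missing_core_field": int(bad_core.sum()),
        "eaf_out_of_range": int(bad_eaf.sum()),
        "n_nonpositive": int(bad_n.sum()),
    }
    df = df[~drop].copy()
    df["pos"] = df["pos"].astype(int)

    # p/z consistency (only checkable above the double-precision floor)
    z = (df["beta"] / df["se"]).to_numpy()
    expected = two_sided_p(z)
    expected = np.asarray(expected, dtype=float)
    checkable = df["pval"].to_numpy() > 1e-300
    rel = np.abs(df["pval"].to_numpy() - expected) / expected
    inconsistent = checkable & (rel > 0.10)
    report["pval_recomputed"] = int(inconsistent.sum())
    if inconsistent.any():
        df.loc[inconsistent, "pval"] = expected[inconsistent]
    report["n_kept"] = len(df)
    return df, report


def read_sumstats(path, dialect: dict | None = None, trait_id: str | None = None,
                  trait_type: str = "quantitative", sd_y: float | None = None,
                  ) -> AssocSet:
    """Read a tab-delimited summary-statistics table into an AssocSet.

    ``dialect`` maps file column names to canonical names; defaults to
    :data:`DEFAULT_DIALECT`. Rows violating record invariants are dropped and
    counted in ``AssocSet.load_report``.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - parser detail
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [src for src in dialect if src not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    df = raw.rename(columns=dialect)[list(dialect.values())]
    df, report = _validate_rows(df)
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows after filtering")
    name = trait_id if trait_id is not None else str(path)
    out = AssocSet(name, df, trait_type=trait_type, sd_y=sd_y)
    out.load_report = report
    return out


def write_sumstats(assoc: AssocSet, path, dialect: dict | None = None) -> None:
    """Write an AssocSet back to the tab-delimited dialect it was read from."""
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    inv = {v: k for k, v in dialect.items()}
    df = assoc.records[COLUMNS].rename(columns=inv)
    df.to_csv(path, sep="\t", index=False)


def write_load_report(assoc: AssocSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(assoc.load_report, fh, indent=2)


def read_feature_table(path) -> dict[str, GenomicWindow]:
    """Read a 4-column BED-like TSV (chrom, start, end, feature_id).

    Coordinates are taken as 1-based inclusive, matching the package-wide
    convention (not BED half-open).
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "feature_id"])
    return {r.feature_id: GenomicWindow(str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples(index=False)}


def _classify_pair(ea_x, oa_x, ea_y, oa_y):
    """How do outcome alleles relate to exposure alleles?

    Returns one of 'same', 'swap', 'flip' (strand complement), 'flip_swap',
    or None when the allele sets cannot be reconciled.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return "flip"
    if (cea, coa) == (oa_x, ea_x):
        return "flip_swap"
    return None


def harmonize(exposure: AssocSet, outcome: AssocSet,
              palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
              ) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele, variant by variant.

    Rules applied per shared variant (matched on ``variant_id``):

    * outcome alleles identical -> retained as is;
    * outcome alleles swapped (or strand-complemented) relative to exposure ->
      outcome beta negated as needed and eaf complemented;
    * palindromic variants (A/T or C/G) with eaf inside
      ``palindrome_eaf_window`` on either side, or with missing eaf, are
      dropped as strand-ambiguous; outside the window, eaf agreement decides
      the strand;
    * irreconcilable allele sets are dropped.

    Returns a paired table with columns ``variant_id, chrom, pos,
    effect_allele, other_allele, eaf_exp, beta_exp, se_exp, n_exp, eaf_out,
    beta_out, se_out, n_out``. Harmonizing the output against the same
    exposure again is the identity (involution).
    """
    lo, hi = palindrome_eaf_window
    merged = exposure.records.merge(
        outcome.records, on="variant_id", suffixes=("_exp", "_out"))
    if merged.empty:
        raise EmptyIntersectionError(
            f"no shared variants between {exposure.trait_id} and {outcome.trait_id}")

    rows = []
    for r in merged.itertuples(index=False):
        ea_x, oa_x = r.effect_allele_exp, r.other_allele_exp
        rel = _classify_pair(ea_x, oa_x, r.effect_allele_out, r.other_allele_out)
        if rel is None:
            continue
        palindromic = oa_x == _COMPLEMENT[ea_x]
        beta_out, eaf_out = r.beta_out, r.eaf_out
        if palindromic:
            # alleles cannot distinguish strands; decide from frequencies
            if (np.isnan(r.eaf_exp) or np.isnan(eaf_out)
                    or lo <= r.eaf_exp <= hi or lo <= eaf_out <= hi):
                continue
            same_side = (r.eaf_exp - 0.5) * (eaf_out - 0.5) > 0
            aligned = rel in ("same", "flip")
            if aligned != same_side:
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
        elif rel in ("swap", "flip_swap"):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if not np.isnan(eaf_out) else eaf_out
        rows.append({
            "variant_id": r.variant_id, "chrom": r.chrom_exp, "pos": r.pos_exp,
            "effect_allele": ea_x, "other_allele": oa_x,
            "eaf_exp": r.eaf_exp, "beta_exp": r.beta_exp, "se_exp": r.se_exp,
            "n_exp": r.n_exp, "eaf_out": eaf_out, "beta_out": beta_out,
            "se_out": r.se_out, "n_out": r.n_out,
        })
    if not rows:
        raise EmptyIntersectionError(
            f"no reconcilable variants between {exposure.trait_id} and "
            f"{outcome.trait_id}")
    out = pd.DataFrame(rows).sort_values(["chrom", "pos"],
                                         kind="mergesort").reset_index(drop=True)
    return out


def harmonized_to_assocsets(table: pd.DataFrame, exposure: AssocSet,
                            outcome: AssocSet) -> tuple[AssocSet, AssocSet]:
    """Rebuild (exposure, outcome) AssocSets from a harmonized pair table."""
    def build(side: str, template: AssocSet) -> AssocSet:
        df = pd.DataFrame({
            "variant_id": table["variant_id"], "chrom": table["chrom"],
            "pos": table["pos"], "effect_allele": table["effect_allele"],
            "other_allele": table["other_allele"],
            "eaf": table[f"eaf_{side}"], "beta": table[f"beta_{side}"],
            "se": table[f"se_{side}"],
            "pval": two_sided_p((table[f"beta_{side}"] / table[f"se_{side}"]).to_numpy()),
            "n": table[f"n_{side}"],
        })
        return AssocSet(template.trait_id, df, template.trait_type, template.sd_y)
    return build("exp", exposure), build("out", outcome)


def extract_cis_window(assoc: AssocSet, feature: GenomicWindow,
                       flank_bp: int = 1_000_000) -> AssocSet:
    """Restrict an AssocSet to the cis-window of a feature.

    Retains variants with ``pos`` in ``[start - flank_bp, end + flank_bp]``
    (both endpoints inclusive) on the feature's chromosome.
    """
    df = assoc.records
    keep = (
        (df["chrom"].astype(str) == str(feature.chrom))
        & (df["pos"] >= feature.start - flank_bp)
        & (df["pos"] <= feature.end + flank_bp)
    )
    out = AssocSet(assoc.trait_id, df[keep].copy(), assoc.trait_type, assoc.sd_y)
    return out
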