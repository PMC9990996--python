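"""LD estimation, greedy clumping, and approximate conditional analysis.

The LD matrix is the signed Pearson correlation of reference-panel dosages.
Clumping follows the PLINK-style greedy rule (smallest p first, prune by r^2
within a window); conditional analysis residualizes marginal z-scores on a
set of index variants using the LD reference, an approximation to joint
summary-statistic conditional estimation that retains each variant's original
standard error.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CollinearityError, FormatError
from .sumstats import AssocSet, two_sided_p

__all__ = [
    "LDMatrix",
    "ClumpResult",
    "estimate_ld",
    "clump",
    "conditional_z",
    "conditional_assoc",
    "read_panel_tsv",
    "read_panel_vcf",
    "save_ld",
    "load_ld",
]


@dataclass
class LDMatrix:
    """Signed correlation matrix over an ordered variant list."""

    variant_ids: list[str]
    r: np.ndarray
    positions: dict[str, int] = field(default=None, repr=False)  # bp positions

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({m}, {m})")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("LD matrix not symmetric within 1e-12")
        self.r = (self.r + self.r.T) / 2.0
        np.clip(self.r, -1.0, 1.0, out=self.r)
        np.fill_diagonal(self.r, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __len__(self) -> int:
        return len(self.variant_ids)

    def index(self, variant_id: str) -> int:
        return self._index[variant_id]

    def subset(self, variant_ids) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        pos = None
        if self.positions is not None:
            pos = {v: self.positions[v] for v in variant_ids}
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)], pos)

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)


@dataclass
class ClumpResult:
    """Greedy clumping output: index variants plus pruned->index assignment."""

    index_variants: list[str]
    assignments: dict[str, str]

    def __len__(self) -> int:
        return len(self.index_variants)


def estimate_ld(genotype_dosages: np.ndarray, variant_ids) -> LDMatrix:
    """Pearson correlation of dosage columns from a reference panel.

    Monomorphic variants (zero variance) are excluded with a warning.
    """
    X = np.asarray(genotype_dosages, dtype=float)
    if X.ndim != 2:
        raise ValueError("dosage matrix must be n_individuals x m")
    variant_ids = list(variant_ids)
    if X.shape[1] != len(variant_ids):
        raise ValueError("variant_ids length mismatch with dosage columns")
    var = X.var(axis=0)
    keep = var > 0
    if not keep.all():
        dropped = [v for v, k in zip(variant_ids, keep) if not k]
        warnings.warn(f"excluding {len(dropped)} monomorphic variants: "
                      f"{dropped[:5]}", stacklevel=2)
        X = X[:, keep]
        variant_ids = [v for v, k in zip(variant_ids, keep) if k]
    if X.shape[1] == 1:
        return LDMatrix(variant_ids, np.ones((1, 1)))
    r = np.corrcoef(X, rowvar=False)
    return LDMatrix(variant_ids, r)


def clump(assoc: AssocSet, ld: LDMatrix, p_index: float = 5e-8,
          r2_thresh: float = 0.01, window_kb: int = 1000) -> ClumpResult:
    """Greedy p-value clumping of a region's associations.

    Repeatedly takes the unassigned variant with the smallest p <= ``p_index``
    as an index (ties broken by position, then variant id) and assigns to it
    every unassigned variant within ``window_kb`` whose r^2 with the index is
    >= ``r2_thresh``. A candidate index that is itself correlated at
    >= ``r2_thresh`` with an already-chosen index (possible beyond the window)
    is assigned to that index instead, so the index set always satisfies
    max pairwise r^2 < ``r2_thresh``.
    """
    df = assoc.records
    missing = [v for v in df["variant_id"] if v not in ld._index]
    if missing:
        raise FormatError(f"variants absent from LD reference: {missing[:5]}")
    order = df.sort_values(["pval", "pos", "variant_id"],
                           kind="mergesort")
    pos = dict(zip(df["variant_id"], df["pos"]))
    unassigned = set(df["variant_id"])
    index_variants: list[str] = []
    assignments: dict[str, str] = {}
    window_bp = window_kb * 1000

    for row in order.itertuples(index=False):
        v = row.variant_id
        if v not in unassigned or row.pval > p_index:
            continue
        # correlated with an existing (out-of-window) index? absorb, not promote
        owner = next((ix for ix in index_variants
                      if ld.r2(v, ix) >= r2_thresh), None)
        if owner is not None:
            assignments[v] = owner
            unassigned.discard(v)
            continue
        index_variants.append(v)
        unassigned.discard(v)
        for u in sorted(unassigned):
            if abs(pos[u] - pos[v]) <= window_bp and ld.r2(u, v) >= r2_thresh:
                assignments[u] = v
                unassigned.discard(u)
    return ClumpResult(index_variants, assignments)


def _condition_weights(ld: LDMatrix, condition_idx: list[int]) -> np.ndarray:
    """Inverse of the condition-set LD block, ridge-regularized when needed."""
    R_cc = ld.r[np.ix_(condition_idx, condition_idx)]
    if np.linalg.cond(R_cc) > 1e8:
        R_cc = R_cc + 1e-6 * np.eye(len(condition_idx))
    return np.linalg.inv(R_cc)


def conditional_z(z: np.ndarray, ld: LDMatrix, condition_idx, target_idx: int,
                  ) -> float:
    """z-score of the target variant conditional on the condition set.

    z_j|C = (z_j - r_jC R_CC^-1 z_C) / sqrt(1 - r_jC R_CC^-1 r_Cj)
    """
    condition_idx = list(condition_idx)
    if target_idx in condition_idx:
        raise ValueError("target variant inside the condition set")
    z = np.asarray(z, dtype=float)
    if not condition_idx:
        return float(z[target_idx])
    R_inv = _condition_weights(ld, condition_idx)
    r_jc = ld.r[target_idx, condition_idx]
    z_c = z[condition_idx]
    denom_sq = 1.0 - float(r_jc @ R_inv @ r_jc)
    if denom_sq <= 0 or np.sqrt(max(denom_sq, 0.0)) <= 1e-6:
        raise CollinearityError(
            f"target index {target_idx} nearly collinear with condition set")
    return float((z[target_idx] - r_jc @ R_inv @ z_c) / np.sqrt(denom_sq))


def conditional_assoc(assoc: AssocSet, ld: LDMatrix, condition_ids,
                      ) -> AssocSet:
    """Residualize a whole AssocSet on the given condition variants.

    Each remaining record's z is replaced by z|C; beta is rebuilt as
    z|C * se with the original se retained, and p recomputed. Condition
    variants are removed from the output. Variants collinear with the
    condition set propagate a CollinearityError.
    """
    condition_ids = [v for v in condition_ids]
    if not condition_ids:
        return AssocSet(assoc.trait_id, assoc.records.copy(),
                        assoc.trait_type, assoc.sd_y)
    df = assoc.records
    sub = ld.subset([v for v in df["variant_id"]])
    z = (df["beta"] / df["se"]).to_numpy()
    cond_idx = [sub.index(v) for v in condition_ids if v in sub._index]
    if not cond_idx:
        return AssocSet(assoc.trait_id, df.copy(), assoc.trait_type, assoc.sd_y)
    R_inv = _condition_weights(sub, cond_idx)
    z_c = z[cond_idx]
    out_rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.variant_id in condition_ids:
            continue
        r_jc = sub.r[i, cond_idx]
        denom_sq = 1.0 - float(r_jc @ R_inv @ r_jc)
        if denom_sq <= 0 or np.sqrt(max(denom_sq, 0.0)) <= 1e-6:
            raise CollinearityError(
                f"{row.variant_id} nearly collinear with condition set")
        z_adj = (z[i] - r_jc @ R_inv @ z_c) / np.sqrt(denom_sq)
        d = row._asdict()
        d["beta"] = z_adj * row.se
        d["pval"] = two_sided_p(z_adj)
        out_rows.append(d)
    out = pd.DataFrame(out_rows)
    return AssocSet(assoc.trait_id, out, assoc.trait_type, assoc.sd_y)


# ---------------------------------------------------------------------------
# Reference-panel I/O

def read_panel_tsv(path) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Read a dosage TSV: columns variant_id, chrom, pos, then one column per
    individual. Returns (n x m dosage matrix, variant_ids, positions)."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["variant_id", "chrom", "pos"]
    if not all(c in df.columns for c in meta_cols):
        raise FormatError(f"{path}: dosage TSV needs columns {meta_cols}")
    dosages = df.drop(columns=meta_cols).to_numpy(dtype=float).T
    positions = dict(zip(df["variant_id"], df["pos"].astype(int)))
    return dosages, df["variant_id"].tolist(), positions


def read_panel_vcf(path) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Read GT (or DS) dosages from a VCF reference panel via cyvcf2."""
    from cyvcf2 import VCF

    ids, positions, cols = [], {}, []
    for var in VCF(str(path)):
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        except Exception:
            gts = np.asarray(var.genotypes)[:, :2]
            ds = np.where(gts < 0, np.nan, gts).sum(axis=1).astype(float)
        ids.append(vid)
        positions[vid] = int(var.POS)
        cols.append(ds)
    if not ids:
        raise FormatError(f"{path}: no variants in VCF")
    return np.column_stack(cols), ids, positions


def save_ld(ld: LDMatrix, prefix: str) -> None:
    """Cache an LD matrix as compressed binary plus a JSON variant sidecar."""
    with gzip.open(f"{prefix}.ld.npy.gz", "wb") as fh:
        np.save(fh, ld.r)
    with open(f"{prefix}.ld.json", "w") as fh:
        json.dump({"variant_ids": ld.variant_ids,
                   "positions": ld.positions}, fh)


def load_ld(prefix: str) -> LDMatrix:
    with gzip.open(f"{prefix}.ld.npy.gz", "rb") as fh:
        r = np.load(fh)
    with open(f"{prefix}.ld.json") as fh:
        meta = json.load(fh)
    pos = meta.get("positions")
    if pos is not None:
        pos = {k: int(v) for k, v in pos.items()}
    return LDMatrix(meta["variant_ids"], r, pos)
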