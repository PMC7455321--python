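"""Instrument selection and strength diagnostics.

Two instrument arms are supported, mirroring the two-arm design of a blood
pressure / drug-target Mendelian randomization study:

* **BP-trait instruments** — genome-wide-significant SNPs (p < 5e-8) pruned
  to near-independence by greedy LD clumping (r^2 < 0.001);
* **drug-target proxies** — genome-wide-significant SNPs lying inside
  user-supplied gene regions (gene body, promoter, enhancer intervals),
  pruned at a lenient r^2 < 0.4 (sensitivity 0.1) and oriented to the
  BP-lowering allele, so a set of correlated cis variants proxies the
  pharmacological action of the encoded target.

LD is consumed as a user- or generator-supplied square correlation matrix;
no reference panel is downloaded or computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
WEAK_F_THRESHOLD = 10.0


class LDMatrix:
    """Pairwise correlations rho_ij among a set of variants.

    Symmetric with unit diagonal; ``rho`` entries are signed correlations on
    a fixed allele coding, so re-orienting a variant's effect allele flips
    the sign of its row and column (see :meth:`reorient`).  Clumping uses
    rho^2 and is orientation-invariant.
    """

    def __init__(self, variant_ids, rho, *, validate: bool = True, tol: float = 1e-8):
        self.variant_ids = list(variant_ids)
        self.rho = np.asarray(rho, dtype=float)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if validate:
            self.validate(tol=tol)

    def validate(self, tol: float = 1e-8) -> None:
        n = len(self.variant_ids)
        if self.rho.shape != (n, n):
            raise InputError(
                f"LD matrix shape {self.rho.shape} does not match {n} variant ids")
        if len(self._index) != n:
            raise InputError("duplicate variant ids in LD matrix")
        if not np.allclose(self.rho, self.rho.T, atol=tol):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=tol):
            raise InputError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.rho) > 1 + tol):
            raise InputError("LD correlations exceed |1|")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id) -> bool:
        return variant_id in self._index

    def subset(self, variant_ids) -> "LDMatrix":
        """Submatrix in the given variant order."""
        missing = [v for v in variant_ids if v not in self._index]
        if missing:
            raise InputError(f"variants missing from LD matrix: {missing}")
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.rho[np.ix_(idx, idx)], validate=False)

    def reorient(self, flipped_ids) -> "LDMatrix":
        """Flip the correlation sign for variants whose effect allele was swapped."""
        sign = np.ones(len(self))
        for v in flipped_ids:
            if v in self._index:
                sign[self._index[v]] = -1.0
        return LDMatrix(self.variant_ids, sign[:, None] * self.rho * sign[None, :],
                        validate=False)

    def r2(self, a, b) -> float:
        return float(self.rho[self._index[a], self._index[b]] ** 2)

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        """Read a square TSV with variant IDs as header row and first column."""
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if list(df.index) != list(df.columns):
            raise InputError("LD matrix row and column variant ids differ")
        return cls([str(v) for v in df.columns], df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.rho, index=self.variant_ids,
                     columns=self.variant_ids).to_csv(path, sep="\t")


@dataclass(frozen=True)
class GeneRegion:
    """A 1-based inclusive genomic interval tied to a drug-target gene."""

    name: str
    chrom: str
    start: int
    end: int
    kind: str = "gene_body"  # gene_body | promoter | enhancer

    def __post_init__(self):
        if self.start > self.end:
            raise InputError(f"region {self.name}: start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


def read_regions(path) -> list[GeneRegion]:
    """Read BED-like TSV (name, chrom, start, end[, kind]); 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    kinds = df["kind"] if "kind" in df.columns else ["gene_body"] * len(df)
    return [GeneRegion(str(r), str(c), int(s), int(e), str(k))
            for r, c, s, e, k in zip(df["name"], df["chrom"], df["start"], df["end"], kinds)]


def write_regions(regions, path) -> None:
    pd.DataFrame(
        [(r.name, r.chrom, r.start, r.end, r.kind) for r in regions],
        columns=["name", "chrom", "start", "end", "kind"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# selection

def select_gw_significant(records: pd.DataFrame, p_threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Rows with pval strictly below the threshold, original order preserved."""
    if not (0 < p_threshold < 1):
        raise ConfigurationError("p_threshold must lie in (0, 1)")
    out = records.loc[records["pval"] < p_threshold].reset_index(drop=True)
    if out.empty:
        logger.warning("no records reach p < %g", p_threshold)
    return out


def ld_clump(records: pd.DataFrame, ld: LDMatrix, r2_threshold: float) -> pd.DataFrame:
    """Greedy LD clumping.

    Records are visited by ascending p-value (ties broken by variant_id); a
    record is kept iff its squared correlation with every already-kept record
    is strictly below ``r2_threshold``.  Output is sorted by p-value.
    """
    if not (0 < r2_threshold <= 1):
        raise ConfigurationError("r2_threshold must lie in (0, 1]")
    missing = [v for v in records["variant_id"] if v not in ld]
    if missing:
        raise InputError(f"records missing from LD matrix: {missing}")
    ordered = records.sort_values(["pval", "variant_id"], kind="mergesort")
    kept: list[str] = []
    keep_idx = []
    for idx, vid in zip(ordered.index, ordered["variant_id"]):
        if all(ld.r2(vid, k) < r2_threshold for k in kept):
            kept.append(vid)
            keep_idx.append(idx)
    return ordered.loc[keep_idx].reset_index(drop=True)


def select_drug_proxies(
    records: pd.DataFrame,
    regions: list[GeneRegion],
    ld: LDMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = 0.4,
) -> pd.DataFrame:
    """Select cis BP-lowering proxies within drug-target gene regions.

    Keeps records lying inside ANY supplied region (1-based inclusive
    bounds), genome-wide significant at ``p_threshold``, then pruned by the
    greedy clumping rule at the lenient ``r2_threshold`` (default 0.4;
    sensitivity analyses use 0.1).  Each kept record is re-oriented so its
    effect allele is the BP-LOWERING allele (beta <= 0 after orientation);
    re-oriented rows are marked in the ``orientation_flipped`` column so the
    caller can flip the matching LD rows via :meth:`LDMatrix.reorient`.

    A single-proxy result is valid output; the pipeline flags such a class
    as single-instrument and restricts it to Wald-only estimation.
    """
    if not regions:
        raise ConfigurationError("empty drug-target region list")
    in_region = records.apply(
        lambda row: any(reg.contains(row["chrom"], row["pos"]) for reg in regions),
        axis=1,
    )
    candidates = select_gw_significant(records.loc[in_region], p_threshold)
    pruned = ld_clump(candidates, ld, r2_threshold)
    return orient_bp_lowering(pruned)


def orient_bp_lowering(records: pd.DataFrame) -> pd.DataFrame:
    """Flip alleles so every record's effect allele lowers BP (beta <= 0)."""
    out = records.copy()
    flip = out["beta"] > 0
    out.loc[flip, ["effect_allele", "other_allele"]] = (
        out.loc[flip, ["other_allele", "effect_allele"]].to_numpy())
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    out["orientation_flipped"] = flip.to_numpy()
    return out


def instrument_diagnostics(
    records: pd.DataFrame,
    trait_sd: float,
    n: float | None = None,
) -> pd.DataFrame:
    """Per-instrument F statistics and variance explained.

    F = (beta/se)^2; r2 = 2*eaf*(1-eaf)*beta^2 / trait_sd^2 under
    Hardy-Weinberg for a continuous trait (NaN when EAF is missing).
    ``weak`` flags F <= 10, the conventional weak-instrument threshold.
    ``n`` is recorded alongside for reporting when supplied.
    """
    if trait_sd <= 0:
        raise ConfigurationError("trait_sd must be positive")
    f_stat = (records["beta"] / records["se"]) ** 2
    r2 = 2.0 * records["eaf"] * (1.0 - records["eaf"]) * records["beta"] ** 2 / trait_sd ** 2
    out = pd.DataFrame({
        "variant_id": records["variant_id"],
        "f_stat": f_stat,
        "r2": r2,
        "weak": f_stat <= WEAK_F_THRESHOLD,
    })
    if n is not None:
        out["n"] = n
    return out.reset_index(drop=True)
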