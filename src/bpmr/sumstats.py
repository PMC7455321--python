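"""Reading, validation, and allele harmonization of GWAS summary statistics.

Summary statistics are held as pandas DataFrames with one row per biallelic
SNP and the canonical columns

    variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
    pval, n  (plus n_case / n_ctrl for binary traits when available)

``beta`` is the additive effect per copy of ``effect_allele`` in trait units
(mm Hg for blood pressure; log odds ratio for binary outcomes).  Coordinates
are 1-based inclusive.  Indels and multi-allelic records are rejected at read
time: the analysis operates on biallelic SNPs only.

Two-sample Mendelian randomization needs the variant-exposure and
variant-outcome effects expressed per copy of the *same* allele;
:func:`harmonize` aligns an outcome panel onto the exposure panel's effect
alleles, resolving allele order swaps and strand flips, and handling
palindromic (A/T, C/G) SNPs by allele-frequency concordance.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Default column mapping, GWAS-catalog-style headers -> canonical names.
DEFAULT_COLUMN_MAP = {
    "SNP": "variant_id",
    "CHR": "chrom",
    "BP": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
    "N_CASE": "n_case",
    "N_CTRL": "n_ctrl",
}

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)

#: Allele-alignment outcomes recorded per harmonized variant.
HARMONIZATION_ACTIONS = (
    "as_is",
    "beta_flipped",
    "strand_flipped",
    "strand_flipped_and_beta_flipped",
    "dropped_palindromic",
    "dropped_mismatch",
)


class ReadResult(NamedTuple):
    """Validated records plus the rejected rows with a per-row reason."""

    records: pd.DataFrame
    rejected: pd.DataFrame


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T and C/G SNPs, whose strand is ambiguous from alleles."""
    return _COMPLEMENT.get(ea) == oa


def _implied_log10_pval(z: np.ndarray) -> np.ndarray:
    # two-sided normal p from |z|, in log10 to survive tiny p-values
    return (np.log(2.0) + stats.norm.logsf(np.abs(z))) / np.log(10.0)


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait_kind: str = "continuous",
    delimiter: str | None = None,
    check_consistency: bool = True,
    consistency_tol: float = 1.0,
) -> ReadResult:
    """Read a delimited summary-statistics file and validate every row.

    Parameters
    ----------
    path
        Delimited text file with a header.  Tab/comma is auto-detected from
        the extension (``.csv`` -> comma, otherwise tab) unless ``delimiter``
        is given.  Lines starting with ``#`` are comments.
    column_map
        Mapping from file headers to canonical names; defaults to the
        GWAS-catalog-style :data:`DEFAULT_COLUMN_MAP`.  Already-canonical
        headers are accepted without mapping.
    trait_kind
        ``"continuous"`` or ``"binary"``.  For binary traits ``n`` is filled
        from ``n_case + n_ctrl`` when absent.
    check_consistency, consistency_tol
        When enabled, a row is rejected if the reported p-value disagrees
        with the two-sided normal p implied by beta/se by more than
        ``consistency_tol`` in log10 units.  GWAS files often truncate
        p-values, hence the generous default of one decade and the switch.

    Returns
    -------
    ReadResult
        ``records`` (valid rows, original order) and ``rejected`` (with a
        ``reason`` column).

    Raises
    ------
    ConfigurationError
        A mapped column is missing from the file.
    InputError
        The file yields zero valid rows.
    """
    if trait_kind not in ("continuous", "binary"):
        raise ConfigurationError(f"unknown trait_kind {trait_kind!r}")
    column_map = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    if delimiter is None:
        delimiter = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=delimiter, comment="#", dtype={"chrom": str},
                      float_precision="round_trip")

    rename = {src: dst for src, dst in column_map.items() if src in raw.columns}
    df = raw.rename(columns=rename)
    missing = [c for c in ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
               if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"mapped columns missing from {path}: {missing}; headers are {list(raw.columns)}"
        )
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if trait_kind == "binary" and {"n_case", "n_ctrl"} <= set(df.columns):
        df["n"] = df["n"].fillna(df["n_case"] + df["n_ctrl"])
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    reasons = _validate_rows(df, check_consistency, consistency_tol)
    bad = reasons != ""
    rejected = df.loc[bad].copy()
    rejected["reason"] = reasons[bad]
    for _, row in rejected.iterrows():
        logger.warning("rejected %s: %s", row.get("variant_id", "<no id>"), row["reason"])
    records = df.loc[~bad].reset_index(drop=True)
    if records.empty:
        raise InputError(f"no valid summary-statistic rows in {path}")
    extra = [c for c in ("n_case", "n_ctrl") if c in df.columns]
    return ReadResult(records[CANONICAL_COLUMNS + extra], rejected)


def _validate_rows(df: pd.DataFrame, check_consistency: bool, tol: float) -> pd.Series:
    """Per-row validation; returns '' for valid rows, else a reason string."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        mask = mask & (reasons == "")
        reasons[mask] = reason

    ea, oa = df["effect_allele"], df["other_allele"]
    flag(~ea.isin(_VALID_ALLELES) | ~oa.isin(_VALID_ALLELES),
         "non-SNP or multi-allelic alleles")
    flag(ea == oa, "identical alleles")
    flag(~np.isfinite(df["beta"]), "nonfinite beta")
    flag(~(df["se"] > 0), "nonpositive SE")
    flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "p-value outside (0, 1]")
    eaf = df["eaf"]
    flag(eaf.notna() & ~((eaf > 0) & (eaf < 1)), "EAF outside (0, 1)")
    if check_consistency:
        ok = reasons == ""
        z = df.loc[ok, "beta"] / df.loc[ok, "se"]
        implied = _implied_log10_pval(z.to_numpy())
        reported = np.log10(df.loc[ok, "pval"].to_numpy())
        bad = np.abs(reported - implied) > tol
        reasons[ok[ok].index[bad]] = "beta/se inconsistent with reported p-value"
    return reasons


# ---------------------------------------------------------------------------
# harmonization

HARMONIZED_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y",
    "pval_x", "pval_y", "n_x", "n_y", "harmonization_action",
]


def _check_unique(df: pd.DataFrame, label: str) -> None:
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise InputError(f"duplicate variant_id in {label} records: {sorted(set(dup))}")


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_window: float = 0.08,
) -> pd.DataFrame:
    """Align outcome effects onto the exposure panel's effect alleles.

    For each variant shared between the panels the outcome record is
    transformed so that ``beta_y`` is expressed per copy of the exposure's
    effect allele:

    * identical allele pair, same order -> kept as is;
    * same pair, order swapped -> outcome beta sign-flipped, EAF mirrored;
    * strand complement (A<->T, C<->G relabelling makes the pairs match) ->
      resolved, then the swap rule applied;
    * palindromic (A/T or C/G) SNPs -> allele labels cannot resolve strand,
      so orientation is inferred from allele-frequency concordance; dropped
      when either EAF lies within ``0.5 +/- palindrome_eaf_window`` or is
      missing;
    * anything else -> ``dropped_mismatch``.

    Returns one row per shared variant, kept and dropped alike, each carrying
    its ``harmonization_action``; filter with :func:`kept_instruments` before
    estimation.

    Raises
    ------
    InputError
        Duplicate variant_id within either panel.
    """
    if not (0 <= palindrome_eaf_window < 0.5):
        raise ConfigurationError("palindrome_eaf_window must lie in [0, 0.5)")
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")

    out_by_id = outcome.set_index("variant_id")
    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window
    rows = []
    for exp in exposure.itertuples(index=False):
        if exp.variant_id not in out_by_id.index:
            continue
        out = out_by_id.loc[exp.variant_id]
        rows.append(_harmonize_one(exp, out, lo, hi))
    return pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)


def _harmonize_one(exp, out, lo: float, hi: float) -> dict:
    ea_x, oa_x = exp.effect_allele, exp.other_allele
    ea_y, oa_y = out["effect_allele"], out["other_allele"]
    beta_y, eaf_y = out["beta"], out["eaf"]
    action = None

    if is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            action = "dropped_mismatch"
        else:
            eaf_x = exp.eaf
            # align labels first (a swap on a palindromic SNP is also a
            # strand flip, so the net transform is at most a beta flip)
            flipped = ea_y != ea_x
            if flipped:
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            if pd.isna(eaf_x) or pd.isna(eaf_y) or lo <= eaf_x <= hi or lo <= eaf_y <= hi:
                action = "dropped_palindromic"
            else:
                if (eaf_x < 0.5) != (eaf_y < 0.5):  # opposite strands
                    beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                    flipped = not flipped
                action = "beta_flipped" if flipped else "as_is"
    elif (ea_y, oa_y) == (ea_x, oa_x):
        action = "as_is"
    elif (ea_y, oa_y) == (oa_x, ea_x):
        beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        action = "beta_flipped"
    else:
        comp = (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y])
        if comp == (ea_x, oa_x):
            action = "strand_flipped"
        elif comp == (oa_x, ea_x):
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            action = "strand_flipped_and_beta_flipped"
        else:
            action = "dropped_mismatch"

    return {
        "variant_id": exp.variant_id,
        "chrom": exp.chrom,
        "pos": exp.pos,
        "effect_allele": ea_x,
        "other_allele": oa_x,
        "beta_x": exp.beta,
        "se_x": exp.se,
        "beta_y": beta_y,
        "se_y": out["se"],
        "eaf_x": exp.eaf,
        "eaf_y": eaf_y,
        "pval_x": exp.pval,
        "pval_y": out["pval"],
        "n_x": exp.n,
        "n_y": out["n"],
        "harmonization_action": action,
    }


def kept_instruments(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows that survived harmonization (dropped records never enter estimation)."""
    keep = ~harmonized["harmonization_action"].str.startswith("dropped")
    return harmonized.loc[keep].reset_index(drop=True)


def write_harmonized(harmonized: pd.DataFrame, path) -> None:
    """Write harmonized instruments as TSV, including the action column."""
    harmonized.to_csv(path, sep="\t", index=False)


def read_harmonized(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_harmonized` (value-exact round trip)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    return df[HARMONIZED_COLUMNS]


def write_sumstats(records: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write canonical summary statistics as TSV; seed recorded as a comment."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        records.to_csv(fh, sep="\t", index=False)
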