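"""Summary-statistic reading, validation and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bpmr.exceptions import ConfigurationError, InputError
from bpmr.sumstats import (
    harmonize, kept_instruments, read_harmonized, read_sumstats,
    write_harmonized, write_sumstats,
)
from conftest import make_records


def _p(beta, se):
    return 2 * stats.norm.sf(abs(beta / se))


def write_tsv(path, df, header_map=None):
    out = df.copy()
    if header_map:
        out = out.rename(columns=header_map)
    out.to_csv(path, sep="\t", index=False)
    return path


GOOD = make_records([
    dict(variant_id="rs1", effect_allele="A", other_allele="G", beta=0.3, se=0.05,
         pval=_p(0.3, 0.05)),
    dict(variant_id="rs2", effect_allele="C", other_allele="T", beta=-0.1, se=0.04,
         pval=_p(-0.1, 0.04)),
    dict(variant_id="rs3", effect_allele="G", other_allele="T", beta=0.02, se=0.03,
         pval=_p(0.02, 0.03)),
])


class TestReadSumstats:
    def test_well_formed_file_reads_all_rows(self, tmp_path):
        path = write_tsv(tmp_path / "x.tsv", GOOD)
        res = read_sumstats(path)
        assert len(res.records) == 3 and res.rejected.empty
        assert list(res.records["variant_id"]) == ["rs1", "rs2", "rs3"]

    def test_gwas_catalog_headers_are_mapped(self, tmp_path):
        headers = {"variant_id": "SNP", "chrom": "CHR", "pos": "BP",
                   "effect_allele": "EA", "other_allele": "OA", "eaf": "EAF",
                   "beta": "BETA", "se": "SE", "pval": "P", "n": "N"}
        path = write_tsv(tmp_path / "x.tsv", GOOD, headers)
        assert len(read_sumstats(path).records) == 3

    @pytest.mark.parametrize("bad_row, reason", [
        (dict(variant_id="rsX", effect_allele="A", other_allele="G",
              beta=0.1, se=0.0, pval=0.5), "nonpositive SE"),
        (dict(variant_id="rsX", effect_allele="AT", other_allele="G",
              beta=0.1, se=0.1, pval=_p(0.1, 0.1)), "non-SNP"),
        (dict(variant_id="rsX", effect_allele="A", other_allele="A",
              beta=0.1, se=0.1, pval=_p(0.1, 0.1)), "identical alleles"),
        (dict(variant_id="rsX", effect_allele="A", other_allele="G",
              beta=0.1, se=0.1, pval=1.5), "p-value outside"),
        (dict(variant_id="rsX", effect_allele="A", other_allele="G",
              beta=0.1, se=0.1, eaf=1.2, pval=_p(0.1, 0.1)), "EAF outside"),
        # |z| = 5 implies p ~ 5.7e-7; reporting 0.9 is off by >1 decade
        (dict(variant_id="rsX", effect_allele="A", other_allele="G",
              beta=0.05, se=0.01, pval=0.9), "inconsistent"),
    ])
    def test_invalid_rows_rejected_with_reason(self, tmp_path, bad_row, reason):
        path = write_tsv(tmp_path / "x.tsv", make_records(
            [dict(variant_id="rs1", effect_allele="A", other_allele="G",
                  beta=0.3, se=0.05, pval=_p(0.3, 0.05)), bad_row]))
        res = read_sumstats(path)
        assert len(res.records) == 1
        assert reason in res.rejected["reason"].iloc[0]

    def test_consistency_check_can_be_disabled(self, tmp_path):
        df = make_records([dict(variant_id="rs1", effect_allele="A",
                                other_allele="G", beta=0.05, se=0.01, pval=0.9)])
        path = write_tsv(tmp_path / "x.tsv", df)
        res = read_sumstats(path, check_consistency=False)
        assert len(res.records) == 1

    def test_missing_mapped_column_is_configuration_error(self, tmp_path):
        path = write_tsv(tmp_path / "x.tsv", GOOD.drop(columns=["se"]))
        with pytest.raises(ConfigurationError, match="se"):
            read_sumstats(path)

    def test_zero_valid_rows_is_input_error(self, tmp_path):
        df = make_records([dict(variant_id="rs1", effect_allele="A",
                                other_allele="G", beta=0.1, se=-1.0, pval=0.5)])
        path = write_tsv(tmp_path / "x.tsv", df)
        with pytest.raises(InputError):
            read_sumstats(path)

    def test_binary_trait_n_filled_from_cases_and_controls(self, tmp_path):
        df = GOOD.copy()
        df["n"] = np.nan
        df["n_case"], df["n_ctrl"] = 100.0, 400.0
        path = write_tsv(tmp_path / "x.tsv", df)
        res = read_sumstats(path, trait_kind="binary")
        assert (res.records["n"] == 500.0).all()

    def test_seed_comment_roundtrip(self, tmp_path):
        path = tmp_path / "x.tsv"
        write_sumstats(GOOD, path, seed=42)
        assert read_sumstats(path).records.shape[0] == 3
        assert "# seed=42" in path.read_text().splitlines()[0]


def _one_exposure(ea="A", oa="G", beta=0.3, eaf=0.2):
    return make_records([dict(variant_id="rs1", effect_allele=ea, other_allele=oa,
                              beta=beta, se=0.05, eaf=eaf, pval=_p(beta, 0.05))])


def _one_outcome(ea, oa, beta=0.2, eaf=0.3):
    return make_records([dict(variant_id="rs1", effect_allele=ea, other_allele=oa,
                              beta=beta, se=0.1, eaf=eaf, pval=_p(beta, 0.1))])


class TestHarmonize:
    # hand-written truth table for exposure pair (A, G), outcome beta 0.2,
    # eaf 0.3: expected action, harmonized beta_y and eaf_y
    TRUTH_TABLE = {
        ("A", "G"): ("as_is", 0.2, 0.3),
        ("G", "A"): ("beta_flipped", -0.2, 0.7),
        ("T", "C"): ("strand_flipped", 0.2, 0.3),
        ("C", "T"): ("strand_flipped_and_beta_flipped", -0.2, 0.7),
    }

    @pytest.mark.parametrize("pair", [(a, b) for a in "ACGT" for b in "ACGT" if a != b])
    def test_allele_pair_truth_table(self, pair):
        """All 12 ordered outcome allele pairs against exposure (A, G)."""
        h = harmonize(_one_exposure(), _one_outcome(*pair))
        assert len(h) == 1
        row = h.iloc[0]
        if pair in self.TRUTH_TABLE:
            action, beta_y, eaf_y = self.TRUTH_TABLE[pair]
            assert row["harmonization_action"] == action
            assert row["beta_y"] == pytest.approx(beta_y)
            assert row["eaf_y"] == pytest.approx(eaf_y)
            assert (row["effect_allele"], row["other_allele"]) == ("A", "G")
        else:
            assert row["harmonization_action"] == "dropped_mismatch"

    @pytest.mark.parametrize("eaf_x, eaf_y, expected_action, expected_beta", [
        (0.2, 0.25, "as_is", 0.2),          # same minor side, same labels
        (0.2, 0.75, "beta_flipped", -0.2),  # opposite sides: strand flip
        (0.50, 0.2, "dropped_palindromic", None),   # exposure EAF in window
        (0.2, 0.45, "dropped_palindromic", None),   # outcome EAF in window
        (np.nan, 0.2, "dropped_palindromic", None),  # missing EAF
    ])
    def test_palindromic_resolved_by_eaf(self, eaf_x, eaf_y, expected_action,
                                         expected_beta):
        h = harmonize(_one_exposure("A", "T", eaf=eaf_x),
                      _one_outcome("A", "T", eaf=eaf_y),
                      palindrome_eaf_window=0.08)
        row = h.iloc[0]
        assert row["harmonization_action"] == expected_action
        if expected_beta is not None:
            assert row["beta_y"] == pytest.approx(expected_beta)

    def test_palindromic_label_swap_then_eaf_agreement(self):
        # outcome (T, A) eaf 0.75 == exposure allele A at eaf 0.25: net flip only
        h = harmonize(_one_exposure("A", "T", eaf=0.25),
                      _one_outcome("T", "A", beta=0.4, eaf=0.75))
        row = h.iloc[0]
        assert row["harmonization_action"] == "beta_flipped"
        assert row["beta_y"] == pytest.approx(-0.4)

    def test_duplicate_variant_id_is_input_error(self):
        dup = pd.concat([_one_exposure(), _one_exposure()], ignore_index=True)
        with pytest.raises(InputError, match="rs1"):
            harmonize(dup, _one_outcome("A", "G"))

    def test_bad_window_rejected(self):
        with pytest.raises(ConfigurationError):
            harmonize(_one_exposure(), _one_outcome("A", "G"),
                      palindrome_eaf_window=0.5)

    def test_kept_plus_dropped_equals_intersection(self, rng):
        from bpmr.synthgen import ScenarioConfig, generate_pair
        pair = generate_pair(ScenarioConfig(n_snps=40, seed=5))
        outcome = pair.outcome.iloc[5:].reset_index(drop=True)  # partial overlap
        h = harmonize(pair.exposure, outcome)
        assert len(h) == 35
        n_dropped = h["harmonization_action"].str.startswith("dropped").sum()
        assert len(kept_instruments(h)) + n_dropped == 35

    def test_involution_under_role_swap(self):
        """Harmonizing with roles swapped keeps the same set and mirrored betas."""
        from bpmr.synthgen import ScenarioConfig, generate_pair
        pair = generate_pair(ScenarioConfig(n_snps=30, seed=9))
        fwd = kept_instruments(harmonize(pair.exposure, pair.outcome))
        rev = kept_instruments(harmonize(pair.outcome, pair.exposure))
        assert set(fwd["variant_id"]) == set(rev["variant_id"])
        merged = fwd.merge(rev, on="variant_id", suffixes=("_f", "_r"))
        # the role swap must recover identical effect magnitudes per variant
        np.testing.assert_allclose(np.abs(merged["beta_x_f"]),
                                   np.abs(merged["beta_y_r"]), rtol=1e-12)
        np.testing.assert_allclose(np.abs(merged["beta_y_f"]),
                                   np.abs(merged["beta_x_r"]), rtol=1e-12)
        # and consistent relative orientation: the Wald ratio in one direction
        # is the reciprocal of the ratio in the other
        np.testing.assert_allclose(
            merged["beta_y_f"] / merged["beta_x_f"],
            merged["beta_x_r"] / merged["beta_y_r"], rtol=1e-12)

    def test_harmonized_roundtrip_is_value_exact(self, tmp_path):
        from bpmr.synthgen import ScenarioConfig, generate_pair
        pair = generate_pair(ScenarioConfig(n_snps=25, seed=3))
        h = harmonize(pair.exposure, pair.outcome)
        path = tmp_path / "harmonized.tsv"
        write_harmonized(h, path)
        back = read_harmonized(path)
        for col in ("beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y"):
            np.testing.assert_array_equal(h[col].to_numpy(), back[col].to_numpy())

    def test_harmonization_undoes_generator_scrambling(self):
        """Scrambled outcome representations must map back onto the truth."""
        from bpmr.synthgen import ScenarioConfig, generate_pair
        cfg = ScenarioConfig(n_snps=50, theta_true=0.1, seed=21,
                             scramble_outcome_alleles=True)
        pair = generate_pair(cfg)
        h = kept_instruments(harmonize(pair.exposure, pair.outcome))
        assert len(h) == 50  # non-palindromic panel: nothing dropped
        # beta_y on the exposure orientation correlates with theta*gamma
        resid = h["beta_y"] - cfg.theta_true * np.asarray(pair.truth.gamma)
        assert np.all(np.abs(resid) < 6 * h["se_y"])
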