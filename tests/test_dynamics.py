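import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from apmskit.dynamics import (aggregate_sites, normalize_prey_to_bait,
                              normalize_ptm_to_protein,
                              timecourse_significance)
from apmskit.io_maxquant import ModifiedPeptideTable


def ptm_table(meta_rows, intensities, sample_ids):
    meta = pd.DataFrame(meta_rows).set_index("peptide_id")
    intens = pd.DataFrame(np.asarray(intensities, dtype=float),
                          index=meta.index, columns=sample_ids)
    return ModifiedPeptideTable(meta=meta, intensities=intens)


class TestNormalizePreyToBait:
    def test_ratio_formula(self, timecourse_annotation):
        sids = timecourse_annotation.sample_ids
        mat = pd.DataFrame(
            [[2.0 ** 22] * 16, [2.0 ** 22] * 16, [2.0 ** 20] * 16],
            index=["BAIT", "PREY_EQ", "PREY_QTR"], columns=sids)
        out = normalize_prey_to_bait(mat, "BAIT")
        assert (out.loc["PREY_EQ"] == 1.0).all()
        assert (out.loc["PREY_QTR"] == 0.25).all()

    def test_missing_bait_sample_blanks_all_preys(self, timecourse_annotation,
                                                  caplog):
        sids = timecourse_annotation.sample_ids
        mat = pd.DataFrame(np.full((3, 16), 100.0),
                           index=["BAIT", "P1", "P2"], columns=sids)
        mat.loc["BAIT", sids[0]] = 0.0  # bait not quantified in sample 1
        with caplog.at_level("WARNING"):
            out = normalize_prey_to_bait(mat, "BAIT")
        assert out[sids[0]].isna().all()
        assert out[sids[1]].notna().all()
        assert any("1 sample" in rec.message for rec in caplog.records)

    def test_absent_bait_row_rejected(self, timecourse_annotation):
        mat = pd.DataFrame(np.full((1, 16), 1.0), index=["P1"],
                           columns=timecourse_annotation.sample_ids)
        with pytest.raises(ValueError, match="absent"):
            normalize_prey_to_bait(mat, "BAIT")

    def test_scale_equivariance(self, timecourse_annotation):
        # multiplying all intensities of one sample by any constant leaves
        # every normalized value unchanged (loading-artifact removal)
        sids = timecourse_annotation.sample_ids
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.lognormal(15, 1, (5, 16)),
                           index=["BAIT", "P1", "P2", "P3", "P4"], columns=sids)
        scaled = mat.copy()
        scaled[sids[3]] *= 7.5
        pd.testing.assert_frame_equal(normalize_prey_to_bait(mat, "BAIT"),
                                      normalize_prey_to_bait(scaled, "BAIT"))


class TestNormalizePtmToProtein:
    def test_valid_value_rule_per_timepoint(self, timecourse_annotation):
        sids = timecourse_annotation.sample_ids
        prot = pd.DataFrame(np.full((1, 16), 1000.0), index=["P1"], columns=sids)
        # siteA: 2 valid replicates at every time point -> dropped
        rowA = np.zeros(16)
        for t_block in range(4):
            rowA[t_block * 4:t_block * 4 + 2] = 50.0
        # siteB: 3 valid replicates at 15 min only -> retained
        rowB = np.zeros(16)
        rowB[8:11] = 50.0  # 15-min block is samples 9..12
        table = ptm_table(
            [{"peptide_id": "pepA", "protein_id": "P1", "mod_type": "phospho",
              "site_position": 10, "residue": "S"},
             {"peptide_id": "pepB", "protein_id": "P1", "mod_type": "phospho",
              "site_position": 20, "residue": "T"}],
            np.vstack([rowA, rowB]), sids)
        out = normalize_ptm_to_protein(table, prot, timecourse_annotation)
        assert list(out.index) == ["P1_phospho_20"]
        # no imputation: unquantified cells stay missing
        assert out.loc["P1_phospho_20"].notna().sum() == 3

    def test_ratio_one_when_peptide_equals_protein(self, timecourse_annotation):
        sids = timecourse_annotation.sample_ids
        prot = pd.DataFrame(np.full((1, 16), 777.0), index=["P1"], columns=sids)
        table = ptm_table(
            [{"peptide_id": "pep", "protein_id": "P1", "mod_type": "acetyl",
              "site_position": 5, "residue": "K"}],
            np.full((1, 16), 777.0), sids)
        out = normalize_ptm_to_protein(table, prot, timecourse_annotation)
        assert (out.loc["P1_acetyl_5"] == 1.0).all()

    def test_unquantified_protein_skipped_with_warning(self,
                                                       timecourse_annotation,
                                                       caplog):
        sids = timecourse_annotation.sample_ids
        prot = pd.DataFrame(np.full((1, 16), 10.0), index=["OTHER"], columns=sids)
        table = ptm_table(
            [{"peptide_id": "pep", "protein_id": "P1", "mod_type": "phospho",
              "site_position": 5, "residue": "S"}],
            np.full((1, 16), 5.0), sids)
        with caplog.at_level("WARNING"):
            out = normalize_ptm_to_protein(table, prot, timecourse_annotation)
        assert len(out) == 0
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_peptide_rows_summed_per_site(self, timecourse_annotation):
        sids = timecourse_annotation.sample_ids
        table = ptm_table(
            [{"peptide_id": "pep1", "protein_id": "P1", "mod_type": "phospho",
              "site_position": 9, "residue": "S"},
             {"peptide_id": "pep2", "protein_id": "P1", "mod_type": "phospho",
              "site_position": 9, "residue": "S"}],
            np.vstack([np.full(16, 30.0), np.full(16, 12.0)]), sids)
        agg = aggregate_sites(table)
        assert (agg.loc["P1_phospho_9"] == 42.0).all()


class TestTimecourseSignificance:
    def test_identical_distributions_not_significant(self, timecourse_annotation):
        sids = timecourse_annotation.sample_ids
        ratios = pd.DataFrame([[1.0] * 16], index=["F"], columns=sids)
        ratios.iloc[0] += np.tile([0.0, 0.01, -0.01, 0.005], 4)
        out = timecourse_significance(ratios, timecourse_annotation)
        assert not out.loc["F", "significant_any_time"]

    def test_fourfold_shift_detected_and_matches_t_oracle(self,
                                                          timecourse_annotation):
        sids = timecourse_annotation.sample_ids
        rng = np.random.default_rng(4)
        base = rng.normal(1.0, 0.1, 4).clip(0.5)
        late = rng.normal(4.0, 0.4, 4).clip(2.0)  # 4-fold at 30 min, CV ~10%
        row = np.concatenate([base, rng.normal(1.0, 0.1, 8).clip(0.5), late])
        ratios = pd.DataFrame([row], index=["F"], columns=sids)
        out = timecourse_significance(ratios, timecourse_annotation)
        p_oracle = sstats.ttest_ind(np.log2(late), np.log2(base),
                                    equal_var=True).pvalue
        assert out.loc["F", "p_30min"] == pytest.approx(p_oracle)
        assert p_oracle < 0.05
        assert out.loc["F", "significant_any_time"]

    def test_single_significant_timepoint_sets_any_flag(self,
                                                        timecourse_annotation):
        sids = timecourse_annotation.sample_ids
        row = np.ones(16) + np.tile([0.0, 0.02, -0.02, 0.01], 4)
        row[4:8] = [5.0, 5.1, 4.9, 5.05]  # shifted at 5 min only
        ratios = pd.DataFrame([row], index=["F"], columns=sids)
        out = timecourse_significance(ratios, timecourse_annotation)
        assert out.loc["F", "p_5min"] < 0.05
        assert out.loc["F", ["p_15min", "p_30min"]].min() > 0.05
        assert out.loc["F", "significant_any_time"]

    def test_result_invariant_to_feature_order(self, timecourse_annotation):
        sids = timecourse_annotation.sample_ids
        rng = np.random.default_rng(9)
        ratios = pd.DataFrame(rng.lognormal(0, 0.3, (6, 16)),
                              index=[f"F{i}" for i in range(6)], columns=sids)
        fwd = timecourse_significance(ratios, timecourse_annotation)
        rev = timecourse_significance(ratios.iloc[::-1], timecourse_annotation)
        pd.testing.assert_frame_equal(fwd, rev.loc[fwd.index])

    def test_missing_time_zero_rejected(self, timecourse_annotation):
        activated = timecourse_annotation.subset(
            [s for s in timecourse_annotation.sample_ids if "t0_" not in s])
        ratios = pd.DataFrame([[1.0] * len(activated)], index=["F"],
                              columns=activated.sample_ids)
        with pytest.raises(ValueError, match="time-0"):
            timecourse_significance(ratios, activated)
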