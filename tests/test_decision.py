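"""Decision engine: table fidelity, band partition, classification,
sequential 1,5-AG logic, timing, and concordance labeling."""

import numpy as np
import pytest

from insulaid import (
    Agreement,
    AidName,
    AnhydroglucitolValue,
    ConfigError,
    EngineConfig,
    GlucoseValue,
    GlycemicProfile,
    HbA1cValue,
    IndexName,
    InsufficientDataError,
    MealTag,
    PpgReading,
    RatioScale,
    Regimen,
    Unit,
    ValidationError,
    assess,
    classify,
    default_tables,
    pfi,
    ppge,
    sequential_ag_assessment,
    timing_recommendation,
)
from insulaid.indices import IndexResult

mg = lambda v: GlucoseValue(v, Unit.MG_DL)


def _tables(**cfg_kwargs):
    return {t.name: t for t in default_tables(EngineConfig(**cfg_kwargs))}


# Verbatim content of the three published decision tables:
# (aid, band label, choice 1, choice 2) for every row.
PRINTED_TABLES = [
    (AidName.AID1, ">74 mg%", Regimen.RAPID_ACTING, Regimen.PREMIXED_50_50),
    (AidName.AID1, "40-74 mg%", Regimen.PREMIXED_30_70, Regimen.PREMIXED_50_50),
    (AidName.AID1, "<40 mg%", Regimen.BASAL, Regimen.PREMIXED_30_70),
    (AidName.AID2, ">0.6", Regimen.RAPID_ACTING, Regimen.PREMIXED_50_50),
    (AidName.AID2, "0.4-0.6", Regimen.PREMIXED_30_70, Regimen.PREMIXED_50_50),
    (AidName.AID2, "<0.4", Regimen.BASAL, Regimen.PREMIXED_30_70),
    (AidName.AID3, ">=20", Regimen.BASAL, Regimen.PREMIXED_WITH_DINNER),
    (AidName.AID3, "<20", Regimen.PREMIXED, Regimen.PREMIXED_WITH_BREAKFAST),
]


class TestDefaultTables:
    def test_every_printed_band_and_choice(self):
        """Regression fixture: the default tables reproduce the published
        rows cell for cell."""
        tables = _tables()
        actual = [
            (name, band.label, band.choice1, band.choice2)
            for name in (AidName.AID1, AidName.AID2, AidName.AID3)
            for band in tables[name].bands
        ]
        assert actual == PRINTED_TABLES

    def test_band_counts(self):
        tables = _tables()
        assert [len(tables[n].bands) for n in (AidName.AID1, AidName.AID2, AidName.AID3)] \
            == [3, 3, 2]

    def test_mmol_scale_table_uses_13_cutoff(self):
        tables = _tables(aid3_scale=RatioScale.MMOL_SCALE)
        assert tables[AidName.AID3].bands[0].lower == 1.3
        assert tables[AidName.AID3].scale == "mmol/l per %"

    def test_aid3_rationales_as_printed(self):
        aid3 = _tables()[AidName.AID3]
        assert aid3.bands[0].rationale == "Higher ratio means fasting type hyperglycemia"
        assert aid3.bands[1].rationale == "Lower ratio means postprandial type hyperglycemia"

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ConfigError):
            default_tables(EngineConfig(aid1_lower=80.0, aid1_upper=74.0))

    @pytest.mark.parametrize("aid", [AidName.AID1, AidName.AID2, AidName.AID3])
    def test_partition_exhaustive_and_disjoint(self, aid):
        """Every value on a fine grid (plus the exact cutoffs) falls in
        exactly one band."""
        table = _tables()[aid]
        grid = np.concatenate([
            np.linspace(-50, 150, 2001),
            np.array([40.0, 74.0, 0.4, 0.6, 1.3, 20.0]),
            np.nextafter([40.0, 74.0, 0.4, 0.6, 20.0], -np.inf),
            np.nextafter([40.0, 74.0, 0.4, 0.6, 20.0], np.inf),
        ])
        for v in grid:
            assert sum(b.contains(float(v)) for b in table.bands) == 1


class TestClassify:
    @pytest.mark.parametrize("value, choice1", [
        (100.0, Regimen.RAPID_ACTING),
        (74.0, Regimen.PREMIXED_30_70),   # middle band owns its endpoints
        (40.0, Regimen.PREMIXED_30_70),
        (39.999, Regimen.BASAL),
        (-5.0, Regimen.BASAL),
    ])
    def test_aid1_bands(self, value, choice1):
        result = IndexResult(IndexName.PPGE, value=value, scale="mg/dl")
        assert classify(result, _tables()[AidName.AID1]).choice1 is choice1

    @pytest.mark.parametrize("value, choice1", [
        (0.7, Regimen.RAPID_ACTING),
        (0.6, Regimen.PREMIXED_30_70),
        (0.5, Regimen.PREMIXED_30_70),
        (0.4, Regimen.PREMIXED_30_70),
        (0.1, Regimen.BASAL),
    ])
    def test_aid2_bands(self, value, choice1):
        result = IndexResult(IndexName.PFI, value=value, scale="dimensionless")
        assert classify(result, _tables()[AidName.AID2]).choice1 is choice1

    def test_aid3_cutoff_goes_to_basal_with_ambiguity_note(self):
        result = IndexResult(IndexName.FPG_HBA1C, value=20.0, scale="mg% per %")
        rec = classify(result, _tables()[AidName.AID3])
        assert rec.choice1 is Regimen.BASAL
        assert any("boundary ambiguity" in n for n in rec.notes)

    def test_aid3_above_cutoff_mmol(self):
        result = IndexResult(IndexName.FPG_HBA1C, value=1.5, scale="mmol/l per %")
        rec = classify(result, _tables(aid3_scale=RatioScale.MMOL_SCALE)[AidName.AID3])
        assert rec.choice1 is Regimen.BASAL
        assert rec.rationale == "Higher ratio means fasting type hyperglycemia"

    def test_negative_excursion_lowest_band_with_warning(self):
        result = ppge(mg(200), mg(180))
        rec = classify(result, _tables()[AidName.AID1])
        assert rec.choice1 is Regimen.BASAL
        assert any("data-quality" in n for n in rec.notes)

    def test_inapplicable_index_rejected(self):
        bad = ppge(mg(126), None)
        with pytest.raises(ValidationError):
            classify(bad, _tables()[AidName.AID1])

    def test_scale_mismatch_rejected(self):
        result = IndexResult(IndexName.FPG_HBA1C, value=1.2, scale="mmol/l per %")
        with pytest.raises(ValidationError):
            classify(result, _tables()[AidName.AID3])  # mg-scale table

    def test_monotone_in_ppg_at_fixed_fpg(self):
        """Raising PPG never moves the first choice toward more basal."""
        ladder = {Regimen.BASAL: 0, Regimen.PREMIXED_30_70: 1, Regimen.RAPID_ACTING: 2}
        tables = _tables()
        for fpg in (90.0, 126.0, 200.0, 320.0):
            last = {AidName.AID1: -1, AidName.AID2: -1}
            for ppg_value in np.linspace(fpg - 30, fpg + 250, 200):
                for aid, index in ((AidName.AID1, ppge(mg(fpg), mg(ppg_value))),
                                   (AidName.AID2, pfi(mg(fpg), mg(ppg_value)))):
                    rank = ladder[classify(index, tables[aid]).choice1]
                    assert rank >= last[aid]
                    last[aid] = rank


class TestSequentialAg:
    def test_above_target_normal_ag_targets_basal(self):
        result = sequential_ag_assessment(HbA1cValue(8.5), AnhydroglucitolValue(14),
                                          a1c_target=7.0, ag_low_threshold=10.0)
        assert result.regimen is Regimen.BASAL_TARGETING
        assert not result.controlled

    def test_above_target_low_ag_targets_prandial_prefers_5050(self):
        result = sequential_ag_assessment(HbA1cValue(8.5), AnhydroglucitolValue(4),
                                          a1c_target=7.0, ag_low_threshold=10.0)
        assert result.regimen is Regimen.PRANDIAL_TARGETING
        assert any("50:50" in n for n in result.notes)

    def test_at_or_below_target_no_recommendation(self):
        result = sequential_ag_assessment(HbA1cValue(6.5), AnhydroglucitolValue(4),
                                          a1c_target=7.0, ag_low_threshold=10.0)
        assert result.regimen is None and result.controlled

    def test_controlled_window_annotated(self):
        result = sequential_ag_assessment(HbA1cValue(7.5), AnhydroglucitolValue(14),
                                          a1c_target=7.0, ag_low_threshold=10.0)
        assert any("6.5-8" in n for n in result.notes)

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValidationError):
            sequential_ag_assessment(None, AnhydroglucitolValue(4), 7.0)
        with pytest.raises(ValidationError):
            sequential_ag_assessment(HbA1cValue(8.0), None, 7.0)


class TestTiming:
    def test_highest_peak_meal(self):
        prof = GlycemicProfile("p", mg(120), [
            PpgReading(MealTag.BREAKFAST, mg(180)),
            PpgReading(MealTag.LUNCH, mg(240)),
            PpgReading(MealTag.DINNER, mg(210)),
        ])
        assert timing_recommendation(prof) is MealTag.LUNCH

    def test_singleton(self):
        prof = GlycemicProfile("p", mg(120), [PpgReading(MealTag.DINNER, mg(300))])
        assert timing_recommendation(prof) is MealTag.DINNER

    def test_tie_breaks_breakfast_first(self):
        prof = GlycemicProfile("p", mg(120), [
            PpgReading(MealTag.DINNER, mg(200)),
            PpgReading(MealTag.BREAKFAST, mg(200)),
        ])
        assert timing_recommendation(prof) is MealTag.BREAKFAST

    def test_no_readings_absent(self):
        assert timing_recommendation(GlycemicProfile("p", mg(120))) is None


class TestAssess:
    def test_fpg_ppg_only_two_aids(self):
        prof = GlycemicProfile("p", mg(200), [PpgReading(MealTag.LUNCH, mg(300))])
        s = assess(prof)
        assert set(s.per_aid) == {AidName.AID1, AidName.AID2}
        assert s.per_aid[AidName.AID1].choice1 is Regimen.RAPID_ACTING  # PPGE 100
        assert s.per_aid[AidName.AID2].choice1 is Regimen.PREMIXED_30_70  # PFI 0.5
        assert s.agreement is Agreement.DISCORDANT
        assert s.n_applicable == 2

    def test_fpg_hba1c_only_is_single(self):
        prof = GlycemicProfile("p", GlucoseValue(7.8, Unit.MMOL_L), hba1c=HbA1cValue(6.0))
        s = assess(prof, EngineConfig(aid3_scale=RatioScale.MMOL_SCALE))
        assert set(s.per_aid) == {AidName.AID3}
        assert s.agreement is Agreement.SINGLE
        assert s.per_aid[AidName.AID3].choice1 is Regimen.BASAL  # exactly at 1.3

    def test_no_inputs_errors_naming_minimum(self):
        with pytest.raises(InsufficientDataError, match="FPG"):
            assess(GlycemicProfile("p", hba1c=HbA1cValue(9.0)))

    def test_full_agreement_when_all_point_basal(self):
        prof = GlycemicProfile("p", mg(260), [PpgReading(MealTag.DINNER, mg(280))],
                               hba1c=HbA1cValue(9.0))
        s = assess(prof)  # PPGE 20, PFI 0.077, ratio 28.9
        assert all(r.choice1 is Regimen.BASAL for r in s.per_aid.values())
        assert s.agreement is Agreement.FULL

    def test_partial_when_strict_subset_shares_choice1(self):
        prof = GlycemicProfile("p", mg(110), [PpgReading(MealTag.LUNCH, mg(250))],
                               hba1c=HbA1cValue(8.0))
        s = assess(prof)  # AID1 & AID2 rapid acting; AID3 ratio 13.75 premixed
        choice1 = [r.choice1 for r in s.per_aid.values()]
        assert choice1.count(Regimen.RAPID_ACTING) == 2
        assert s.agreement is Agreement.PARTIAL

    def test_unit_invariant_classification(self):
        """The same patient expressed in mmol/l classifies identically."""
        prof_mg = GlycemicProfile("p", mg(126), [PpgReading(MealTag.LUNCH, mg(200))],
                                  hba1c=HbA1cValue(6.3))
        prof_mmol = GlycemicProfile("p", GlucoseValue(7.0, Unit.MMOL_L), [
            PpgReading(MealTag.LUNCH, GlucoseValue(200 / 18.0, Unit.MMOL_L))],
            hba1c=HbA1cValue(6.3))
        s_mg = assess(prof_mg)
        s_mmol = assess(prof_mmol, EngineConfig(working_unit=Unit.MMOL_L))
        assert {a: r.choice1 for a, r in s_mg.per_aid.items()} == \
               {a: r.choice1 for a, r in s_mmol.per_aid.items()}

    def test_cross_scale_disagreement_surfaced(self):
        # FPG 200 / HbA1c 9: mg ratio 22.2 >= 20 but mmol ratio 1.23 < 1.3
        prof = GlycemicProfile("p", mg(200), [PpgReading(MealTag.LUNCH, mg(230))],
                               hba1c=HbA1cValue(9.0))
        s = assess(prof)
        assert any("scale disagreement" in n for n in s.notes)

    def test_hba1c_severity_note_without_altering_outputs(self):
        prof = GlycemicProfile("p", mg(200), [PpgReading(MealTag.LUNCH, mg(300))],
                               hba1c=HbA1cValue(11.5))
        s = assess(prof)
        assert any("11.5" in n for n in s.notes)
        assert s.per_aid[AidName.AID1].choice1 is Regimen.RAPID_ACTING

    def test_sequential_skipped_without_thresholds(self):
        prof = GlycemicProfile("p", mg(200), [PpgReading(MealTag.LUNCH, mg(300))],
                               hba1c=HbA1cValue(9.0), ag=AnhydroglucitolValue(4))
        s = assess(prof)
        assert s.sequential_ag is None
        assert any("sequential assessment skipped" in n for n in s.notes)

    def test_sequential_runs_with_thresholds(self):
        cfg = EngineConfig(a1c_target=7.0, ag_low_threshold=10.0)
        prof = GlycemicProfile("p", mg(200), [PpgReading(MealTag.LUNCH, mg(300))],
                               hba1c=HbA1cValue(9.0), ag=AnhydroglucitolValue(4))
        s = assess(prof, cfg)
        assert s.sequential_ag.regimen is Regimen.PRANDIAL_TARGETING
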