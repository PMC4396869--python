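import pytest

from insulaid import (
    EngineConfig,
    GlucoseValue,
    GlycemicProfile,
    HbA1cValue,
    MealTag,
    PpgReading,
    Unit,
)


@pytest.fixture
def config():
    return EngineConfig()


@pytest.fixture
def three_meal_profile():
    """FPG 150 with breakfast/lunch/dinner readings peaking at lunch."""
    return GlycemicProfile(
        patient_id="p-three-meals",
        fpg=GlucoseValue(150, Unit.MG_DL),
        ppg_readings=[
            PpgReading(MealTag.BREAKFAST, GlucoseValue(180, Unit.MG_DL), 1.5),
            PpgReading(MealTag.LUNCH, GlucoseValue(240, Unit.MG_DL), 2.0),
            PpgReading(MealTag.DINNER, GlucoseValue(210, Unit.MG_DL), 1.0),
        ],
        hba1c=HbA1cValue(8.2),
    )


@pytest.fixture
def cohort_csv(tmp_path):
    """A small well-formed SMBG cohort file with two patients."""
    text = (
        "patient_id,measurement_type,meal_tag,value,unit,hours_post_meal,date\n"
        "p01,FASTING,,200,mg/dl,,2024-01-05\n"
        "p01,POSTPRANDIAL,LUNCH,300,mg/dl,1.5,2024-01-05\n"
        "p01,HBA1C,,9.1,%,,\n"
        "p02,FASTING,,7.8,mmol/l,,\n"
        "p02,HBA1C,,6.0,%,,\n"
    )
    path = tmp_path / "cohort.csv"
    path.write_text(text)
    return path
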