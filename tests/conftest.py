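import pytest

from ddxbench import DiseaseLexicon, Vignette


@pytest.fixture
def lexicon() -> DiseaseLexicon:
    """Small cardiology-flavoured lexicon exercising all three relations."""
    return DiseaseLexicon.from_dict(
        {
            "myocardial infarction": {
                "synonyms": ["heart attack", "MI"],
                "related": ["unstable angina"],
            },
            "acute coronary syndrome": {
                "umbrella_of": ["myocardial infarction", "unstable angina"],
            },
            "gastroesophageal reflux disease": {"synonyms": ["GERD", "acid reflux"]},
        }
    )


@pytest.fixture
def make_vignette():
    """Factory for minimal valid vignettes; override any field by keyword."""

    def _make(vid: str = "v1", **overrides) -> Vignette:
        base = dict(
            id=vid,
            age=55,
            sex="male",
            chief_complaints=["chest pain"],
            body_system="cardiovascular",
            commonness="common",
            gold_main="myocardial infarction",
            gold_differential=["unstable angina", "pericarditis"],
            status="gold",
        )
        base.update(overrides)
        return Vignette(**base)

    return _make


@pytest.fixture
def tiny_suite(make_vignette):
    return [
        make_vignette("v1"),
        make_vignette(
            "v2",
            body_system="respiratory",
            gold_main="pneumonia",
            gold_differential=["acute bronchitis"],
            chief_complaints=["cough", "fever"],
            commonness="less_common",
        ),
        make_vignette(
            "v3",
            body_system="gastrointestinal",
            gold_main="gastroesophageal reflux disease",
            gold_differential=[],
            chief_complaints=["heartburn"],
            age=40,
            sex="female",
        ),
    ]
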