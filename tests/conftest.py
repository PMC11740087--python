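import pytest

from snpmeta import GenotypeCounts, StudyRecord


def make_record(study_id="s1", polymorphism="-251", ethnicity="Asian",
                cancer_type="Gastric cancer", source_of_control="HB",
                cases=(10, 20, 30), controls=(5, 25, 40)):
    return StudyRecord(
        study_id=study_id, author="Doe", year=2015, country="China",
        ethnicity=ethnicity, cancer_type=cancer_type,
        source_of_control=source_of_control, genotyping_method="PCR-RFLP",
        polymorphism=polymorphism,
        cases=GenotypeCounts(*cases), controls=GenotypeCounts(*controls))


@pytest.fixture
def records():
    """Five studies: three -251 Asian, one -251 Caucasian, one +678."""
    return [
        make_record("s1"),
        make_record("s2", cases=(8, 30, 22), controls=(9, 28, 23)),
        make_record("s3", cases=(12, 40, 48), controls=(14, 44, 42)),
        make_record("s4", ethnicity="Caucasian", source_of_control="PB"),
        make_record("s5", polymorphism="+678"),
    ]
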