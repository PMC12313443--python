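import pytest

from gutweb.design import DesignSpec, DetectionRecord, WebUnitKey


@pytest.fixture
def tiny_design():
    """Two predator species, three prey targets, one field/treatment/plot."""
    return DesignSpec(
        years=["2020"],
        fields_per_year=1,
        treatments=["fertilized"],
        plots_per_treatment=1,
        sessions_per_year={"2020": 2},
        predator_species=["Poecilus", "Araneae"],
        prey_targets=["Collembola", "Oligochaeta", "Poecilus"],
        self_detection_map={"Poecilus": "Poecilus"},
    )


@pytest.fixture
def small_design():
    """One-field, two-treatment, two-plot, three-session design with the full
    default species and prey panel — big enough for webs, small enough for
    repeated SES runs."""
    return DesignSpec(
        years=["2020"],
        fields_per_year=1,
        treatments=["fertilized", "unfertilized"],
        plots_per_treatment=2,
        sessions_per_year={"2020": 3},
    )


@pytest.fixture
def unit(tiny_design):
    return WebUnitKey("2020", "F1", "fertilized", "P1", 1)


def make_record(unit, species, positives, design):
    det = {t: (1 if t in positives else 0) for t in design.prey_targets}
    return DetectionRecord(unit, species, det)
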