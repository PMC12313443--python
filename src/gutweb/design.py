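"""Study-design data model and sampling-unit enumeration.

The sampling design is a nested factorial: in each year, a number of
replicate fields is split into treatment halves (e.g. manure-fertilized vs
unfertilized), each half holding a fixed number of plots that are visited
on a series of biweekly sessions.  The grain of every downstream quantity
(interaction web, specialization, diversity) is one plot at one session —
the *sampling unit* — identified by the full five-part key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "WebUnitKey",
    "DesignSpec",
    "DetectionRecord",
    "CommunitySample",
    "enumerate_units",
    "barley_design",
    "DEFAULT_PREY_TARGETS",
    "DEFAULT_PREDATOR_SPECIES",
    "DEFAULT_SELF_DETECTION_MAP",
]


@dataclass(frozen=True, order=True)
class WebUnitKey:
    """Identity of one sampling unit: plot × treatment × field × session × year."""

    year: str
    field: str
    treatment: str
    plot: str
    session: int

    def __str__(self) -> str:
        return f"{self.year}/{self.field}/{self.treatment}/{self.plot}/s{self.session}"


# Prey panel assembled from the three multiplex assays: field-crop prey taxa
# (aphids, cereal leaf beetle, springtails, earthworms, gastropods), intraguild
# prey (spiders, ladybeetles) and the common carabid/staphylinid taxa.
DEFAULT_PREY_TARGETS: tuple[str, ...] = (
    "Metopolophium_dirhodum",
    "Rhopalosiphum_padi",
    "Sitobion_avenae",
    "Oulema_melanopus",
    "Collembola",
    "Oligochaeta",
    "Gastropoda",
    "Araneae",
    "Coccinellidae",
    "Bembidion",
    "Harpalus",
    "Poecilus",
    "Pterostichus",
    "Philonthus_carbonarius",
    "Philonthus_cognatus",
)

DEFAULT_PREDATOR_SPECIES: tuple[str, ...] = (
    "Bembidion",
    "Harpalus",
    "Poecilus",
    "Pterostichus",
    "Philonthus_carbonarius",
    "Philonthus_cognatus",
    "Araneae",
)

# A predator testing positive for its own taxon's primer is a self-detection
# and is removed before webs are built.
DEFAULT_SELF_DETECTION_MAP: dict[str, str] = {
    "Bembidion": "Bembidion",
    "Harpalus": "Harpalus",
    "Poecilus": "Poecilus",
    "Pterostichus": "Pterostichus",
    "Philonthus_carbonarius": "Philonthus_carbonarius",
    "Philonthus_cognatus": "Philonthus_cognatus",
    "Araneae": "Araneae",
}


@dataclass
class DesignSpec:
    """Declarative description of the sampling design and assay panel.

    Parameters
    ----------
    years
        Year labels, e.g. ``["2020", "2021"]``.
    fields_per_year
        Number of replicate fields sampled in each year.
    treatments
        Ordered treatment labels applied to the two field halves.
    plots_per_treatment
        Number of plots delimited per treatment half.
    sessions_per_year
        Mapping year label -> number of biweekly sampling sessions.
    predator_species
        Labels of the predator taxa whose gut contents are assayed.
    prey_targets
        Labels of the prey assay targets (one binary detection column each).
    self_detection_map
        Mapping predator species -> the prey target that constitutes a
        self-detection for that species (species may be absent).
    """

    years: list[str]
    fields_per_year: int = 3
    treatments: list[str] = field(default_factory=lambda: ["fertilized", "unfertilized"])
    plots_per_treatment: int = 4
    sessions_per_year: dict[str, int] = field(default_factory=dict)
    predator_species: list[str] = field(default_factory=lambda: list(DEFAULT_PREDATOR_SPECIES))
    prey_targets: list[str] = field(default_factory=lambda: list(DEFAULT_PREY_TARGETS))
    self_detection_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SELF_DETECTION_MAP)
    )

    def __post_init__(self) -> None:
        if self.fields_per_year < 1 or self.plots_per_treatment < 1:
            raise ValueError("fields_per_year and plots_per_treatment must be >= 1")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatment labels must be distinct")
        if not self.treatments:
            raise ValueError("at least one treatment is required")
        for year in self.years:
            n = self.sessions_per_year.get(year)
            if n is None or n < 1:
                raise ValueError(f"sessions_per_year must give a count >= 1 for year {year!r}")
        targets = set(self.prey_targets)
        for sp, tgt in self.self_detection_map.items():
            if tgt not in targets:
                raise ValueError(
                    f"self-detection target {tgt!r} for species {sp!r} is not a prey target"
                )
        # drop self-map entries for species not in the panel silently: a map
        # shared between years may mention species absent from one year
        self.self_detection_map = {
            sp: tgt for sp, tgt in self.self_detection_map.items() if sp in self.predator_species
        }

    def field_labels(self, year: str) -> list[str]:
        return [f"F{i}" for i in range(1, self.fields_per_year + 1)]

    def plot_labels(self) -> list[str]:
        return [f"P{i}" for i in range(1, self.plots_per_treatment + 1)]

    def sessions(self, year: str) -> list[int]:
        if year not in self.sessions_per_year:
            raise KeyError(f"unknown year: {year!r}")
        return list(range(1, self.sessions_per_year[year] + 1))


@dataclass
class DetectionRecord:
    """One captured predator individual with its binary prey-detection vector."""

    unit: WebUnitKey
    predator_species: str
    detections: dict[str, int]

    def validate(self, design: DesignSpec) -> None:
        if self.predator_species not in design.predator_species:
            raise ValueError(f"unknown predator species {self.predator_species!r}")
        if set(self.detections) != set(design.prey_targets):
            missing = set(design.prey_targets) - set(self.detections)
            extra = set(self.detections) - set(design.prey_targets)
            raise ValueError(f"detection vector mismatch (missing {missing}, extra {extra})")
        for tgt, v in self.detections.items():
            if v not in (0, 1):
                raise ValueError(f"non-binary detection value {v!r} for target {tgt!r}")


@dataclass
class CommunitySample:
    """Per-unit community counts: wet pitfall-trap catches plus aphid tiller counts."""

    unit: WebUnitKey
    pitfall_counts: dict[str, int]
    tiller_aphid_counts: dict[str, int]

    def validate(self, known_aphids: Sequence[str] | None = None) -> None:
        for taxon, c in {**self.pitfall_counts, **self.tiller_aphid_counts}.items():
            if c < 0:
                raise ValueError(f"negative count {c} for taxon {taxon!r} at unit {self.unit}")
        if known_aphids is not None:
            unknown = set(self.tiller_aphid_counts) - set(known_aphids)
            if unknown:
                raise ValueError(f"tiller counts for non-aphid taxa {sorted(unknown)}")


def enumerate_units(design: DesignSpec, year: str) -> list[WebUnitKey]:
    """All sampling units of one year, in lexicographic (field, treatment, plot,
    session) order.

    The length is the full factorial product
    ``fields_per_year * len(treatments) * plots_per_treatment * sessions``.
    """
    if year not in design.years or year not in design.sessions_per_year:
        raise KeyError(f"unknown year: {year!r}")
    units = []
    for fld in design.field_labels(year):
        for trt in design.treatments:
            for plot in design.plot_labels():
                for sess in design.sessions(year):
                    units.append(WebUnitKey(year, fld, trt, plot, sess))
    return units


def barley_design() -> DesignSpec:
    """The two-year barley-field design: 3 fields per year, 2 treatment halves,
    4 plots per half, 7 sessions in the first year and 6 in the second."""
    return DesignSpec(
        years=["2020", "2021"],
        fields_per_year=3,
        treatments=["fertilized", "unfertilized"],
        plots_per_treatment=4,
        sessions_per_year={"2020": 7, "2021": 6},
    )
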