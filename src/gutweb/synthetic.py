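"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the two-year barley study design: replicate fields
split into fertilized/unfertilized halves, plots sampled on biweekly
sessions, individual predators with binary multi-target gut-content
detections, and per-unit community counts from pitfall traps and tiller
collections.

The generative model is Dirichlet-multinomial.  Each predator species
holds, per session and treatment, a diet-preference vector drawn from a
Dirichlet distribution whose concentration κ(session) is the specialization
dial: small κ concentrates a species' diet on few prey (specialized webs,
high H2'), large κ makes every diet track the shared availability weights
(generalized webs, H2' near 0).  The default κ profile is U-shaped over the
season — concentrated early and late, even at mid-season — so the
downstream pipeline should recover low–high–low generalization, i.e. the
seasonal specialization valley, from generated data.

Capture counts are Poisson per species × unit; community counts are
negative-binomial around seasonal mean profiles to emulate pitfall
overdispersion.  The whole dataset is a pure function of the parameter set,
including its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .design import CommunitySample, DesignSpec, DetectionRecord, WebUnitKey, barley_design, enumerate_units

__all__ = [
    "SyntheticParams",
    "simulate_species_preferences",
    "simulate_detections",
    "simulate_community",
    "DEFAULT_PREY_TAXA",
    "DEFAULT_APHID_TAXA",
    "DEFAULT_PREDATOR_TAXA",
    "DEFAULT_DETRITIVORE_TARGETS",
]

# Community taxon lists used for diversity: prey groups known to be consumed
# by the beetle and spider predators, with aphids counted on tillers.
DEFAULT_APHID_TAXA: tuple[str, ...] = (
    "Metopolophium_dirhodum",
    "Rhopalosiphum_padi",
    "Sitobion_avenae",
)
DEFAULT_PREY_TAXA: tuple[str, ...] = (
    "Collembola",
    "Oligochaeta",
    "Gastropoda",
    "Oulema_melanopus",
) + DEFAULT_APHID_TAXA
DEFAULT_PREDATOR_TAXA: tuple[str, ...] = (
    "Bembidion",
    "Harpalus",
    "Poecilus",
    "Pterostichus",
    "Philonthus_carbonarius",
    "Philonthus_cognatus",
    "Araneae",
)
DEFAULT_DETRITIVORE_TARGETS: tuple[str, ...] = ("Collembola", "Oligochaeta")

# Mid-season hump used for the default community abundance profiles: primary
# production, and with it prey activity-density, peaks during stem elongation.
_SEASONAL_HUMP = {1: 0.5, 2: 1.0, 3: 1.6, 4: 2.0, 5: 1.6, 6: 1.0, 7: 0.5}

# U-shaped specialization profile: diets concentrated (small κ) early and
# late in the season, even (large κ) at mid-season.
DEFAULT_KAPPA_BY_SESSION = {1: 0.1, 2: 0.3, 3: 1.0, 4: 3.0, 5: 1.0, 6: 0.3, 7: 0.1}


def _default_community_profile() -> dict[str, dict[int, float]]:
    profile: dict[str, dict[int, float]] = {}
    for taxon in ("Collembola", "Oligochaeta"):
        profile[taxon] = {s: 10.0 * h for s, h in _SEASONAL_HUMP.items()}
    for taxon in ("Gastropoda", "Oulema_melanopus"):
        profile[taxon] = {s: 3.0 * h for s, h in _SEASONAL_HUMP.items()}
    for taxon in DEFAULT_APHID_TAXA:
        profile[taxon] = {s: 2.0 * h for s, h in _SEASONAL_HUMP.items()}
    for taxon in DEFAULT_PREDATOR_TAXA:
        profile[taxon] = 5.0  # predator activity-density roughly flat
    return profile


def _default_tiller_profile() -> dict[str, dict[int, float]]:
    # aphid counts summed over 30 collected tillers; builds up over the season
    return {taxon: {s: 15.0 * h for s, h in _SEASONAL_HUMP.items()} for taxon in DEFAULT_APHID_TAXA}


@dataclass
class SyntheticParams:
    """Parameters of the synthetic study.

    The defaults are the study conditions: the two-year 3-field × 2-treatment
    × 4-plot design with 7/6 sessions, a U-shaped seasonal concentration
    profile, and mid-season-peaking community abundances.
    """

    design: DesignSpec = field(default_factory=barley_design)
    individuals_per_species_per_unit: float = 3.0
    preference_concentration_by_session: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_KAPPA_BY_SESSION)
    )
    base_prey_availability: dict[str, float] | None = None
    detections_per_individual: float = 2.0
    treatment_availability_multiplier: dict[str, float] = field(
        default_factory=lambda: {"fertilized": 1.5, "unfertilized": 1.0}
    )
    detritivore_targets: tuple[str, ...] = DEFAULT_DETRITIVORE_TARGETS
    community_abundance_profile: dict[str, float | dict[int, float]] = field(
        default_factory=_default_community_profile
    )
    tiller_aphid_profile: dict[str, float | dict[int, float]] = field(
        default_factory=_default_tiller_profile
    )
    community_dispersion: float = 2.0
    shared_preferences: bool = False  # all species share one preference vector
    inject_self_detections: bool = False  # emit self-detections to exercise the cleaner
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_prey_availability is None:
            self.base_prey_availability = {t: 1.0 for t in self.design.prey_targets}
        for s, k in self.preference_concentration_by_session.items():
            if k <= 0:
                raise ValueError(f"concentration for session {s} must be > 0, got {k}")
        for t, w in self.base_prey_availability.items():
            if w <= 0:
                raise ValueError(f"availability weight for {t!r} must be > 0, got {w}")
        if self.individuals_per_species_per_unit < 0 or self.detections_per_individual < 0:
            raise ValueError("means must be >= 0")
        if self.community_dispersion <= 0:
            raise ValueError("community_dispersion must be > 0")

    def kappa(self, session: int) -> float:
        try:
            return self.preference_concentration_by_session[session]
        except KeyError:
            raise KeyError(f"no preference concentration declared for session {session}") from None


def _keyed_rng(seed: int, *key) -> np.random.Generator:
    h = zlib.crc32("|".join(str(k) for k in key).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, h]))


def _availability(params: SyntheticParams, treatment: str | None) -> np.ndarray:
    w = np.array([params.base_prey_availability[t] for t in params.design.prey_targets])
    if treatment is not None:
        mult = params.treatment_availability_multiplier.get(treatment, 1.0)
        detr = np.array([t in params.detritivore_targets for t in params.design.prey_targets])
        w = np.where(detr, w * mult, w)
    return w / w.sum()


def simulate_species_preferences(
    params: SyntheticParams,
    species: str,
    session: int,
    treatment: str | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Diet-preference probability vector of one species at one session.

    Drawn from Dirichlet(κ(session) · availability), where availability is the
    normalized base prey weighting with the treatment multiplier applied to
    detritivore targets.  Without an explicit ``rng`` the draw is a
    deterministic function of (seed, species, session, treatment), so every
    unit of the same treatment sees the same species-level preference — the
    association that the null model is meant to detect.  With
    ``shared_preferences`` the species label is ignored and all species share
    one vector (no true predator × prey association).
    """
    kappa = params.kappa(session)
    if params.shared_preferences:
        # one vector for the whole dataset: no predator × prey association and
        # full exchangeability of diet data points within any shuffling stratum
        weights = _availability(params, None)
        alpha = params.kappa(1) * weights
        if rng is None:
            rng = _keyed_rng(params.seed, "pref", "shared")
    else:
        weights = _availability(params, treatment)
        alpha = kappa * weights
        if rng is None:
            rng = _keyed_rng(params.seed, "pref", species, session, treatment or "")
    # numpy's dirichlet underflows for very small alpha; use the Gamma
    # representation with log-draws for stability
    g = rng.standard_gamma(alpha)
    if g.sum() == 0:
        p = np.zeros_like(g)
        p[int(rng.integers(len(g)))] = 1.0
        return p
    return g / g.sum()


def simulate_detections(params: SyntheticParams) -> list[DetectionRecord]:
    """Individual-level detection records for the whole design.

    Per unit and species the number of captured individuals is Poisson; each
    individual's positive targets come from a multinomial draw (Poisson
    number of prey data points) over the species × session × treatment
    preference vector, collapsed to binary presence.  Self-detection targets
    are zeroed at generation time (the generator models post-cleaning data)
    unless ``inject_self_detections`` is set.
    """
    design = params.design
    targets = list(design.prey_targets)
    records: list[DetectionRecord] = []
    for year in design.years:
        for unit in enumerate_units(design, year):
            rng = _keyed_rng(params.seed, "det", unit)
            for species in design.predator_species:
                n = int(rng.poisson(params.individuals_per_species_per_unit))
                if n == 0:
                    continue
                p = simulate_species_preferences(params, species, unit.session, unit.treatment)
                self_target = design.self_detection_map.get(species)
                for _ in range(n):
                    k = int(rng.poisson(params.detections_per_individual))
                    counts = rng.multinomial(k, p) if k > 0 else np.zeros(len(p), dtype=int)
                    det = {t: int(c > 0) for t, c in zip(targets, counts)}
                    if not params.inject_self_detections and self_target is not None:
                        det[self_target] = 0
                    records.append(DetectionRecord(unit, species, det))
    return records


def _mean_at(entry: float | Mapping[int, float], session: int) -> float:
    if isinstance(entry, Mapping):
        return float(entry.get(session, 0.0))
    return float(entry)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_community(params: SyntheticParams) -> list[CommunitySample]:
    """Per-unit pitfall and tiller count tables.

    Counts are negative-binomial around the seasonal mean profile (taxon ->
    scalar or session -> mean); detritivore taxa get the treatment
    availability multiplier, emulating the manure effect on decomposer
    abundance.  Aphid tiller counts are generated separately from the
    pitfall catches.
    """
    design = params.design
    samples: list[CommunitySample] = []
    for year in design.years:
        for unit in enumerate_units(design, year):
            rng = _keyed_rng(params.seed, "comm", unit)
            mult = params.treatment_availability_multiplier.get(unit.treatment, 1.0)
            pitfall = {}
            for taxon in params.community_abundance_profile:
                mean = _mean_at(params.community_abundance_profile[taxon], unit.session)
                if taxon in params.detritivore_targets:
                    mean *= mult
                pitfall[taxon] = _nb_draw(rng, mean, params.community_dispersion)
            tillers = {}
            for taxon in params.tiller_aphid_profile:
                mean = _mean_at(params.tiller_aphid_profile[taxon], unit.session)
                tillers[taxon] = _nb_draw(rng, mean, params.community_dispersion)
            samples.append(CommunitySample(unit, pitfall, tillers))
    return samples
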