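# Example configuration: the two-year barley-field study design.
# Any key under `synthetic` is passed to SyntheticParams; `community` holds
# the taxon lists used for the diversity calculations.
design:
  years: ["2020", "2021"]
  fields_per_year: 3
  treatments: [fertilized, unfertilized]
  plots_per_treatment: 4
  sessions_per_year: {"2020": 7, "2021": 6}
  predator_species:
    - Bembidion
    - Harpalus
    - Poecilus
    - Pterostichus
    - Philonthus_carbonarius
    - Philonthus_cognatus
    - Araneae
  prey_targets:
    - Metopolophium_dirhodum
    - Rhopalosiphum_padi
    - Sitobion_avenae
    - Oulema_melanopus
    - Collembola
    - Oligochaeta
    - Gastropoda
    - Araneae
    - Coccinellidae
    - Bembidion
    - Harpalus
    - Poecilus
    - Pterostichus
    - Philonthus_carbonarius
    - Philonthus_cognatus
  self_detection_map:
    Bembidion: Bembidion
    Harpalus: Harpalus
    Poecilus: Poecilus
    Pterostichus: Pterostichus
    Philonthus_carbonarius: Philonthus_carbonarius
    Philonthus_cognatus: Philonthus_cognatus
    Araneae: Araneae

synthetic:
  individuals_per_species_per_unit: 3.0
  detections_per_individual: 2.0
  # seasonal specialization dial: small = concentrated diets
  preference_concentration_by_session: {1: 0.1, 2: 0.3, 3: 1.0, 4: 3.0, 5: 1.0, 6: 0.3, 7: 0.1}
  treatment_availability_multiplier: {fertilized: 1.5, unfertilized: 1.0}

community:
  predator_taxa:
    - Bembidion
    - Harpalus
    - Poecilus
    - Pterostichus
    - Philonthus_carbonarius
    - Philonthus_cognatus
    - Araneae
  prey_taxa:
    - Collembola
    - Oligochaeta
    - Gastropoda
    - Oulema_melanopus
    - Metopolophium_dirhodum
    - Rhopalosiphum_padi
    - Sitobion_avenae
  aphid_taxa:
    - Metopolophium_dirhodum
    - Rhopalosiphum_padi
    - Sitobion_avenae
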