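"""Desk-scale study presets.

The full study design (three hospital systems, engineered five-cohort
relative-risk ladder, site detection with a CAM audit) is expensive at the
sizes a GPU cluster would use; these presets fix the problem sizes the
package uses for its own replication runs on a single CPU: a few hundred
patients per site, 64 x 64 images, five replicate seeds. The prevalence
regimes, confound geometry, disease effect size and training schedule are
the study conditions; only the cohort sizes are scaled down.
"""

from __future__ import annotations

from .cohorts import standard_specs
from .modeling import TrainSchedule
from .synthetic import GeneratorConfig, SiteProfile, TokenSpec
from .experiments import (
    ExperimentConfig,
    audit_profiles,
    default_profiles,
    engineered_pool_profiles,
)

REPLICATE_SEEDS = (0, 1, 2, 3, 4)

#: cohort size per site for engineered-prevalence runs (paper-scale: 10,000)
ENGINEERED_COHORT_PATIENTS = 300


def engineered_config(seed: int, confounds: bool = True) -> ExperimentConfig:
    """Pool + schedule for the engineered relative-risk study.

    Source pools of 600 patients per internal site at 10% prevalence keep
    every standard design (up to 9.9% patient-level positives, sex-
    balanced) feasible after subsampling to 300 patients per site.
    """
    return ExperimentConfig(
        profiles=engineered_pool_profiles(confounds=confounds),
        generator=GeneratorConfig(
            patients_per_site={"site_a": 600, "site_b": 600, "site_c": 250},
            seed=seed,
        ),
        schedule=TrainSchedule(max_epochs=20, seed=seed),
        cohort_patients_per_site=ENGINEERED_COHORT_PATIENTS,
    )


def engineered_specs(names=("balanced", "a_severe")):
    """Subset of the five standard designs used in replicate runs."""
    specs = standard_specs("site_a", "site_b", ENGINEERED_COHORT_PATIENTS)
    return [s for s in specs if s.name in names]


def generalization_config(seed: int) -> ExperimentConfig:
    """Natural-prevalence three-site study.

    Site sizes follow the real systems' proportions (the low-prevalence
    site is by far the largest), scaled so the rare-disease site still
    yields evaluable test positives.
    """
    return ExperimentConfig(
        generator=GeneratorConfig(
            patients_per_site={"site_a": 120, "site_b": 600, "site_c": 150},
            seed=seed,
        ),
        schedule=TrainSchedule(max_epochs=20, seed=seed),
    )


def detection_config(seed: int, confounds: bool = True) -> ExperimentConfig:
    """Site-detection / CAM-audit study.

    With confounds off, the null design uses equal prevalence everywhere so
    disease burden cannot stand in for the site; accuracy should then sit
    at the majority-class rate.
    """
    if confounds:
        profiles = audit_profiles()
    else:
        profiles = default_profiles(confounds=False, prevalences=(0.05, 0.05, 0.05))
    return ExperimentConfig(
        profiles=profiles,
        generator=GeneratorConfig(patients_per_site=170, seed=seed),
        schedule=TrainSchedule(max_epochs=20, seed=seed),
    )


def localization_profiles() -> list[SiteProfile]:
    """Two sites whose images differ only by a corner token (no disease)."""
    return [
        SiteProfile(site_id="site_a", prevalence=0.0, token=TokenSpec("top_left", 6, 1.0)),
        SiteProfile(site_id="site_b", prevalence=0.0, token=TokenSpec("bottom_right", 6, 1.0)),
    ]


def localization_config(seed: int) -> ExperimentConfig:
    return ExperimentConfig(
        profiles=localization_profiles(),
        generator=GeneratorConfig(patients_per_site=60, seed=seed, effect_size=0.0),
        internal_sites=("site_a", "site_b"),
        external_site="site_b",
        schedule=TrainSchedule(max_epochs=12, seed=seed),
    )
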