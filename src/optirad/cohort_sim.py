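"""Synthetic patient/control cohorts of tract-averaged metrics.

Generates the long-format table the mixed-effects analysis consumes, with
known planted fixed effects so estimator recovery can be verified.  One row
per subject x timepoint x hemisphere x metric:

    value = intercept + beta_group * group + beta_timepoint * timepoint
            + beta_age * (age - AGE_CENTER) + beta_gender * gender
            + subject intercept + hemisphere deviation + residual

Hemisphere is encoded ipsi/contra for patients (relative to the operated
side) and left/right for controls.  Patients contribute baseline and
after-surgery rows; controls only baseline unless follow-up is requested.

Noise scales (``subject_sd``, ``hemisphere_sd``, ``residual_sd``) are
expressed as fractions of each metric's intercept so one setting is
meaningful across metrics whose natural scales span four orders of
magnitude (diffusivities in mm^2/s vs unitless anisotropies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "METRICS",
    "DEFAULT_INTERCEPTS",
    "DEFAULT_EFFECTS",
    "TABLE3_SIGN_PATTERN",
    "CohortSimSpec",
    "simulate_cohort_table",
    "strong_pattern_effects",
    "null_effects",
]

METRICS = ("MD", "AD", "RD", "FA", "muMD", "Long", "Trans", "muFA", "ODEntropy")

AGE_CENTER = 11.0  # years; cohort median age, effects are planted about it

#: Group-level metric values in the optic radiations of a paediatric cohort
#: (diffusivities in mm^2/s; FA/muFA/ODEntropy unitless).
DEFAULT_INTERCEPTS = {
    "MD": 7.94e-4,
    "AD": 1.23e-3,
    "RD": 5.81e-4,
    "FA": 0.432,
    "muMD": 1.07e-3,
    "Long": 2.68e-3,
    "Trans": 2.61e-4,
    "muFA": 0.886,
    "ODEntropy": 0.465,
}

#: Default planted fixed effects: magnitudes at the scale observed in
#: paediatric epilepsy cohorts, signs following the significant-change
#: summary (group: all diffusivities up, muFA down; timepoint: AD/FA/Long/
#: muFA/ODEntropy down, RD/Trans up); non-significant cells are zero.
DEFAULT_EFFECTS = {
    "MD": {"group": 3.01e-5, "timepoint": 0.0, "gender": 1.48e-5, "age": -5.29e-6},
    "AD": {"group": 4.13e-5, "timepoint": -3.95e-5, "gender": 2.40e-5, "age": -4.18e-6},
    "RD": {"group": 2.74e-5, "timepoint": 1.65e-5, "gender": 1.21e-5, "age": -5.92e-6},
    "FA": {"group": 0.0, "timepoint": -2.80e-2, "gender": 0.0, "age": 3.76e-3},
    "muMD": {"group": 3.98e-5, "timepoint": 0.0, "gender": 1.62e-5, "age": -6.04e-6},
    "Long": {"group": 7.96e-5, "timepoint": -4.12e-5, "gender": 3.38e-5, "age": -9.39e-6},
    "Trans": {"group": 1.97e-5, "timepoint": 1.03e-5, "gender": 9.82e-6, "age": -4.27e-6},
    "muFA": {"group": -4.86e-3, "timepoint": -6.58e-3, "gender": 0.0, "age": 1.66e-3},
    "ODEntropy": {"group": 0.0, "timepoint": -4.37e-2, "gender": 0.0, "age": 4.50e-3},
}

#: Direction of significant group/timepoint changes ('up'/'down'/None).
TABLE3_SIGN_PATTERN = {
    "MD": {"group": "up", "timepoint": None},
    "AD": {"group": "up", "timepoint": "down"},
    "RD": {"group": "up", "timepoint": "up"},
    "FA": {"group": None, "timepoint": "down"},
    "muMD": {"group": "up", "timepoint": None},
    "Long": {"group": "up", "timepoint": "down"},
    "Trans": {"group": "up", "timepoint": "up"},
    "muFA": {"group": "down", "timepoint": "down"},
    "ODEntropy": {"group": None, "timepoint": "down"},
}


def strong_pattern_effects(scale: float = 0.08) -> dict:
    """Planted effects following the significant-change sign pattern.

    Group and timepoint effects are set to ``sign * scale * intercept`` per
    metric (zero where the pattern has no significant change); age and
    gender keep their defaults.  Large enough relative to the default noise
    scales that the pattern is recovered with near certainty.
    """
    effects = {}
    sign = {"up": 1.0, "down": -1.0, None: 0.0}
    for metric in METRICS:
        eff = dict(DEFAULT_EFFECTS[metric])
        for contrast in ("group", "timepoint"):
            eff[contrast] = sign[TABLE3_SIGN_PATTERN[metric][contrast]] * scale * DEFAULT_INTERCEPTS[metric]
        effects[metric] = eff
    return effects


def null_effects() -> dict:
    """All fixed effects zero (for type-I error control checks)."""
    return {m: {"group": 0.0, "timepoint": 0.0, "gender": 0.0, "age": 0.0} for m in METRICS}


@dataclass
class CohortSimSpec:
    """Cohort composition, planted effects and noise scales."""

    n_patients: int = 43
    n_controls: int = 50
    effects: dict = field(default_factory=lambda: {m: dict(v) for m, v in DEFAULT_EFFECTS.items()})
    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    subject_sd: float = 0.03  # fraction of metric intercept
    hemisphere_sd: float = 0.01
    residual_sd: float = 0.02
    male_fraction_patients: float = 22.0 / 43.0
    male_fraction_controls: float = 30.0 / 50.0
    age_range: tuple[float, float] = (5.0, 19.0)
    controls_followup: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        for sd in (self.subject_sd, self.hemisphere_sd, self.residual_sd):
            if sd < 0:
                raise ValueError("noise scales must be non-negative")
        missing = [m for m in METRICS if m not in self.effects or m not in self.intercepts]
        if missing:
            raise ValueError(f"effects/intercepts missing metrics: {missing}")


def simulate_cohort_table(spec: CohortSimSpec) -> pd.DataFrame:
    """Long-format metric table with planted ground truth; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    subjects = [("patient", f"P{i:03d}") for i in range(spec.n_patients)] + [
        ("control", f"C{i:03d}") for i in range(spec.n_controls)
    ]
    for group, sid in subjects:
        is_patient = group == "patient"
        male_frac = spec.male_fraction_patients if is_patient else spec.male_fraction_controls
        age = rng.uniform(*spec.age_range)
        gender = "M" if rng.uniform() < male_frac else "F"
        timepoints = ["baseline", "after_surgery"] if (is_patient or spec.controls_followup) else ["baseline"]
        hemispheres = ["ipsi", "contra"] if is_patient else ["left", "right"]
        subj_z = {m: rng.normal() for m in METRICS}
        hemi_z = {(m, h): rng.normal() for m in METRICS for h in hemispheres}
        for tp in timepoints:
            for hemi in hemispheres:
                for metric in METRICS:
                    scale = spec.intercepts[metric]
                    eff = spec.effects[metric]
                    value = (
                        scale
                        + eff["group"] * (1.0 if is_patient else 0.0)
                        + eff["timepoint"] * (1.0 if tp == "after_surgery" else 0.0)
                        + eff["age"] * (age - AGE_CENTER)
                        + eff["gender"] * (1.0 if gender == "M" else 0.0)
                        + spec.subject_sd * scale * subj_z[metric]
                        + spec.hemisphere_sd * scale * hemi_z[(metric, hemi)]
                        + spec.residual_sd * scale * rng.normal()
                    )
                    rows.append(
                        {
                            "subject": sid,
                            "group": group,
                            "timepoint": tp,
                            "hemisphere": hemi,
                            "age": age,
                            "gender": gender,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)
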