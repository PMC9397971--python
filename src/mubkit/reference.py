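"""Published reference values for chronic midportion Achilles tendinopathy.

Group means and standard deviations from a validation cohort of 41
adults with unilateral midportion Achilles tendinopathy (isometric
strength and LEFS available for a 20-participant subgroup).  They serve
two purposes: defaults for the cohort simulator, and inputs for the
worked Difference-Index / Hedge's-g examples.

All ultrasound values are triplicate-averaged per plane; thickness in
mm, echogenicity on the 8-bit 0–255 scale, homogeneity on 0–1.
"""

from __future__ import annotations

N_GROUP = 41
N_SUBGROUP = 20

#: (asymptomatic mean, asymptomatic SD, symptomatic mean, symptomatic SD)
SIDE_MEANS: dict[str, tuple[float, float, float, float]] = {
    "soleus_lunge_cm":            (11.6, 3.5, 10.8, 3.8),
    "gastroc_lunge_cm":           (70.6, 11.3, 68.5, 10.9),
    "plantarflexion_nm":          (139.0, 30.3, 133.9, 35.2),
    "dorsiflexion_nm":            (43.6, 10.6, 42.5, 10.5),
    "thickness_longitudinal_mm":  (5.15, 1.30, 6.69, 1.75),
    "echogenicity_longitudinal":  (77.0, 15.7, 69.6, 13.3),
    "homogeneity_longitudinal":   (0.595, 0.023, 0.618, 0.029),
    "thickness_transverse_mm":    (5.17, 1.13, 6.48, 1.78),
    "echogenicity_transverse":    (83.7, 15.4, 78.3, 14.6),
    "homogeneity_transverse":     (0.621, 0.025, 0.644, 0.032),
}

#: variables measured only in the strength subgroup (n = 20)
SUBGROUP_ONLY = ("plantarflexion_nm", "dorsiflexion_nm", "lefs")

#: (mean, SD, min, max) of the patient-reported measures
CLINICAL_MEANS: dict[str, tuple[float, float, float, float]] = {
    "visa_q1": (7.0, 3.2, 0, 10),   # stiffness
    "visa_q2": (6.6, 3.2, 0, 10),   # stretching
    "visa_q3": (7.4, 2.6, 0, 10),   # pain walking
    "visa_q4": (7.5, 2.7, 0, 10),   # pain stairs
    "visa_q5": (6.3, 2.9, 0, 10),   # pain heel raise
    "visa_q6": (4.4, 3.4, 0, 10),   # pain hopping
    "visa_q7": (5.8, 2.5, 0, 10),   # sports level
    "visa_q8": (15.6, 7.8, 0, 30),  # sport time
    "lefs":    (63.9, 10.6, 0, 80),
}

VISA_ITEMS = tuple(f"visa_q{k}" for k in range(1, 9))
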