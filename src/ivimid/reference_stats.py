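"""Published group-level summary statistics used as generator defaults.

These are the per-group means and standard deviations of the regional
IVIM features, demographics and sleep scores reported for a cohort of 42
insomnia-disorder (ID) patients and 42 normal controls (NC).  The
synthetic cohort generator treats them as the true marginal parameters
of each group.

Region abbreviations follow the AAL naming used in the source cohort:
DSFC = dorsolateral superior frontal cortex, HPC = hippocampus,
CA = anterior cingulate/paracingulate, PCC = posterior cingulate,
AMG = amygdala, FSF = fusiform, PCS = precuneus, CAD = caudate,
PTM = putamen, PLD = pallidum, TLM = thalamus; trailing L/R = hemisphere.

Units: ``Dstar`` features are pseudo-diffusion coefficients on the
conventional reporting scale of 1e-3 mm^2/s; ``f`` features are
dimensionless perfusion fractions.
"""

from __future__ import annotations

GROUPS = ("ID", "NC")

#: Features whose group difference survived FDR correction in the source
#: cohort; {feature: {group: (mean, sd)}}.
IVIM_FEATURE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    # pseudo-diffusion coefficient D* (1e-3 mm^2/s)
    "DSFCR_Dstar": {"ID": (20.20, 4.66), "NC": (23.34, 5.19)},
    "HPCL_Dstar": {"ID": (41.98, 15.33), "NC": (31.81, 19.09)},
    "CADR_Dstar": {"ID": (34.38, 14.07), "NC": (41.82, 13.93)},
    "PTML_Dstar": {"ID": (39.83, 14.37), "NC": (29.33, 12.52)},
    "PTMR_Dstar": {"ID": (53.35, 25.43), "NC": (66.06, 17.59)},
    "PLDR_Dstar": {"ID": (34.46, 23.44), "NC": (47.88, 20.93)},
    "TLML_Dstar": {"ID": (28.65, 11.19), "NC": (18.79, 6.54)},
    # perfusion fraction f (dimensionless)
    "DSFCL_f": {"ID": (0.14, 0.02), "NC": (0.15, 0.02)},
    "DSFCR_f": {"ID": (0.15, 0.02), "NC": (0.17, 0.01)},
    "HPCL_f": {"ID": (0.20, 0.02), "NC": (0.18, 0.02)},
    "AMGR_f": {"ID": (0.18, 0.04), "NC": (0.20, 0.05)},
    "FSFL_f": {"ID": (0.17, 0.02), "NC": (0.16, 0.02)},
    "PTML_f": {"ID": (0.12, 0.01), "NC": (0.10, 0.02)},
    "PLDL_f": {"ID": (0.11, 0.05), "NC": (0.07, 0.07)},
}

#: Demographics per group: {variable: {group: (mean, sd)}}.
DEMOGRAPHIC_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"ID": (34.69, 9.59), "NC": (32.45, 10.51)},
    "education": {"ID": (13.71, 3.34), "NC": (15.17, 3.29)},
    "bmi": {"ID": (21.73, 2.88), "NC": (21.79, 2.95)},
}

#: Male counts out of 42 per group (19 male / 23 female ID; 16 / 26 NC).
MALE_FRACTION: dict[str, float] = {"ID": 19 / 42, "NC": 16 / 42}

#: Observed 2x2 gender contingency table, rows = (ID, NC), cols = (male, female).
GENDER_TABLE = ((19, 23), (16, 26))

#: Pittsburgh Sleep Quality Index totals (0-21 scale): {group: (mean, sd)}.
PSQI_STATS: dict[str, tuple[float, float]] = {"ID": (12.36, 2.84), "NC": (3.45, 1.33)}

#: The 22 regions analyzed (11 bilateral pairs), label -> abbreviation.
REGION_NAMES: dict[int, str] = {
    1: "DSFCL", 2: "DSFCR",
    3: "HPCL", 4: "HPCR",
    5: "CAL", 6: "CAR",
    7: "PCCL", 8: "PCCR",
    9: "TLML", 10: "TLMR",
    11: "PCSL", 12: "PCSR",
    13: "CADL", 14: "CADR",
    15: "PTML", 16: "PTMR",
    17: "PLDL", 18: "PLDR",
    19: "AMGL", 20: "AMGR",
    21: "FSFL", 22: "FSFR",
}


def pooled_moments(stats: dict[str, tuple[float, float]]) -> tuple[float, float]:
    """Mean and SD of the equal-weight two-group mixture.

    Used to standardize a subject's value against the whole-cohort
    distribution implied by the per-group parameters.
    """
    (m1, s1), (m2, s2) = (stats[g] for g in GROUPS)
    mean = 0.5 * (m1 + m2)
    var = 0.5 * (s1**2 + s2**2) + 0.25 * (m1 - m2) ** 2
    return mean, var**0.5
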