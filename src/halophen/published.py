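"""Published model constants for *Salicornia europaea* phenotyping.

These are the fixed, versioned coefficients of the predictive layer: the
general projected-area model, the two substrate-salinity models (one per
salt-tolerance population), the per-population biomass-vs-area calibration
curves, and the reference confusion matrices of the discriminant classifier.
They are shipped as data, deliberately separate from the fitting code, so a
re-fit on new data can never silently overwrite them.

Units convention (the only scaling under which the coefficient magnitudes are
commensurate): PA in cm^2, Sd in cm, Ht in cm, Sal.s. in mM NaCl, ΔE1
dimensionless.
"""

from __future__ import annotations

import numpy as np

#: General projected-area model, both populations:
#: PA = 83.34 - 0.23*Sal.s. + 1629.97*Sd + 25.71*Ht - 6.38*dE1
PA_MODEL: dict[str, float] = {
    "const": 83.34,
    "Sal.s.": -0.23,
    "Sd": 1629.97,
    "Ht": 25.71,
    "dE1": -6.38,
}

#: Substrate-salinity model, lower salt-tolerant population (Ciechocinek):
#: Sal.s. = 2532 - 1.6*PA + 4803.05*Sd + 34.83*Ht - 48.45*dE1
SALINITY_MODEL_LOWER: dict[str, float] = {
    "const": 2532.0,
    "PA": -1.6,
    "Sd": 4803.05,
    "Ht": 34.83,
    "dE1": -48.45,
}

#: Substrate-salinity model, higher salt-tolerant population (Inowrocław):
#: Sal.s. = -0.76 - 0.59*PA + 5775.15*Sd + 10.57*Ht - 14.87*dE1
SALINITY_MODEL_HIGHER: dict[str, float] = {
    "const": -0.76,
    "PA": -0.59,
    "Sd": 5775.15,
    "Ht": 10.57,
    "dE1": -14.87,
}

#: Biomass-vs-projected-area calibrations, highest power first (np.polyval
#: order). Lower salt-tolerant (Cie) is linear; higher salt-tolerant (Inw)
#: is a 2nd-degree polynomial.
BIOMASS_CALIBRATIONS: dict[tuple[str, str], tuple[float, ...]] = {
    ("lower", "FW"): (0.0325, -1.7611),
    ("lower", "DW"): (0.0027, 0.5238),
    ("higher", "FW"): (0.0005, -0.19, 21.43),
    ("higher", "DW"): (5e-05, -0.02, 2.87),
}

#: Salinity classes used by the discriminant layer, in reporting order.
CLASS_LABELS: tuple[str, ...] = ("CSS", "ISS", "NOS", "OS")

#: Treatment name -> substrate salinity (mM NaCl).
TREATMENT_SALINITY: dict[str, int] = {
    "NO-S": 0,
    "L-OS": 200,
    "H-OS": 400,
    "SS": 1000,
}

#: Reference confusion matrices of the discriminant classifier (rows = true
#: class, columns = predicted, order CSS/ISS/NOS/OS).  Training set n=96,
#: validation set n=24, leave-one-out cross-validation n=96.
TRAINING_CONFUSION = np.array(
    [
        [12, 0, 0, 0],
        [0, 12, 0, 0],
        [0, 0, 24, 0],
        [0, 0, 1, 47],
    ]
)

VALIDATION_CONFUSION = np.array(
    [
        [3, 0, 0, 0],
        [0, 3, 0, 0],
        [0, 0, 6, 0],
        [0, 0, 0, 12],
    ]
)

CROSS_VALIDATION_CONFUSION = np.array(
    [
        [12, 0, 0, 0],
        [0, 12, 0, 0],
        [0, 0, 24, 0],
        [0, 0, 0, 48],
    ]
)


def assign_class(population: str, treatment: str) -> str:
    """Map (population, treatment) to the salinity class used for sorting.

    NOS: no salinity (0 mM, both populations); OS: the optimum range
    (200 + 400 mM, both populations); CSS / ISS: severe salinity (1000 mM)
    in the lower- and higher-tolerant population respectively.
    """
    if treatment not in TREATMENT_SALINITY:
        raise ValueError(f"unknown treatment {treatment!r}")
    if population not in ("lower", "higher"):
        raise ValueError(f"unknown population {population!r}")
    if treatment == "NO-S":
        return "NOS"
    if treatment in ("L-OS", "H-OS"):
        return "OS"
    return "CSS" if population == "lower" else "ISS"
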