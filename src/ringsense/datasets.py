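"""Published summary tables of the 19-species conifer common-garden study.

The underlying core measurements of that study are not public, but its
printed species-level summaries are, and several downstream results are
closed under them: the cross-species correlations between climate
sensitivity and growth potential, and the fraction of species with
significant responses.  This module ships those printed values so the
closed computations can be reproduced exactly.

Contents
--------
``species_summary()``
    Per species: 4-letter code, mean basal area increment (cm2/yr).
``sensitivity_coefficients()``
    Per species: standardized growth-sensitivity coefficients to spring
    frost days, current and previous summer SPEI and winter temperature
    (TRI change per SD of covariate), with significance flags
    (p < 0.05 in the source analysis).
``significant_fractions()``
    Percentage of species with a significant response per covariate
    (winter temperature counted for positive responses, the direction the
    study tallies).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "species_summary",
    "sensitivity_coefficients",
    "significant_fractions",
]

# code, mean BAI (cm2/yr)
_SPECIES = [
    ("ABAL", 29.5), ("ABGR", 55.9), ("ABVE", 12.6), ("CHLA", 20.0),
    ("CRJA", 18.3), ("LAKA", 23.1), ("PIAR", 10.9), ("PINI", 19.3),
    ("PIAB", 27.7), ("PIOM", 13.7), ("PIOR", 23.8), ("PISI", 34.8),
    ("PSEM", 48.6), ("TABA", 9.8), ("TACU", 3.9), ("THPL", 47.0),
    ("TSCA", 18.4), ("TSDI", 9.3), ("TSHE", 42.6),
]

# code -> (coefficient, significant) per covariate
_COEFS = {
    #        spring frost      current SPEI     previous SPEI    winter temp
    "ABAL": ((-0.012, False), (0.040, True),  (0.012, False),  (0.006, False)),
    "ABGR": ((-0.017, False), (0.020, False), (0.012, False),  (0.042, True)),
    "ABVE": ((-0.004, False), (0.024, False), (-0.019, False), (0.007, False)),
    "CHLA": ((-0.039, True),  (0.028, True),  (0.023, False),  (0.023, False)),
    "CRJA": ((0.014, False),  (0.050, True),  (0.033, True),   (0.125, True)),
    "LAKA": ((-0.121, True),  (0.052, True),  (0.102, True),   (-0.043, True)),
    "PIAR": ((-0.020, False), (0.044, True),  (0.004, False),  (-0.021, False)),
    "PINI": ((-0.021, False), (0.053, True),  (-0.017, False), (0.016, False)),
    "PIAB": ((-0.055, True),  (0.077, True),  (0.003, False),  (-0.038, True)),
    "PIOM": ((-0.081, True),  (0.064, True),  (0.026, True),   (-0.042, True)),
    "PIOR": ((-0.057, True),  (0.050, True),  (0.044, True),   (0.018, False)),
    "PISI": ((-0.050, True),  (0.061, True),  (0.008, False),  (-0.040, True)),
    "PSEM": ((-0.054, True),  (0.032, True),  (0.017, False),  (0.032, True)),
    "TABA": ((-0.003, False), (0.077, True),  (-0.017, False), (0.103, True)),
    "TACU": ((0.028, False),  (0.047, True),  (-0.020, False), (0.053, True)),
    "THPL": ((-0.023, False), (0.046, True),  (0.002, False),  (-0.005, False)),
    "TSCA": ((-0.027, False), (0.038, True),  (-0.018, False), (-0.008, False)),
    "TSDI": ((0.011, False),  (0.066, True),  (-0.029, True),  (-0.028, False)),
    "TSHE": ((-0.017, False), (0.049, True),  (-0.020, False), (0.057, True)),
}

_COVARIATES = ("spring_frost", "current_spei", "previous_spei", "winter_temp")


def species_summary() -> pd.DataFrame:
    """Species codes with printed mean basal area increment (cm2/yr)."""
    return pd.DataFrame(_SPECIES, columns=["species_code", "mean_bai"])


def sensitivity_coefficients() -> pd.DataFrame:
    """Printed standardized sensitivity coefficients with significance flags."""
    rows = []
    for code, vals in _COEFS.items():
        row: dict[str, object] = {"species_code": code}
        for cov, (b, sig) in zip(_COVARIATES, vals):
            row[cov] = b
            row[f"sig_{cov}"] = sig
        rows.append(row)
    return pd.DataFrame(rows)


def significant_fractions() -> dict[str, float]:
    """Percent of species with significant responses, per covariate.

    Winter temperature counts only significant *positive* responses; the
    other covariates count any significant response.  Values are rounded
    to whole percent.
    """
    df = sensitivity_coefficients()
    n = len(df)
    out = {}
    for cov in _COVARIATES:
        if cov == "winter_temp":
            k = int(((df[f"sig_{cov}"]) & (df[cov] > 0)).sum())
        else:
            k = int(df[f"sig_{cov}"].sum())
        out[cov] = round(100.0 * k / n)
    return out
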