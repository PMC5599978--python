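"""Published point estimates from the field-cricket (Teleogryllus commodus)
nutritional-geometry study that this package re-implements analytically.

These printed estimates serve two roles:

* defaults for the synthetic-data generators, so parameter-recovery tests run
  at a realistic effect-size scale;
* desk-scale inputs for plug-in cross-checks (vector angles between linear
  nutritional gradients, predicted responses from the published G matrix).

Trait order for the 4x4 genetic matrix is (Pm, Cm, Pf, Cf): male protein and
carbohydrate intake, then female.  Gradients are on the z-scale (both intakes
and traits standardized within sex).
"""

from __future__ import annotations

import numpy as np

#: linear nutritional gradients (beta_P, beta_C) per sex per trait, z-scale
LINEAR_GRADIENTS = {
    ("female", "lifespan"): (-0.06, 0.60),
    ("female", "dre"): (0.52, 0.53),
    ("female", "lre"): (0.35, 0.70),
    ("male", "lifespan"): (0.28, 0.76),
    ("male", "dre"): (-0.15, 0.80),
    ("male", "lre"): (-0.09, 0.79),
}

#: quadratic (PxP, CxC) and correlational (PxC) gradients per sex per trait
NONLINEAR_GRADIENTS = {
    ("female", "lifespan"): (-0.08, -0.32, -0.33),
    ("female", "dre"): (-0.35, -0.09, 0.21),
    ("female", "lre"): (-0.33, -0.18, 0.06),
    ("male", "lifespan"): (-0.25, -0.22, -0.19),
    ("male", "dre"): (-0.01, -0.11, -0.25),
    ("male", "lre"): (-0.04, -0.10, -0.22),
}

#: sample sizes in the no-choice experiment
N_NOCHOICE = {"female": 222, "male": 208}

#: published additive genetic covariance matrix for regulated intake,
#: trait order (Pm, Cm, Pf, Cf); variances equal heritabilities because the
#: intakes were variance-standardized
G_POINT = np.array(
    [
        [0.34, 0.18, 0.24, 0.11],
        [0.18, 0.20, 0.17, 0.09],
        [0.24, 0.17, 0.31, 0.13],
        [0.11, 0.09, 0.13, 0.15],
    ]
)

G_TRAIT_ORDER = ("Pm", "Cm", "Pf", "Cf")

#: regulated intake points (mg over 21 days of dietary choice)
RIP_MEAN = {"female": (262.69, 577.10), "male": (179.22, 578.57)}

#: published sequential-comparison components (SS_reduced, SS_complete,
#: df1, df2, printed F) for rows where the partial-F identity is
#: self-consistent.  Keyed by (comparison, trait, tier).
SEQUENTIAL_ROWS = {
    ("F-vs-M", "lifespan", "linear"): (253.60, 243.44, 2, 424, 8.85),
    ("F-vs-M", "lifespan", "quadratic"): (208.83, 201.79, 2, 420, 7.33),
    ("F-vs-M", "lifespan", "correlational"): (190.38, 189.46, 1, 418, 2.03),
    ("F-vs-M", "dre", "linear"): (272.22, 199.81, 2, 424, 76.83),
    ("F-vs-M", "dre", "quadratic"): (187.97, 168.05, 2, 420, 24.89),
    ("F-vs-M", "dre", "correlational"): (167.64, 158.03, 1, 418, 25.41),
    ("F-vs-M", "lre", "linear"): (218.14, 192.99, 2, 424, 27.63),
    ("F-vs-M", "lre", "quadratic"): (177.74, 165.68, 2, 420, 15.29),
    ("F-vs-M", "lre", "correlational"): (163.86, 160.27, 1, 418, 9.35),
    ("F", "ls-vs-dre", "quadratic"): (256.64, 239.89, 2, 434, 15.15),
    ("F", "ls-vs-dre", "correlational"): (239.33, 227.54, 1, 432, 22.37),
    ("F", "ls-vs-lre", "linear"): (279.34, 263.34, 2, 438, 13.31),
    ("F", "ls-vs-lre", "correlational"): (221.67, 215.61, 1, 432, 12.15),
    ("F", "dre-vs-lre", "linear"): (289.78, 280.07, 2, 438, 7.59),
    ("F", "dre-vs-lre", "quadratic"): (225.82, 225.09, 2, 434, 0.70),
    ("F", "dre-vs-lre", "correlational"): (222.17, 221.23, 1, 432, 1.84),
    ("M", "ls-vs-dre", "linear"): (180.69, 160.51, 2, 410, 25.77),
    ("M", "ls-vs-dre", "quadratic"): (142.37, 129.95, 2, 406, 19.40),
    ("M", "ls-vs-dre", "correlational"): (120.15, 119.94, 1, 404, 0.71),
    ("M", "ls-vs-lre", "linear"): (188.49, 173.09, 2, 410, 18.24),
    ("M", "ls-vs-lre", "quadratic"): (151.81, 142.83, 2, 406, 12.76),
    ("M", "ls-vs-lre", "correlational"): (134.19, 134.12, 1, 404, 0.21),
    ("M", "dre-vs-lre", "linear"): (113.06, 112.73, 2, 410, 0.60),
    ("M", "dre-vs-lre", "quadratic"): (109.02, 108.63, 2, 406, 0.72),
    ("M", "dre-vs-lre", "correlational"): (97.11, 97.07, 1, 404, 0.17),
}

#: published rows whose printed F cannot be reproduced from their own printed
#: SS/df components via the partial-F identity (presumed typographic errors;
#: every other row reproduces to printed precision)
SEQUENTIAL_ROWS_INCONSISTENT = {
    ("F", "ls-vs-dre", "linear"): (325.66, 282.74, 2, 438, 118.45),
    ("F", "ls-vs-lre", "quadratic"): (235.88, 224.64, 2, 434, 20.52),
}

#: published posterior-mean angles (degrees) between linear gradient vectors
PUBLISHED_ANGLES = {
    ("F-vs-M", "lifespan"): 25.99,
    ("F-vs-M", "dre"): 55.19,
    ("F-vs-M", "lre"): 33.06,
    ("F", "ls-vs-dre"): 51.18,
    ("F", "ls-vs-lre"): 32.50,
    ("F", "dre-vs-lre"): 18.66,
    ("M", "ls-vs-dre"): 30.48,
    ("M", "ls-vs-lre"): 26.71,
    ("M", "dre-vs-lre"): 4.03,
}


def linear_vector(sex: str, trait: str) -> np.ndarray:
    """Published (beta_P, beta_C) linear gradient as an array."""
    return np.asarray(LINEAR_GRADIENTS[(sex, trait)], dtype=float)
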