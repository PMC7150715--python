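"""Versioned constant records for published index formulas.

The parent study prints none of the numerical constants of the oral glucose
insulin sensitivity index (OGIS), the Stumvoll regression indices or the
C-peptide kinetic model; they are transcribed here from the primary
literature, each in a single record with a citation string, so every formula
reads its constants from one auditable place.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml


@dataclass(frozen=True)
class OgisConstants:
    """Parameters of the 2-hour OGIS formula (clinical units).

    Glucose in mg/dl, insulin in μU/ml, dose per body surface area in g/m².
    """

    p1: float = 289.0
    p2: float = 270.0
    p3: float = 14000.0
    p4: float = 440.0
    p5: float = 637e-6
    p6: float = 117.0
    v_distribution: float = 10000.0  # ml/m2
    g_clamp: float = 90.0  # mg/dl reference clamp glucose
    citation: str = (
        "Mari A, Pacini G, Murphy E, Ludvik B, Nolan JJ. A model-based "
        "method for assessing insulin sensitivity from the oral glucose "
        "tolerance test. Diabetes Care 2001;24:539-548 (2-h variant)."
    )


@dataclass(frozen=True)
class StumvollConstants:
    """Coefficients of Stumvoll's demographic OGTT regression indices.

    MCR in ml·kg⁻¹·min⁻¹ and ISI in μmol·kg⁻¹·min⁻¹·(pmol/l)⁻¹ use BMI
    (kg/m²), insulin at 120 min (pmol/l) and glucose at 90 min (mmol/l);
    first/second-phase secretion (PH1/PH2, pmol) use insulin at 0 and
    30 min (pmol/l) and glucose at 30 min (mmol/l).
    """

    mcr: tuple = (18.8, -0.271, -0.0052, -0.27)  # const, BMI, I120, G90
    isi: tuple = (0.226, -0.0032, -0.0000645, -0.0037)  # const, BMI, I120, G90
    ph1: tuple = (1283.0, 1.829, -138.7, 3.772)  # const, I30, G30, I0
    ph2: tuple = (286.0, 0.416, -25.94, 2.132)  # const, I30, G30, I0
    citation: str = (
        "Stumvoll M, Mitrakou A, Pimenta W, et al. Use of the oral glucose "
        "tolerance test to assess insulin release and insulin sensitivity. "
        "Diabetes Care 2000;23:295-301; Stumvoll M, Van Haeften T, Fritsche "
        "A, Gerich J. Diabetes Care 2001;24:796-797."
    )


@dataclass(frozen=True)
class CpeptideKinetics:
    """Population two-compartment C-peptide kinetic parameters.

    Van Cauter-type population values: short half-life and its fractional
    amplitude are fixed; the long half-life grows linearly with age. The
    distribution volume is taken proportional to body surface area (normal
    non-obese adults).
    """

    t_half_short: float = 4.95  # min
    fraction_short: float = 0.76  # amplitude fraction of the fast phase
    t_half_long_intercept: float = 29.2  # min
    t_half_long_age_slope: float = 0.14  # min per year of age
    vd_litre_per_m2: float = 3.11  # distribution volume per BSA
    citation: str = (
        "Van Cauter E, Mestrez F, Sturis J, Polonsky KS. Estimation of "
        "insulin secretion rates from C-peptide levels. Comparison of "
        "individual and standard kinetic parameters for C-peptide "
        "clearance. Diabetes 1992;41:368-377."
    )

    def rate_constants(self, age: float) -> tuple[float, float, float]:
        """Return (k1, k2, k3) in min⁻¹ for a subject of the given age.

        k1: central->peripheral, k2: peripheral->central, k3: irreversible
        elimination from the central compartment. Derived from the two
        exponential half-lives and the fast-phase fraction by the standard
        re-parameterisation.
        """
        import math

        a = math.log(2.0) / self.t_half_short
        b = math.log(2.0) / (
            self.t_half_long_intercept + self.t_half_long_age_slope * age
        )
        f = self.fraction_short
        k2 = f * b + (1.0 - f) * a
        k3 = a * b / k2
        k1 = a + b - k2 - k3
        return k1, k2, k3


OGIS_CONSTANTS = OgisConstants()
STUMVOLL_CONSTANTS = StumvollConstants()
CPEPTIDE_KINETICS = CpeptideKinetics()


def constants_to_yaml(path) -> None:
    """Serialize all constant records (with citations) to a YAML file."""
    payload = {
        "ogis": asdict(OGIS_CONSTANTS),
        "stumvoll": asdict(STUMVOLL_CONSTANTS),
        "cpeptide_kinetics": asdict(CPEPTIDE_KINETICS),
    }
    # tuples -> lists for clean YAML
    for rec in payload.values():
        for k, v in rec.items():
            if isinstance(v, tuple):
                rec[k] = list(v)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
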