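"""Assay mathematics: PAMPA permeability, monomer-dimer equilibrium,
LDH cytotoxicity and luminescence fold-change.

All formulas are simple closed forms; units are kept explicit.  Volumes are
in mL (= cm^3), membrane area in cm^2, time in seconds, so the apparent
permeability Pe comes out in cm/s.  Concentration units cancel everywhere
except the dimer KD, which is returned in the units of the supplied total
protein concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PampaWell",
    "PampaResult",
    "DimerEquilibrium",
    "CytotoxMeasurement",
    "AssayError",
    "pampa_pe",
    "classify_permeability",
    "kd_from_fraction_dimer",
    "fraction_dimer_from_kd",
    "percent_cytotoxicity",
    "fold_change",
    "PERMEABILITY_CUTOFF_CM_S",
    "CM_PER_S_TO_NM_PER_S",
]

#: Vendor-recommended cutoff separating low from high passive permeability:
#: 15 nm/s, i.e. 1.5e-6 cm/s.
PERMEABILITY_CUTOFF_CM_S = 1.5e-6
CM_PER_S_TO_NM_PER_S = 1.0e7


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class PampaWell:
    """One donor/acceptor well pair of a parallel artificial membrane
    permeability assay.

    Defaults reflect the plate protocol: 300 uL donor, 200 uL acceptor,
    17 h incubation, 0.3 cm^2 membrane filter area.
    """

    cd_t: float  # donor concentration at time t (mM)
    ca_t: float  # acceptor concentration at time t (mM)
    c0: float  # initial donor concentration (mM)
    vd: float = 0.3  # donor volume (mL)
    va: float = 0.2  # acceptor volume (mL)
    area: float = 0.3  # membrane filter area (cm^2)
    t: float = 17 * 3600.0  # incubation time (s)

    def __post_init__(self) -> None:
        if min(self.vd, self.va, self.area, self.t) <= 0:
            raise AssayError("volumes, area and incubation time must be positive")
        if self.cd_t < 0 or self.ca_t < 0:
            raise AssayError("concentrations must be non-negative")
        if self.c0 <= 0:
            raise AssayError("invalid initial concentration")


@dataclass(frozen=True)
class PampaResult:
    ceq: float  # equilibrium concentration (mM)
    retention: float  # mass retention R (fraction)
    pe: float  # apparent permeability (cm/s)

    @property
    def pe_nm_s(self) -> float:
        return self.pe * CM_PER_S_TO_NM_PER_S


def pampa_pe(well: PampaWell) -> PampaResult:
    """Apparent permeability from the mass-balance equation.

    Ceq = (CD*VD + CA*VA) / (VD + VA);  R = 1 - (CD*VD + CA*VA)/(C0*VD);
    Pe = -ln(1 - CA/Ceq) / (A * (1/VD + 1/VA) * t).
    """
    mass = well.cd_t * well.vd + well.ca_t * well.va
    ceq = mass / (well.vd + well.va)
    retention = 1.0 - mass / (well.c0 * well.vd)
    if well.ca_t >= ceq and well.ca_t > 0:
        raise AssayError("equilibrated or over-equilibrated well: Pe undefined")
    ratio = 0.0 if ceq == 0 else well.ca_t / ceq
    pe = -math.log(1.0 - ratio) / (well.area * (1.0 / well.vd + 1.0 / well.va) * well.t)
    return PampaResult(ceq=ceq, retention=retention, pe=pe)


def classify_permeability(pe_cm_s: float, cutoff: float = PERMEABILITY_CUTOFF_CM_S) -> str:
    """"low" or "high" relative to the cutoff; a Pe exactly at the cutoff is
    conservatively called low."""
    return "high" if pe_cm_s > cutoff else "low"


@dataclass(frozen=True)
class DimerEquilibrium:
    """Monomer-dimer equilibrium state at one total protein concentration.

    ``p_total`` counts chains (monomer units); mass balance is
    p_total = monomer + 2*dimer, fraction dimer FD = 2*dimer/p_total, and
    KD = monomer^2 / dimer (concentration units of ``p_total``).
    """

    p_total: float
    fraction_dimer: float
    monomer: float
    dimer: float
    kd: float

    def __post_init__(self) -> None:
        if abs(self.monomer + 2 * self.dimer - self.p_total) > 1e-9 * max(self.p_total, 1.0):
            raise AssayError("mass balance violated")


def kd_from_fraction_dimer(fraction_dimer: float, p_total: float) -> DimerEquilibrium:
    """Dimer dissociation constant from an observed fraction dimer.

    dimer = FD*Ptotal/2, monomer = Ptotal - 2*dimer, KD = monomer^2/dimer.
    """
    if not (0.0 < fraction_dimer <= 1.0):
        raise AssayError("no dimer; KD unbounded" if fraction_dimer == 0 else "fraction dimer must be in (0, 1]")
    if p_total <= 0:
        raise AssayError("total concentration must be positive")
    dimer = fraction_dimer * p_total / 2.0
    monomer = p_total - 2.0 * dimer
    kd = monomer * monomer / dimer
    return DimerEquilibrium(p_total, fraction_dimer, monomer, dimer, kd)


def fraction_dimer_from_kd(kd: float, p_total: float) -> DimerEquilibrium:
    """Equilibrium speciation at a given KD and total chain concentration.

    Solves the mass-balance quadratic 2 m^2 + KD m - KD Ptotal = 0 for the
    monomer concentration, m = (-KD + sqrt(KD^2 + 8 KD Ptotal)) / 4,
    evaluated in the cancellation-free conjugate form
    m = 2 KD Ptotal / (KD + sqrt(KD^2 + 8 KD Ptotal)).
    """
    if kd < 0:
        raise AssayError("KD must be non-negative")
    if p_total <= 0:
        raise AssayError("total concentration must be positive")
    if kd == 0:
        monomer, dimer = 0.0, p_total / 2.0
    else:
        monomer = 2.0 * kd * p_total / (kd + math.sqrt(kd * kd + 8.0 * kd * p_total))
        dimer = monomer * monomer / kd
    fd = 2.0 * dimer / p_total
    return DimerEquilibrium(p_total, fd, monomer, dimer, kd)


@dataclass(frozen=True)
class CytotoxMeasurement:
    """LDH-release luminescence readings (arbitrary units)."""

    experimental: float
    background: float  # medium-only control
    maximum: float  # detergent-lysed maximum-release control

    def __post_init__(self) -> None:
        if self.maximum <= self.background:
            raise AssayError("invalid controls: maximum LDH release must exceed background")


def percent_cytotoxicity(m: CytotoxMeasurement) -> float:
    """(experimental - background) / (maximum - background) * 100."""
    return (m.experimental - m.background) / (m.maximum - m.background) * 100.0


def fold_change(mean_after: float, mean_before: float) -> float:
    """Luminescence fold difference: mean after compound addition over mean
    before."""
    if mean_before <= 0:
        raise AssayError("mean luminescence before addition must be positive")
    return mean_after / mean_before
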