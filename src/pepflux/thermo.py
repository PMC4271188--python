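"""Equilibrium thermodynamics of n:m proton:peptide symport.

A proton-coupled oligopeptide transporter (POT family) moving ``n`` protons
and ``m`` neutral peptides per cycle,

    n H+(out) + m Pep(out)  <=>  n H+(in) + m Pep(in),

has zero net flux at a single transmembrane voltage, the reversal
(equilibrium) potential.  With the voltage defined as
``delta_psi = psi_in - psi_out`` (outside at ground) and a Nernstian slope
of ``mv_per_decade`` millivolts per 10-fold concentration ratio,

    delta_psi_rev = mv_per_decade * ( (pH_in - pH_out)
                    - (m/n) * log10([Pep]_in / [Pep]_out) ).

The reversal potential depends only on the gradients and the coupling
stoichiometry, never on the transport mechanism, which is what makes it a
clean probe of stoichiometry: clamp the voltage (K+/valinomycin), watch the
direction of proton flux, and bracket n.

Units: concentrations in mM, voltages in mV, temperature in K.  Membrane
voltages are plain floats in mV throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidInputError

__all__ = [
    "ThermoConstants",
    "AssayConditions",
    "Stoichiometry",
    "reversal_potential",
    "nernst_potential",
    "required_k_out",
    "driving_force",
    "predicted_direction",
    "accumulation_ratio",
    "GAS_CONSTANT",
    "FARADAY",
]

#: Universal gas constant, J / (mol K).
GAS_CONSTANT = 8.31446261815324
#: Faraday constant, C / mol.
FARADAY = 96485.33212331001


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants of the Nernstian slope.

    Parameters
    ----------
    mv_per_decade:
        Millivolts per 10-fold concentration ratio.  Defaults to the round
        value 60, which reproduces every printed voltage in the assay design
        (the exact value at 301.5 K is within 0.3% of it).
    temperature:
        Kelvin; only consulted by :meth:`exact`.
    proton_charge:
        Signed valence of the proton, +1.
    """

    mv_per_decade: float = 60.0
    temperature: float = 301.5
    proton_charge: int = 1

    def __post_init__(self) -> None:
        if not self.mv_per_decade > 0:
            raise InvalidInputError("mv_per_decade must be positive")
        if self.proton_charge != 1:
            raise InvalidInputError("proton_charge must be +1")
        if not self.temperature > 0:
            raise InvalidInputError("temperature must be positive (K)")

    @classmethod
    def exact(cls, temperature: float = 301.5) -> "ThermoConstants":
        """Constants with the slope computed as RT ln(10) / F in mV."""
        mv = 1000.0 * GAS_CONSTANT * temperature * math.log(10.0) / FARADAY
        return cls(mv_per_decade=mv, temperature=temperature)


DEFAULT_CONSTANTS = ThermoConstants()


def _require_positive(name: str, value: float) -> None:
    if not value > 0 or not math.isfinite(value):
        raise InvalidInputError(f"{name} must be a positive finite number, got {value!r}")


def _require_ph(name: str, value: float) -> None:
    if not (0.0 <= value <= 14.0):
        raise InvalidInputError(f"{name} must lie in [0, 14], got {value!r}")


@dataclass(frozen=True)
class AssayConditions:
    """Chemical state on the two faces of the liposome membrane.

    ``in`` refers to the lumen, ``out`` to the bath.  Concentrations in mM.
    Potassium defaults reproduce the standard hyperpolarising gradient
    (120 mM inside, 1.2 mM outside, i.e. -120 mV on valinomycin addition).
    """

    ph_in: float
    ph_out: float
    pep_in: float
    pep_out: float
    k_in: float = 120.0
    k_out: float = 1.2

    def __post_init__(self) -> None:
        _require_ph("ph_in", self.ph_in)
        _require_ph("ph_out", self.ph_out)
        for name in ("pep_in", "pep_out", "k_in", "k_out"):
            _require_positive(name, getattr(self, name))

    def swapped(self) -> "AssayConditions":
        """Conditions with every in/out label exchanged."""
        return AssayConditions(
            ph_in=self.ph_out,
            ph_out=self.ph_in,
            pep_in=self.pep_out,
            pep_out=self.pep_in,
            k_in=self.k_out,
            k_out=self.k_in,
        )


@dataclass(frozen=True)
class Stoichiometry:
    """Coupling ratio: ``n_protons`` protons per ``m_peptides`` peptides."""

    n_protons: int
    m_peptides: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.n_protons, int) and self.n_protons >= 1):
            raise InvalidInputError("n_protons must be an integer >= 1")
        if not (isinstance(self.m_peptides, int) and self.m_peptides >= 1):
            raise InvalidInputError("m_peptides must be an integer >= 1")

    @property
    def ratio(self) -> float:
        """Protons per peptide, n/m."""
        return self.n_protons / self.m_peptides


def nernst_potential(
    ion_out: float, ion_in: float, consts: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Equilibrium potential (mV) for a single permeant ion.

    ``mv_per_decade * log10(ion_out / ion_in)``; sign convention
    psi_in - psi_out, so a high internal K+ gives a negative-inside voltage
    once valinomycin renders the membrane K+-selective.
    """
    _require_positive("ion_out", ion_out)
    _require_positive("ion_in", ion_in)
    return consts.mv_per_decade * math.log10(ion_out / ion_in)


def required_k_out(
    target_mv: float, k_in: float, consts: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """External K+ (mM) that clamps the voltage at ``target_mv``.

    Exact inverse of :func:`nernst_potential` for fixed internal K+; used to
    plan the potassium gradients of a voltage series.
    """
    _require_positive("k_in", k_in)
    if not math.isfinite(target_mv):
        raise InvalidInputError("target_mv must be finite")
    return k_in * 10.0 ** (target_mv / consts.mv_per_decade)


def reversal_potential(
    cond: AssayConditions,
    stoich: Stoichiometry,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Voltage (mV) at which net coupled flux is zero.

    Antisymmetric under exchange of all in/out labels.  For a 100-fold
    inward peptide gradient with no pH gradient this is -120/n * (m) mV at
    the default 60 mV/decade slope: -40 mV for 3:1, -30 mV for 4:1,
    -20 mV for 6:1.
    """
    dph = cond.ph_in - cond.ph_out
    pep_term = (stoich.m_peptides / stoich.n_protons) * math.log10(
        cond.pep_in / cond.pep_out
    )
    return consts.mv_per_decade * (dph - pep_term)


def driving_force(
    applied_mv: float,
    cond: AssayConditions,
    stoich: Stoichiometry,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Signed displacement from equilibrium, ``applied - reversal`` (mV).

    Negative means inward proton/peptide flux (lumen acidification),
    positive outward (alkalinization), zero equilibrium.
    """
    return applied_mv - reversal_potential(cond, stoich, consts)


def predicted_direction(
    applied_mv: float,
    cond: AssayConditions,
    stoich: Stoichiometry,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> str:
    """Predicted flux direction at a clamped voltage.

    Returns ``"acidification"``, ``"alkalinization"`` or ``"no_net_flux"``.
    """
    df = driving_force(applied_mv, cond, stoich, consts)
    if df < 0:
        return "acidification"
    if df > 0:
        return "alkalinization"
    return "no_net_flux"


def accumulation_ratio(
    stoich: Stoichiometry,
    ph_out: float,
    ph_in: float,
    applied_mv: float = 0.0,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Equilibrium [Pep]_in / [Pep]_out sustained by the proton gradient.

    Obtained by solving the reversal-potential relation for the peptide
    ratio at a given voltage:

        ratio = 10 ** ( (n/m) * ( (pH_in - pH_out) - applied/slope ) ).

    At zero voltage this reduces to ([H+]_out/[H+]_in)**(n/m): one pH unit
    acid outside accumulates a 3:1-coupled peptide 1000-fold and a
    4:1-coupled peptide 10000-fold, the thermodynamic basis of the
    di- vs tri-peptide steady-state uptake contrast.
    """
    _require_ph("ph_out", ph_out)
    _require_ph("ph_in", ph_in)
    if not math.isfinite(applied_mv):
        raise InvalidInputError("applied_mv must be finite")
    exponent = stoich.ratio * ((ph_in - ph_out) - applied_mv / consts.mv_per_decade)
    return 10.0 ** exponent
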