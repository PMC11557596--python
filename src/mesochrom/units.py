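"""Reduced-unit system for the chromatin polymer simulation.

The simulation works in reduced units: the euchromatin (EC/A) bead diameter
``sigma_AA`` is the length unit, the thermal energy ``e = k_B T`` is the
energy unit, and the nucleoplasmic viscosity is unity (``eta* = 1``).  The
derived time unit is ``tau = eta * sigma_AA^3 / (eta* e)``.

At the physiological defaults (T = 310 K, eta = 1.5 cP, sigma_AA = 18 nm)
the energy unit is 4.28 pN nm and tau evaluates to ~2.0e-3 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Boltzmann constant in pN nm / K  (1 J = 1e21 pN nm)
K_B_PN_NM = 1.380649e-2


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced simulation units and physical units.

    Parameters
    ----------
    temperature_K:
        Absolute temperature; 310 K (physiological) by default.
    viscosity_cP:
        Nucleoplasmic viscosity in centipoise.
    sigma_AA_nm:
        EC/A bead diameter in nm; defines the reduced length unit.
    reduced_viscosity:
        Viscosity in reduced units (conventionally 1).
    time_unit_ms:
        Reduced time unit tau in ms.  ``None`` (default) derives it from
        ``eta * sigma_AA^3 / (eta* e)``; it may be overridden explicitly.
    """

    temperature_K: float = 310.0
    viscosity_cP: float = 1.5
    sigma_AA_nm: float = 18.0
    reduced_viscosity: float = 1.0
    time_unit_ms: float | None = None
    energy_unit_pNnm: float = field(init=False)

    def __post_init__(self) -> None:
        e = K_B_PN_NM * self.temperature_K
        object.__setattr__(self, "energy_unit_pNnm", e)
        if self.time_unit_ms is None:
            # tau = eta sigma^3 / (eta* e):
            #   [Pa s] [m^3] / [J] = s
            eta_pa_s = self.viscosity_cP * 1e-3
            sigma_m = self.sigma_AA_nm * 1e-9
            e_joule = e * 1e-21
            tau_s = eta_pa_s * sigma_m**3 / (self.reduced_viscosity * e_joule)
            object.__setattr__(self, "time_unit_ms", tau_s * 1e3)

    # -- conversions ---------------------------------------------------
    def length_to_nm(self, r: float) -> float:
        return r * self.sigma_AA_nm

    def length_from_nm(self, nm: float) -> float:
        return nm / self.sigma_AA_nm

    def energy_to_pNnm(self, u: float) -> float:
        return u * self.energy_unit_pNnm

    def energy_from_pNnm(self, pnnm: float) -> float:
        return pnnm / self.energy_unit_pNnm

    def time_to_ms(self, t: float) -> float:
        return t * self.time_unit_ms

    def time_from_ms(self, ms: float) -> float:
        return ms / self.time_unit_ms


def nucleosomes_per_bead(bead_diameter_nm: float, nucleosome_nm: float = 10.0) -> int:
    """Number of nucleosomes a coarse-grained bead represents.

    Scales as the cube of the diameter ratio: a 25 nm heterochromatin bead
    corresponds to 16 nucleosomes (~3 kbp), an 18 nm euchromatin bead to 6
    (~1.2 kbp), for a 10 nm nucleosome.
    """
    return round((bead_diameter_nm / nucleosome_nm) ** 3)
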