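"""Unit conversions between lattice volume fractions and molar concentrations.

The mean-field lattice model works in volume fractions: every protein
residue, every solvent segment and every ATP molecule occupies one lattice
site of volume ``v``.  Comparison with experiment requires converting the
dilute-branch protein volume fraction to a chain molarity (the saturation
concentration) and the reservoir ATP volume fraction to an ATP molarity.

The site volume is set by the hydration size of an amino acid, about
0.65 nm, interpreted as a hydration *radius*, so ``v = (4/3) pi r^3 =
1.1503 nm^3``.  This spherical reading is what reproduces the model's
anchor numbers (a 5 uM saturation concentration at beta*eps1 = -2 with
N2 = 65); a cubic site of 0.65 nm edge misses them by exactly 4*pi/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import Avogadro

#: mol/L corresponding to a number density of 1 molecule per nm^3
_MOLAR_PER_NM3 = 1e24 / Avogadro


@dataclass(frozen=True)
class UnitSystem:
    """Length/volume bookkeeping for the incompressible lattice model.

    Parameters
    ----------
    residue_radius_nm:
        Hydration radius of one amino-acid residue in nanometres.  The
        lattice site volume is the volume of the corresponding sphere.
    """

    residue_radius_nm: float = 0.65

    def __post_init__(self) -> None:
        if self.residue_radius_nm <= 0:
            raise ValueError("residue_radius_nm must be positive")

    @property
    def site_volume_nm3(self) -> float:
        """Volume ``v`` of one lattice site (one residue / one ATP) in nm^3."""
        return 4.0 / 3.0 * math.pi * self.residue_radius_nm**3

    def phi_to_molar(self, phi: float, n_sites_per_unit: int = 1) -> float:
        """Convert a volume fraction to molarity of the diffusing unit.

        A unit occupying ``n_sites_per_unit`` lattice sites (``N1`` for a
        protein chain, 1 for ATP) at volume fraction ``phi`` has number
        density ``phi / (n * v)``; the result is in mol/L.
        """
        if phi < 0:
            raise ValueError("phi must be non-negative")
        return phi / (n_sites_per_unit * self.site_volume_nm3) * _MOLAR_PER_NM3

    def molar_to_phi(self, conc_molar: float, n_sites_per_unit: int = 1) -> float:
        """Inverse of :meth:`phi_to_molar`."""
        if conc_molar < 0:
            raise ValueError("concentration must be non-negative")
        return conc_molar * n_sites_per_unit * self.site_volume_nm3 / _MOLAR_PER_NM3


DEFAULT_UNITS = UnitSystem()


def phi_to_molar(phi: float, n_sites_per_unit: int = 1,
                 units: UnitSystem = DEFAULT_UNITS) -> float:
    """Module-level convenience wrapper around :meth:`UnitSystem.phi_to_molar`."""
    return units.phi_to_molar(phi, n_sites_per_unit)


def molar_to_phi(conc_molar: float, n_sites_per_unit: int = 1,
                 units: UnitSystem = DEFAULT_UNITS) -> float:
    """Module-level convenience wrapper around :meth:`UnitSystem.molar_to_phi`."""
    return units.molar_to_phi(conc_molar, n_sites_per_unit)
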