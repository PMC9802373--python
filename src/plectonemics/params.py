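"""Elastic parameters and molecule geometry for supercoiled DNA.

Units used throughout the package: lengths in nm, forces in pN, energies in
pN·nm (1 pN·nm = 1e-21 J) unless a function states k_BT units, times in s,
linking numbers in turns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Boltzmann constant in pN·nm/K.
KB = 0.0138064852


@dataclass(frozen=True)
class ElasticParams:
    """Elastic constants and helical geometry of double-stranded DNA.

    Parameters
    ----------
    bend_persistence :
        Bending persistence length ``A`` (nm).
    twist_persistence :
        Twist persistence length ``C`` (nm).
    plectoneme_stiffness :
        Effective torsional stiffness ``P`` of the plectonemic phase (nm).
    helical_repeat :
        Base pairs per helical turn of relaxed B-DNA.
    helical_rise :
        Contour length per base pair (nm).
    temperature :
        Absolute temperature (K); thermal energy ``kT`` is derived.
    """

    bend_persistence: float = 40.0
    twist_persistence: float = 100.0
    plectoneme_stiffness: float = 20.0
    helical_repeat: float = 10.5
    helical_rise: float = 0.34
    temperature: float = 298.0

    def __post_init__(self) -> None:
        for name in (
            "bend_persistence",
            "twist_persistence",
            "plectoneme_stiffness",
            "helical_repeat",
            "helical_rise",
            "temperature",
        ):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in pN·nm."""
        return KB * self.temperature

    @property
    def omega0(self) -> float:
        """Intrinsic twist density 2π/(repeat·rise) of relaxed B-DNA (rad/nm)."""
        return 2.0 * math.pi / (self.helical_repeat * self.helical_rise)


@dataclass(frozen=True)
class MoleculeSpec:
    """A torsionally constrained linear DNA molecule.

    The relaxed linking number is ``Lk0 = n_bp / helical_repeat`` and the
    contour length is ``L = n_bp · helical_rise``.
    """

    n_bp: int
    helical_repeat: float = 10.5
    helical_rise: float = 0.34

    def __post_init__(self) -> None:
        if self.n_bp <= 0:
            raise ValueError("n_bp must be a positive integer")
        if self.helical_repeat <= 0 or self.helical_rise <= 0:
            raise ValueError("helical geometry must be strictly positive")

    @property
    def contour_length(self) -> float:
        """Contour length L (nm)."""
        return self.n_bp * self.helical_rise

    @property
    def lk0(self) -> float:
        """Relaxed linking number Lk0 (turns)."""
        return self.n_bp / self.helical_repeat

    @classmethod
    def from_params(cls, n_bp: int, params: ElasticParams) -> "MoleculeSpec":
        return cls(
            n_bp=n_bp,
            helical_repeat=params.helical_repeat,
            helical_rise=params.helical_rise,
        )
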