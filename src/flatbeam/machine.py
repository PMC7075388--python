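"""Machine description: MLC geometry, kinematic limits and dose rates.

All geometry is expressed in the isocenter plane, in cm. ``x`` is the leaf
travel direction, ``y`` the leaf stacking direction, and the beam central
axis pierces the plane at (0, 0).
"""
from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class MachineSpec:
    """MLC and accelerator characteristics relevant to dynamic delivery.

    Parameters
    ----------
    n_leaf_pairs : int
        Number of opposed leaf pairs in the MLC.
    leaf_width : float
        Leaf width projected at isocenter (cm); equals the fluence-row pitch.
    min_gap : float
        Minimum opposed-leaf gap required during dynamic delivery (cm).
    v_max : float
        Maximum leaf speed (cm/s).
    overtravel : float
        Maximum leaf-tip extension past the beam centerline into the
        opposing half-plane (cm).
    bank_span : float
        Maximum distance between any two leaf tips of the same bank (cm);
        set by the movable carriage.
    dose_rate_mod : float
        Nominal dose rate of the unflattened (FFF) beam (MU/min).
    dose_rate_ref : float
        Nominal dose rate of the flattened reference beam (MU/min).
    """

    n_leaf_pairs: int = 80
    leaf_width: float = 0.5
    min_gap: float = 0.6
    v_max: float = 6.0
    overtravel: float = 15.0
    bank_span: float = 20.0
    dose_rate_mod: float = 1400.0
    dose_rate_ref: float = 600.0

    def __post_init__(self) -> None:
        for name in (
            "n_leaf_pairs", "leaf_width", "min_gap", "v_max",
            "overtravel", "bank_span", "dose_rate_mod", "dose_rate_ref",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"MachineSpec.{name} must be strictly positive")
        if not self.min_gap < self.bank_span:
            raise ValueError("min_gap must be smaller than bank_span")
        if not self.overtravel < self.bank_span:
            raise ValueError("overtravel must be smaller than bank_span")

    @property
    def dose_rate_mod_per_s(self) -> float:
        """FFF dose rate in MU/s."""
        return self.dose_rate_mod / 60.0

    @property
    def dose_rate_ref_per_s(self) -> float:
        """Flattened-beam dose rate in MU/s."""
        return self.dose_rate_ref / 60.0

    def replace(self, **kwargs) -> "MachineSpec":
        return replace(self, **kwargs)


def default_machine_spec() -> MachineSpec:
    """Agility-class 160-leaf MLC defaults.

    80 leaf pairs of 0.5 cm projected width, 6 mm dynamic leaf gap, 6.0 cm/s
    maximum leaf speed, 15 cm overtravel past the centerline, 20 cm same-bank
    span, 1400 MU/min unflattened and 600 MU/min flattened dose rate.
    """
    return MachineSpec()
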