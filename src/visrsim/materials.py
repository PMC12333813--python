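"""Incompressible transversely isotropic (ITI) materials.

A transversely isotropic solid has five engineering constants: Young's
moduli ``ET`` (in the plane of isotropy) and ``EL`` (along the axis of
symmetry, AoS), shear moduli ``muT`` and ``muL``, and Poisson's ratios
``nuTT`` and ``nuLT``.  Incompressibility removes two degrees of freedom:

    nuLT = 1/2
    nuTT = 1 - ET / (2 EL)
    muT  = ET / (2 (1 + nuTT))

so an ITI material is fully described by three independent constants,
conventionally (ET, EL, muL).  Soft-tissue panels (skeletal muscle,
kidney, breast) fall in the few-to-tens of kPa range for all four moduli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TIMaterial",
    "make_incompressible_material",
    "material_library",
    "panel_to_frame",
    "save_panel",
    "load_panel",
]

#: relative tolerance to which the incompressibility constraints must hold
CONSTRAINT_RTOL = 1e-12

_PANEL_RESOURCE = "material_panel.csv"


@dataclass(frozen=True)
class TIMaterial:
    """One incompressible TI material.  All moduli in Pa."""

    ET: float
    EL: float
    muT: float
    muL: float
    nuTT: float
    nuLT: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("ET", "EL", "muT", "muL"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.nuLT != 0.5:
            raise ValueError(f"incompressibility requires nuLT = 1/2, got {self.nuLT!r}")
        nuTT_expected = 1.0 - self.ET / (2.0 * self.EL)
        if not np.isclose(self.nuTT, nuTT_expected, rtol=CONSTRAINT_RTOL, atol=0.0):
            raise ValueError(
                f"nuTT={self.nuTT!r} violates incompressibility "
                f"(expected {nuTT_expected!r} from ET, EL)"
            )
        muT_expected = self.ET / (2.0 * (1.0 + self.nuTT))
        if not np.isclose(self.muT, muT_expected, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"muT={self.muT!r} inconsistent with ET/(2(1+nuTT))={muT_expected!r}"
            )
        if not 0.0 < self.muL / self.EL < 1.0:
            raise ValueError(f"muL/EL must lie in (0, 1), got {self.muL / self.EL!r}")

    @property
    def muL_over_EL(self) -> float:
        """Shear-to-Young's modulus ratio along the AoS (the ΔRE biomarker)."""
        return self.muL / self.EL


def make_incompressible_material(
    ET: float, EL: float, muL: float, label: str = ""
) -> TIMaterial:
    """Build an ITI material from its three independent constants (Pa).

    ``nuLT``, ``nuTT`` and ``muT`` follow from the incompressibility
    constraints.  ``ET > 2 EL`` is rejected because it would imply a
    negative ``nuTT``.
    """
    for name, v in (("ET", ET), ("EL", EL), ("muL", muL)):
        if not np.isfinite(v) or v <= 0.0:
            raise ValueError(f"{name} must be strictly positive, got {v!r}")
    if ET > 2.0 * EL:
        raise ValueError(f"ET={ET} > 2*EL={2 * EL}: nuTT would be negative")
    nuTT = 1.0 - ET / (2.0 * EL)
    muT = ET / (2.0 * (1.0 + nuTT))
    return TIMaterial(ET=ET, EL=EL, muT=muT, muL=muL, nuTT=nuTT, nuLT=0.5, label=label)


def material_library() -> list[TIMaterial]:
    """The 12-material simulated soft-tissue panel.

    Parameters are read from the versioned CSV fixture shipped with the
    package and re-validated through :func:`make_incompressible_material`.
    The panel spans ET 11.74-24.96 kPa, EL 35.23-82.78 kPa, muT
    3.20-6.80 kPa and muL 4.80-40.80 kPa and contains the clustered pairs
    (shared muL of 16.20 and 4.80 kPa, shared muT of 3.60 and 3.20 kPa)
    and the near-tied muL/EL group {0.26, 0.26, 0.26, 0.27} used by the
    rank statistics, plus one pair of ratios ~7% apart.
    """
    with resources.files("visrsim.data").joinpath(_PANEL_RESOURCE).open("r") as fh:
        table = pd.read_csv(fh)
    return [
        make_incompressible_material(
            ET=row.ET_kPa * 1e3,
            EL=row.EL_kPa * 1e3,
            muL=row.muL_kPa * 1e3,
            label=str(row.label),
        )
        for row in table.itertuples()
    ]


def panel_to_frame(panel: list[TIMaterial]) -> pd.DataFrame:
    """Flatten a material panel to the tabular interchange layout (kPa)."""
    return pd.DataFrame(
        {
            "label": [m.label for m in panel],
            "ET_kPa": [m.ET / 1e3 for m in panel],
            "EL_kPa": [m.EL / 1e3 for m in panel],
            "muT_kPa": [m.muT / 1e3 for m in panel],
            "muL_kPa": [m.muL / 1e3 for m in panel],
            "nuTT": [m.nuTT for m in panel],
            "nuLT": [m.nuLT for m in panel],
            "muL_over_EL": [m.muL_over_EL for m in panel],
        }
    )


def save_panel(panel: list[TIMaterial], path: str | Path) -> None:
    panel_to_frame(panel).to_csv(path, index=False, float_format="%.17g")


def load_panel(path: str | Path) -> list[TIMaterial]:
    """Load a panel table (kPa columns) and re-derive the dependent constants."""
    table = pd.read_csv(path)
    return [
        make_incompressible_material(
            ET=row.ET_kPa * 1e3,
            EL=row.EL_kPa * 1e3,
            muL=row.muL_kPa * 1e3,
            label=str(row.label),
        )
        for row in table.itertuples()
    ]
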