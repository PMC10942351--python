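"""Theoretical resolution of a Fourier light field microscope (fLFM).

In fLFM the microlens array sits conjugate to the objective's back focal
plane; each lenslet images the sample from one angular perspective.  The
object-space lateral resolution under the paraxial Abbe limit is

    R_xy = lambda * f_FL / (d_MLA * M)

for emission wavelength lambda, Fourier-lens focal length f_FL, microlens
pitch d_MLA and objective magnification M.  The axial resolution depends
on the usable array radius d_max; the published expression's grouping is
typographically ambiguous, so selectable variants are provided and the
variant used is recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

AXIAL_VARIANTS = ("rxy2_over_lambda_dmax", "rxy2_over_2lambda_dmax")


@dataclass
class OpticalParams:
    """All lengths in the unit given by the field name; dimensionless M."""

    lambda_um: float
    f_fl_mm: float
    magnification: float
    d_mla_mm: float
    d_max_mm: float = 6.5
    na_ml: float | None = None

    def __post_init__(self) -> None:
        for name in ("lambda_um", "f_fl_mm", "magnification", "d_mla_mm", "d_max_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def lateral_resolution(p: OpticalParams) -> float:
    """Object-space lateral resolution R_xy in micrometers."""
    # f_FL / d_MLA is dimensionless (mm/mm); lambda carries the microns
    return p.lambda_um * (p.f_fl_mm / p.d_mla_mm) / p.magnification


def axial_resolution(p: OpticalParams, variant: str = "rxy2_over_lambda_dmax"):
    """Object-space axial resolution R_z in micrometers.

    ``rxy2_over_lambda_dmax``: R_z = d_MLA * R_xy^2 / (lambda * d_max)
    (the default, dimensionally consistent reading);
    ``rxy2_over_2lambda_dmax`` halves it.  Returns (value, metadata).
    """
    if variant not in AXIAL_VARIANTS:
        raise ConfigurationError(f"unknown axial variant {variant!r}; expected one of {AXIAL_VARIANTS}")
    rxy = lateral_resolution(p)
    d_mla_um = p.d_mla_mm * 1000.0
    d_max_um = p.d_max_mm * 1000.0
    rz = d_mla_um * rxy**2 / (p.lambda_um * d_max_um)
    if variant == "rxy2_over_2lambda_dmax":
        rz /= 2.0
    meta = {
        "variant": variant,
        "R_xy_um": rxy,
        "interpretation": "d_max is the usable microlens-array radius",
    }
    return rz, meta
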