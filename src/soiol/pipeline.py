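"""End-to-end per-eye calculation: biometry in millimetres -> IOL powers.

This is the single place where millimetre inputs (as biometers and the
clinical tables print them) are converted to the SI metres the vergence
formulas use.  The steps, in order:

1. Wang-Koch adjust the axial length (identity at or below 26 mm); the
   adjusted AL feeds both the ELP model and the vergence formula.
2. Predict the effective lens position with the Haigis linear model.
3. Evaluate the silicone-oil and water-filled emmetropizing IOL powers
   and their difference.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import optics_core
from .elp_model import (
    WANG_KOCH_HAIGIS,
    BiometryInputs,
    IOLConstants,
    WangKochCoefficients,
    a0_from_a_constant,
    haigis_elp,
    wang_koch_adjust,
)
from .optics_core import DEFAULT_MEDIA, EyeGeometry, OpticalMedia

__all__ = ["EyePowerResult", "DEFAULT_CONSTANTS", "compute_eye"]

MM_PER_M = 1000.0

#: Fallback constants when no IOL model is specified: A-constant 118
#: through the standard conversion (a nominal mid-range lens).
DEFAULT_CONSTANTS = a0_from_a_constant(118.0, model_name="default-A118")


@dataclass(frozen=True)
class EyePowerResult:
    """Per-eye outputs, in the units clinicians read (mm and D)."""

    elp_mm: float
    adjusted_al_mm: float
    so_power_d: float
    water_power_d: float
    delta_d: float
    constants: IOLConstants


def compute_eye(
    axial_length_mm: float,
    mean_k_d: float,
    acd_mm: float,
    constants: IOLConstants = DEFAULT_CONSTANTS,
    media: OpticalMedia = DEFAULT_MEDIA,
    wang_koch: WangKochCoefficients = WANG_KOCH_HAIGIS,
) -> EyePowerResult:
    """Full single-eye calculation from millimetre biometry."""
    inputs = BiometryInputs(axial_length_mm, acd_mm, mean_k_d)
    al_adj_mm = wang_koch_adjust(inputs.axial_length_mm, wang_koch)
    elp_mm = haigis_elp(
        BiometryInputs(al_adj_mm, acd_mm, mean_k_d), constants
    )
    geometry = EyeGeometry(
        axial_length=al_adj_mm / MM_PER_M,
        corneal_power=mean_k_d,
        elp=elp_mm / MM_PER_M,
        n_aqueous=media.n_aqueous,
    )
    return EyePowerResult(
        elp_mm=elp_mm,
        adjusted_al_mm=al_adj_mm,
        so_power_d=optics_core.so_iol_power(geometry, media),
        water_power_d=optics_core.water_iol_power(geometry, media),
        delta_d=optics_core.so_water_delta(geometry, media),
        constants=constants,
    )
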