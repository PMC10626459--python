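"""Effective lens position (ELP) prediction and axial-length preconditioning.

The ELP — the predicted distance from the posterior corneal vertex to the
IOL optical plane — follows the Haigis linear model

    ELP = a0 + a1 * AC + a2 * AL      (all in mm),

where ``AC`` is the preoperative anterior chamber depth, ``AL`` the axial
length, and ``(a0, a1, a2)`` constants optimized per IOL model.  When only
a manufacturer A-constant is known, the standard conversion yields the
default triple ``a1 = 0.4, a2 = 0.1`` with

    a0 = (0.62467 * A - 68.747) - 0.4 * 3.37 - 0.1 * 23.39,

i.e. the personalized-ACD regression recentred on population-mean anterior
chamber depth (3.37 mm) and axial length (23.39 mm).  This is a community
convention, not an optimized fit, and registry entries built this way are
marked as such.

Long eyes: optical biometers overestimate AL above ~26 mm; the Wang-Koch
linear adjustment (Haigis variant) replaces AL by ``slope*AL + intercept``
strictly above the 26 mm threshold.  The adjusted AL feeds both the ELP
model and the vergence formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError, DomainError, InputValidationError

__all__ = [
    "IOLConstants",
    "BiometryInputs",
    "WangKochCoefficients",
    "WANG_KOCH_HAIGIS",
    "haigis_elp",
    "wang_koch_adjust",
    "a0_from_a_constant",
    "load_constants_registry",
    "default_registry_path",
]

logger = logging.getLogger(__name__)

# Population means used by the classical A-constant -> Haigis-a0 recentring.
_POP_MEAN_AC_MM = 3.37
_POP_MEAN_AL_MM = 23.39


@dataclass(frozen=True)
class IOLConstants:
    """Haigis constant triple for one IOL model, with optional A-constant.

    ``source`` records provenance, e.g. ``"registry"`` for a supplied
    optimized triple or ``"A-constant conversion"`` for a synthesized one.
    """

    model_name: str
    a0: float
    a1: float
    a2: float
    a_constant: float | None = None
    source: str = "registry"

    def __post_init__(self) -> None:
        if not (0.0 <= self.a1 <= 1.0):
            raise InputValidationError(f"{self.model_name}: a1={self.a1} outside [0, 1]")
        if not (0.0 <= self.a2 <= 1.0):
            raise InputValidationError(f"{self.model_name}: a2={self.a2} outside [0, 1]")
        # ELP is affine in (AC, AL), so checking the corners of the
        # physiological box AL in [20, 30] mm, AC in [2, 4] mm bounds it.
        lo = self.a0 + 2.0 * self.a1 + 20.0 * self.a2
        hi = self.a0 + 4.0 * self.a1 + 30.0 * self.a2
        if not (2.0 < lo and hi < 9.0):
            raise InputValidationError(
                f"{self.model_name}: constants place ELP in [{lo:.2f}, {hi:.2f}] mm "
                "over AL 20-30 mm / AC 2-4 mm; expected within (2, 9) mm"
            )


@dataclass(frozen=True)
class BiometryInputs:
    """Preoperative biometry for one eye, in the units the biometer prints."""

    axial_length_mm: float
    anterior_chamber_depth_mm: float
    mean_k_d: float

    def __post_init__(self) -> None:
        if not (14.0 < self.axial_length_mm < 40.0):
            raise InputValidationError(
                f"axial_length_mm={self.axial_length_mm} outside (14, 40)"
            )
        if not (1.5 < self.anterior_chamber_depth_mm < 5.0):
            raise InputValidationError(
                f"anterior_chamber_depth_mm={self.anterior_chamber_depth_mm} "
                "outside (1.5, 5.0)"
            )
        if not (30.0 < self.mean_k_d < 60.0):
            raise InputValidationError(f"mean_k_d={self.mean_k_d} outside (30, 60)")


@dataclass(frozen=True)
class WangKochCoefficients:
    """Linear AL adjustment ``slope*AL + intercept`` applied above ``threshold_mm``."""

    slope: float = 0.9621
    intercept: float = 0.6763
    threshold_mm: float = 26.0
    source: str = "Wang-Koch first-generation linear, Haigis variant"


#: Default coefficients; overridable via config for other formula variants.
WANG_KOCH_HAIGIS = WangKochCoefficients()


def haigis_elp(inputs: BiometryInputs, constants: IOLConstants) -> float:
    """Predicted ELP in mm: ``a0 + a1*AC + a2*AL``.

    Callers handling long eyes must pass an already Wang-Koch-adjusted
    axial length (see :func:`wang_koch_adjust`).
    """
    elp = (
        constants.a0
        + constants.a1 * inputs.anterior_chamber_depth_mm
        + constants.a2 * inputs.axial_length_mm
    )
    if not (0.0 < elp < inputs.axial_length_mm):
        raise DomainError(
            f"ELP={elp:.2f} mm outside (0, AL={inputs.axial_length_mm} mm) "
            f"for constants {constants.model_name!r}"
        )
    return elp


def wang_koch_adjust(
    axial_length_mm: float,
    coefficients: WangKochCoefficients = WANG_KOCH_HAIGIS,
) -> float:
    """Adjusted axial length in mm; identity at or below the threshold."""
    if axial_length_mm <= 0:
        raise InputValidationError(f"axial_length_mm={axial_length_mm} must be > 0")
    if axial_length_mm <= coefficients.threshold_mm:
        return axial_length_mm
    adjusted = coefficients.slope * axial_length_mm + coefficients.intercept
    if adjusted <= 0:
        raise ConfigError(
            f"Wang-Koch coefficients {coefficients} map AL {axial_length_mm} mm "
            f"to non-positive {adjusted} mm"
        )
    return adjusted


def a0_from_a_constant(
    a_constant: float, model_name: str = "unnamed"
) -> IOLConstants:
    """Synthesize a default Haigis triple from a manufacturer A-constant.

    ``a1 = 0.4``, ``a2 = 0.1`` and ``a0`` from the classical
    personalized-ACD conversion recentred on population means (module
    docstring).  Provenance is recorded as ``"A-constant conversion"``.
    """
    if not (110.0 < a_constant < 125.0):
        raise InputValidationError(f"a_constant={a_constant} outside (110, 125)")
    acd_const = 0.62467 * a_constant - 68.747
    a0 = acd_const - 0.4 * _POP_MEAN_AC_MM - 0.1 * _POP_MEAN_AL_MM
    return IOLConstants(
        model_name=model_name,
        a0=a0,
        a1=0.4,
        a2=0.1,
        a_constant=a_constant,
        source="A-constant conversion",
    )


def default_registry_path() -> Path:
    """Path of the packaged IOL-constant registry (A-constant stubs)."""
    return Path(__file__).parent / "data" / "constants.yaml"


def load_constants_registry(path: str | Path | None = None) -> dict[str, IOLConstants]:
    """Load a YAML registry mapping IOL model names to Haigis constants.

    The file holds a top-level list of mappings with keys ``model_name``
    and either a full ``(a0, a1, a2)`` triple or an ``a_constant`` (triple
    wins when both are present; the A-constant is kept as metadata).
    An empty file yields an empty registry with a logged warning.
    """
    path = Path(path) if path is not None else default_registry_path()
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if raw is None:
        logger.warning("constants registry %s is empty", path)
        return {}
    if not isinstance(raw, list):
        raise ConfigError(f"{path}: expected a top-level list of entries")
    registry: dict[str, IOLConstants] = {}
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict) or "model_name" not in entry:
            raise ConfigError(f"{path}: entry {i} lacks model_name")
        name = str(entry["model_name"])
        if name in registry:
            raise ConfigError(f"{path}: duplicate model_name {name!r}")
        has_triple = all(k in entry and entry[k] is not None for k in ("a0", "a1", "a2"))
        a_const = entry.get("a_constant")
        if has_triple:
            registry[name] = IOLConstants(
                model_name=name,
                a0=float(entry["a0"]),
                a1=float(entry["a1"]),
                a2=float(entry["a2"]),
                a_constant=float(a_const) if a_const is not None else None,
                source=str(entry.get("source", "registry")),
            )
        elif a_const is not None:
            registry[name] = a0_from_a_constant(float(a_const), model_name=name)
        else:
            raise ConfigError(
                f"{path}: entry {name!r} has neither (a0,a1,a2) nor a_constant"
            )
    return registry
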