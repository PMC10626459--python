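"""Packaged clinical tables, strict CSV I/O and a synthetic biometry generator.

Two cohorts ship with the package, transcribed cell-for-cell from the
source study:

* ``group_a`` — 13 silicone-oil-dependent eyes (oil retained long term;
  secondary IOL implantation), including diagnoses and logMAR visual
  acuities;
* ``group_b`` — 19 eyes with silicone-oil tamponade and first-stage IOL
  implantation (oil later removed), biometry and powers only.

Ages are recorded as decade strings ("50s") and never parsed to numbers.
The per-row IOL model is unknown (the source lists only the pooled set of
six models), so ``iol_model`` is optional and empty in the fixtures.

The synthetic generator draws truncated-normal biometry matched to the
silicone-oil-dependent cohort's summary statistics and synthesizes
plausible implanted-power/refraction outcomes around the theoretical
power, for property tests and pipeline exercises.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import InputValidationError

__all__ = [
    "BiometryRecord",
    "SyntheticParams",
    "PACKAGED_TABLES",
    "load_table",
    "write_table",
    "generate_synthetic",
]

_DATA_DIR = Path(__file__).parent / "data"

PACKAGED_TABLES = {
    "group_a": _DATA_DIR / "group_a.csv",
    "group_b": _DATA_DIR / "group_b.csv",
}

CSV_HEADER = [
    "patient_id",
    "age_decade",
    "sex",
    "axial_length_mm",
    "mean_k_d",
    "acd_mm",
    "iol_model",
    "implanted_power_d",
    "postop_sphere_d",
    "theoretical_power_d",
    "diagnosis",
    "va_preop_uc",
    "va_preop_cc",
    "va_postop_cc",
]

_REQUIRED_FLOATS = {
    "axial_length_mm": (14.0, 40.0),
    "mean_k_d": (30.0, 60.0),
    "acd_mm": (1.5, 5.0),
    "implanted_power_d": (0.0, 40.0),
    "postop_sphere_d": (-15.0, 15.0),
}
_OPTIONAL_FLOATS = {
    "theoretical_power_d": (0.0, 40.0),
    "va_preop_uc": (-0.3, 3.0),
    "va_preop_cc": (-0.3, 3.0),
    "va_postop_cc": (-0.3, 3.0),
}


@dataclass(frozen=True)
class BiometryRecord:
    """One eye's measured inputs plus implanted-lens outcome."""

    patient_id: str
    age_decade: str
    sex: str
    axial_length_mm: float
    mean_k_d: float
    acd_mm: float
    implanted_power_d: float
    postop_sphere_d: float
    iol_model: str | None = None
    theoretical_power_d: float | None = None
    diagnosis: str | None = None
    va_preop_uc: float | None = None
    va_preop_cc: float | None = None
    va_postop_cc: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise InputValidationError(
                f"{self.patient_id}: sex={self.sex!r} not in {{M, F}}"
            )
        for name, (lo, hi) in _REQUIRED_FLOATS.items():
            v = getattr(self, name)
            if not (lo < v < hi):
                raise InputValidationError(
                    f"{self.patient_id}: {name}={v} outside ({lo}, {hi})"
                )
        for name, (lo, hi) in _OPTIONAL_FLOATS.items():
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise InputValidationError(
                    f"{self.patient_id}: {name}={v} outside [{lo}, {hi}]"
                )


def _parse_row(row: dict[str, str], line_no: int) -> BiometryRecord:
    kwargs: dict[str, object] = {}
    for f in dc_fields(BiometryRecord):
        raw = (row.get(f.name) or "").strip()
        if f.name in ("patient_id", "age_decade", "sex"):
            if not raw:
                raise InputValidationError(f"row {line_no}: missing {f.name}")
            kwargs[f.name] = raw
        elif f.name in ("iol_model", "diagnosis"):
            kwargs[f.name] = raw or None
        elif f.name in _REQUIRED_FLOATS:
            if not raw:
                raise InputValidationError(f"row {line_no}: missing {f.name}")
            try:
                kwargs[f.name] = float(raw)
            except ValueError as exc:
                raise InputValidationError(
                    f"row {line_no}: unparseable {f.name}={raw!r}"
                ) from exc
        else:  # optional floats
            if raw:
                try:
                    kwargs[f.name] = float(raw)
                except ValueError as exc:
                    raise InputValidationError(
                        f"row {line_no}: unparseable {f.name}={raw!r}"
                    ) from exc
            else:
                kwargs[f.name] = None
    return BiometryRecord(**kwargs)  # type: ignore[arg-type]


def load_table(name_or_path: str | Path) -> list[BiometryRecord]:
    """Read a biometry CSV (packaged name ``"group_a"``/``"group_b"`` or a path).

    Strict: the documented header must be present and every cell must parse
    and pass range validation; failures name the row and field.
    """
    path = PACKAGED_TABLES.get(str(name_or_path), Path(name_or_path))
    if not path.exists():
        raise InputValidationError(
            f"no packaged table or file named {name_or_path!r} "
            f"(packaged: {sorted(PACKAGED_TABLES)})"
        )
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_HEADER if c not in header]
        if missing:
            raise InputValidationError(f"{path}: missing columns {missing}")
        records = [_parse_row(row, i) for i, row in enumerate(reader, start=2)]
    return records


def write_table(records: list[BiometryRecord], path: str | Path) -> None:
    """Write records back to the documented CSV dialect (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_HEADER)
        writer.writeheader()
        for r in records:
            row = {c: getattr(r, c) for c in CSV_HEADER}
            writer.writerow({k: ("" if v is None else v) for k, v in row.items()})


@dataclass(frozen=True)
class SyntheticParams:
    """Truncated-normal biometry distributions for the synthetic cohort.

    Defaults match the silicone-oil-dependent cohort's summaries:
    AL 22.8 +/- 1.3 mm on (20, 30), K 43.9 +/- 1.8 D on (38, 48),
    ACD 2.94 +/- 0.31 mm on (2, 4.5).  ``sphere_noise_sd_d`` injects
    spherical-equivalent outcome noise (D) around the theoretical power.
    """

    al_mean: float = 22.8
    al_sd: float = 1.3
    al_bounds: tuple[float, float] = (20.0, 30.0)
    k_mean: float = 43.9
    k_sd: float = 1.8
    k_bounds: tuple[float, float] = (38.0, 48.0)
    acd_mean: float = 2.94
    acd_sd: float = 0.31
    acd_bounds: tuple[float, float] = (2.0, 4.5)
    sphere_noise_sd_d: float = 0.6

    def __post_init__(self) -> None:
        for sd in (self.al_sd, self.k_sd, self.acd_sd):
            if sd <= 0:
                raise InputValidationError(f"non-positive SD {sd}")
        if self.sphere_noise_sd_d < 0:
            raise InputValidationError("sphere_noise_sd_d must be >= 0")


def _truncnorm(rng, mean, sd, bounds, n):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_synthetic(
    n: int,
    seed: int,
    params: SyntheticParams = SyntheticParams(),
) -> list[BiometryRecord]:
    """Draw ``n`` reproducible synthetic eyes.

    Biometry is truncated-normal per ``params``; the theoretical
    silicone-oil IOL power is computed with the default A-constant (118)
    Haigis triple, the implanted power is that value rounded to the 0.5 D
    steps lenses come in, and the postoperative sphere is the remainder
    plus Gaussian noise — so the synthetic validation pipeline sees
    outcomes scattered around its own predictions.
    """
    from .pipeline import compute_eye  # local import: avoids a cycle

    if n < 1:
        raise InputValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    al = _truncnorm(rng, params.al_mean, params.al_sd, params.al_bounds, n)
    k = _truncnorm(rng, params.k_mean, params.k_sd, params.k_bounds, n)
    acd = _truncnorm(rng, params.acd_mean, params.acd_sd, params.acd_bounds, n)
    noise = rng.normal(0.0, params.sphere_noise_sd_d or 1e-12, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    decades = rng.choice(["40s", "50s", "60s", "70s"], size=n)

    records = []
    for i in range(n):
        result = compute_eye(al[i], k[i], acd[i])
        theoretical = result.so_power_d
        implanted = float(np.clip(np.round(theoretical * 2) / 2, 0.5, 39.5))
        sphere = float(np.clip(theoretical - implanted + noise[i], -14.9, 14.9))
        records.append(
            BiometryRecord(
                patient_id=f"S{i + 1:04d}",
                age_decade=str(decades[i]),
                sex=str(sexes[i]),
                axial_length_mm=float(al[i]),
                mean_k_d=float(k[i]),
                acd_mm=float(acd[i]),
                implanted_power_d=implanted,
                postop_sphere_d=sphere,
                theoretical_power_d=float(np.clip(theoretical, 0.05, 39.95)),
            )
        )
    return records
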