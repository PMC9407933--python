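"""Ergonomic assessment of product/task layouts against a strength field.

Each task point (e.g., a shelf position an object is lifted from) carries
a required upward force.  The assessment compares that requirement with
the allowable force F_d = k*F available at the point, where F is the
laboratory limit force from the strength field and k in (0, 1] is the
working-conditions correction.  Verdicts:

* ``OK`` — inside the reach boundary with F_d >= required force;
* ``FORCE_INADEQUATE`` — reachable, but the available force falls short;
* ``OUT_OF_REACH`` — beyond the reach boundary (or outside the modeled
  angular/height region, flagged in the note); available force 0.

Constant-strength layers of the rescaled field can be exported as ASCII
OBJ/STL meshes for CAD placement of the layout.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core_model import (
    REACH_TOL,
    StrengthField,
    extract_constant_strength_layer,
    rescale_forces,
)
from .errors import SchemaError, ValidationError

LAYOUT_COLUMNS = ("label", "alpha_deg", "z_cm", "r_cm", "required_force_N")
REPORT_SCHEMA_VERSION = "1.0"


class Verdict(str, enum.Enum):
    OK = "OK"
    FORCE_INADEQUATE = "FORCE_INADEQUATE"
    OUT_OF_REACH = "OUT_OF_REACH"


@dataclass(frozen=True)
class TaskPoint:
    """A layout point in the body-centered cylindrical frame with its force demand."""

    label: str
    alpha: float  # degrees
    z: float  # cm
    r: float  # cm
    required_force: float  # newtons, upward lift

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValidationError(f"task point {self.label!r}: radius must be >= 0, got {self.r}")
        if self.required_force < 0:
            raise ValidationError(
                f"task point {self.label!r}: required force must be >= 0, got {self.required_force}"
            )


@dataclass(frozen=True)
class BodyPlacement:
    """Rigid placement of the body frame in a room: position (cm) + facing angle.

    ``facing_deg`` is the room-frame direction of the sagittal axis
    (alpha = 0); positive alpha turns toward the measured limb's side.
    """

    x: float = 0.0
    y: float = 0.0
    facing_deg: float = 0.0


def task_point_from_room(
    label: str,
    x: float,
    y: float,
    z: float,
    required_force: float,
    placement: BodyPlacement = BodyPlacement(),
) -> TaskPoint:
    """Convert a room-frame point (cm) to a body-frame task point."""
    dx = x - placement.x
    dy = y - placement.y
    r = math.hypot(dx, dy)
    alpha = math.degrees(math.atan2(dy, dx)) - placement.facing_deg
    alpha = (alpha + 180.0) % 360.0 - 180.0
    return TaskPoint(label=label, alpha=alpha, z=z, r=r, required_force=required_force)


@dataclass(frozen=True)
class PointAssessment:
    point: TaskPoint
    verdict: Verdict
    available_force: float  # F_d at the point (0 when out of reach)
    margin: float  # available - required
    note: str = ""


@dataclass(frozen=True)
class LayoutReport:
    """Per-point verdicts for a whole layout, in input order."""

    assessments: tuple[PointAssessment, ...]
    fd_scale: float = 1.0

    def __len__(self) -> int:
        return len(self.assessments)

    def __iter__(self):
        return iter(self.assessments)

    @property
    def all_ok(self) -> bool:
        return all(a.verdict is Verdict.OK for a in self.assessments)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "fd_scale": self.fd_scale,
            "points": [
                {
                    "label": a.point.label,
                    "alpha_deg": a.point.alpha,
                    "z_cm": a.point.z,
                    "r_cm": a.point.r,
                    "required_force_N": a.point.required_force,
                    "verdict": a.verdict.value,
                    "available_force_N": round(a.available_force, 3),
                    "margin_N": round(a.margin, 3),
                    "note": a.note,
                }
                for a in self.assessments
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def assess_point(field: StrengthField, point: TaskPoint, fd_scale: float = 1.0) -> PointAssessment:
    """Assess one task point: reachability and force adequacy under F_d = k*F."""
    if not (0 < fd_scale <= 1):
        raise ValidationError(f"fd_scale must lie in (0, 1], got {fd_scale}")
    if not field.in_extent(point.alpha, point.z):
        return PointAssessment(
            point=point,
            verdict=Verdict.OUT_OF_REACH,
            available_force=0.0,
            margin=-point.required_force,
            note="outside modeled region",
        )
    reach = field.reach_at(point.alpha, point.z)
    if point.r > reach + REACH_TOL:
        return PointAssessment(
            point=point,
            verdict=Verdict.OUT_OF_REACH,
            available_force=0.0,
            margin=-point.required_force,
            note=f"beyond reach boundary ({reach:.1f} cm)",
        )
    available = fd_scale * field.value_at(point.alpha, point.z, point.r)
    margin = available - point.required_force
    verdict = Verdict.OK if margin >= 0 else Verdict.FORCE_INADEQUATE
    return PointAssessment(point=point, verdict=verdict, available_force=available, margin=margin)


def assess_layout(
    field: StrengthField, points: Sequence[TaskPoint], fd_scale: float = 1.0
) -> LayoutReport:
    """Assess every task point; an empty layout yields an empty report."""
    return LayoutReport(
        assessments=tuple(assess_point(field, p, fd_scale) for p in points),
        fd_scale=fd_scale,
    )


def export_layers(
    field: StrengthField,
    levels: Sequence[float],
    out_dir: str | Path,
    fd_scale: float = 1.0,
    fmt: str = "obj",
) -> list[Path]:
    """Export constant-strength layers of the F_d field as mesh files.

    Levels are allowable-force values in newtons; one ``layer_<level>N``
    file per level is written to ``out_dir``.  Nested levels produce
    nested surfaces.
    """
    if not levels:
        raise ValidationError("need at least one layer level to export")
    if any(l <= 0 for l in levels):
        raise ValidationError(f"layer levels must be positive, got {list(levels)}")
    if fmt not in ("obj", "stl"):
        raise ValidationError(f"format must be 'obj' or 'stl', got {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fd_field = rescale_forces(field, fd_scale)
    paths = []
    for level in levels:
        layer = extract_constant_strength_layer(fd_field, level)
        name = f"layer_{level:g}N.{fmt}"
        paths.append(layer.export_mesh(out_dir / name))
    return paths


def load_layout(path: str | Path) -> list[TaskPoint]:
    """Read a layout CSV (``label,alpha_deg,z_cm,r_cm,required_force_N``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"label": str})
    except Exception as e:
        raise SchemaError(f"{path}: cannot parse CSV ({e})") from e
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    points = []
    for pos, rec in enumerate(df.itertuples(index=False)):
        try:
            points.append(
                TaskPoint(
                    label=str(rec.label),
                    alpha=float(rec.alpha_deg),
                    z=float(rec.z_cm),
                    r=float(rec.r_cm),
                    required_force=float(rec.required_force_N),
                )
            )
        except (TypeError, ValueError) as e:
            if isinstance(e, ValidationError):
                raise
            raise SchemaError(f"{path}: row {pos + 1}: non-numeric coordinate ({e})") from None
    return points
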