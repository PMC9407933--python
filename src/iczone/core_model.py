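"""Core domain model for Individual Convenient Zones (ICZ).

An ICZ describes the space one upper limb can reach, annotated at every
point with the maximum *upward* force the person can exert there.  Points
live in a body-centered cylindrical frame:

* ``alpha`` — angle in degrees about the vertical body axis; 0 is the
  sagittal plane, positive toward the measured limb's side;
* ``z`` — height in cm above the floor;
* ``r`` — radial distance in cm from the body axis.

The raw laboratory product is a cloud of :class:`StrengthSample` points.
:func:`build_strength_field` turns the cloud into a
:class:`StrengthField` — forces on a regular (alpha, z, r) lattice —
using piecewise-linear interpolation along each measured ray followed by
isotonic (monotone non-increasing in r) regression, because liftable
force physically decreases as the hand moves away from the body.
Constant-strength layers (iso-force surfaces) are then extracted with
:func:`extract_constant_strength_layer`, and laboratory limit forces F
can be proportionally reduced to allowable working forces F_d with
:func:`rescale_forces`.

The five-feature simplified characterization (F1–F4 in newtons, D1 in
cm) used for repository matching is computed by
:func:`extract_simplified_features`.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import CoverageError, SchemaError, ValidationError

SCHEMA_VERSION = "1.0"

#: absolute tolerance (cm) when comparing radii against a reach boundary
REACH_TOL = 1e-6

_RAY_DECIMALS = 6  # rounding used to group samples into (alpha, z) rays


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnthropometricProfile:
    """Static body dimensions of one subject.

    Lengths are in cm, mass in kg.  ``limb_side`` records which limb the
    strength data describe (mirroring is a stored flag, never a geometric
    transform of the data).  ``reach_convention`` records whether reach
    distances are measured to the handgrip axis or to the fingertips.
    """

    subject_id: str
    body_height: float
    shoulder_height: float
    elbow_height: float
    body_mass: float
    age: float | None = None
    notes: str | None = None
    limb_side: str = "right"
    reach_convention: str = "handgrip"

    def __post_init__(self) -> None:
        for name in ("body_height", "shoulder_height", "elbow_height", "body_mass"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be a strictly positive number, got {v!r}")
        if not (self.elbow_height < self.shoulder_height < self.body_height):
            raise ValidationError(
                "expected elbow_height < shoulder_height < body_height, got "
                f"{self.elbow_height} / {self.shoulder_height} / {self.body_height} cm"
            )
        if self.limb_side not in ("left", "right"):
            raise ValidationError(f"limb_side must be 'left' or 'right', got {self.limb_side!r}")
        if self.reach_convention not in ("handgrip", "fingertip"):
            raise ValidationError(
                f"reach_convention must be 'handgrip' or 'fingertip', got {self.reach_convention!r}"
            )


@dataclass(frozen=True)
class StrengthSample:
    """One force measurement: max upward force (N) at a point of the reach space."""

    alpha: float  # degrees
    z: float  # cm above floor
    r: float  # cm from body axis
    force: float  # newtons

    def __post_init__(self) -> None:
        if not (-180.0 <= self.alpha <= 180.0):
            raise ValidationError(f"alpha must lie in [-180, 180] degrees, got {self.alpha}")
        if self.r < 0:
            raise ValidationError(f"radius must be non-negative, got {self.r}")
        if not (math.isfinite(self.force) and self.force >= 0):
            raise ValidationError(f"force must be finite and non-negative, got {self.force}")

    @property
    def ray(self) -> tuple[float, float]:
        """The (alpha, z) ray this sample belongs to."""
        return (round(self.alpha, _RAY_DECIMALS), round(self.z, _RAY_DECIMALS))


@dataclass(frozen=True)
class GridSpec:
    """Lattice resolution for field construction: 5 deg x 5 cm x 1 cm by default."""

    d_alpha: float = 5.0
    d_z: float = 5.0
    d_r: float = 1.0

    def __post_init__(self) -> None:
        for name in ("d_alpha", "d_z", "d_r"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass
class ICZModel:
    """A subject's full spatial-strength characteristic.

    ``samples`` is the measured point cloud; ``reach_boundary`` optionally
    maps an (alpha, z) ray to its maximum reach radius in cm.  Where no
    boundary is supplied the largest measured radius on the ray is used.
    """

    profile: AnthropometricProfile
    samples: tuple[StrengthSample, ...]
    reach_boundary: dict[tuple[float, float], float] | None = None

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        if not self.samples:
            raise ValidationError("an ICZ model needs at least one strength sample")
        if self.reach_boundary is not None:
            rb = {
                (round(a, _RAY_DECIMALS), round(z, _RAY_DECIMALS)): float(r)
                for (a, z), r in self.reach_boundary.items()
            }
            self.reach_boundary = rb
            for s in self.samples:
                reach = rb.get(s.ray)
                if reach is not None and s.r > reach + REACH_TOL:
                    raise ValidationError(
                        f"sample at {s.ray} has r={s.r} cm beyond its reach boundary {reach} cm"
                    )

    def rays(self) -> dict[tuple[float, float], list[StrengthSample]]:
        """Group samples by (alpha, z) ray."""
        out: dict[tuple[float, float], list[StrengthSample]] = {}
        for s in self.samples:
            out.setdefault(s.ray, []).append(s)
        return out

    def reach_for(self, alpha: float, z: float) -> float:
        """Reach radius (cm) for a measured ray: supplied boundary or max sampled r."""
        key = (round(alpha, _RAY_DECIMALS), round(z, _RAY_DECIMALS))
        if self.reach_boundary and key in self.reach_boundary:
            return self.reach_boundary[key]
        rs = [s.r for s in self.samples if s.ray == key]
        if not rs:
            raise CoverageError(f"no samples on ray (alpha={alpha} deg, z={z} cm)")
        return max(rs)


@dataclass(frozen=True)
class SimplifiedFeatures:
    """The five-value quick characterization of a person.

    f1–f4 are upward-force values in newtons, d1 is the anterior reach in
    cm at shoulder height in the sagittal plane:

    * f1 — force at full reach D1, shoulder height, alpha = 0;
    * f2 — force at full reach, shoulder height, alpha = 60 deg;
    * f3 — force at mid-reach D1/2, shoulder height, alpha = 0;
    * f4 — force at full reach, elbow height, alpha = 0.
    """

    f1: float
    f2: float
    f3: float
    f4: float
    d1: float
    profile: AnthropometricProfile | None = None

    def __post_init__(self) -> None:
        for name in ("f1", "f2", "f3", "f4", "d1"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be strictly positive, got {v!r}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.f1, self.f2, self.f3, self.f4, self.d1)


# ---------------------------------------------------------------------------
# lattice helpers
# ---------------------------------------------------------------------------


def _lattice(lo: float, hi: float, step: float) -> np.ndarray:
    """Regular 1-D lattice from lo to hi (inclusive; hi appended if off-step)."""
    if hi < lo:
        raise ValidationError(f"lattice bounds out of order: [{lo}, {hi}]")
    n = int(math.floor((hi - lo) / step + 1e-9))
    pts = lo + step * np.arange(n + 1, dtype=float)
    if hi - pts[-1] > 1e-9:
        pts = np.append(pts, hi)
    return pts


def _grid_eval(
    grids: Sequence[np.ndarray], values: np.ndarray, point: Sequence[float]
) -> float:
    """Multilinear interpolation on a rectilinear grid; coordinates are clamped
    to the grid extent.  Size-1 dimensions are passed through."""
    corners: list[tuple[int, int]] = []
    weights: list[float] = []
    for g, x in zip(grids, point):
        if g.size == 1:
            corners.append((0, 0))
            weights.append(0.0)
            continue
        x = min(max(float(x), float(g[0])), float(g[-1]))
        i = int(np.searchsorted(g, x, side="right")) - 1
        i = min(max(i, 0), g.size - 2)
        corners.append((i, i + 1))
        weights.append((x - g[i]) / (g[i + 1] - g[i]))
    out = 0.0
    for choice in itertools.product((0, 1), repeat=len(grids)):
        w = 1.0
        idx = []
        for (lohi, t, c) in zip(corners, weights, choice):
            idx.append(lohi[c])
            w *= t if c else (1.0 - t)
        if w:
            out += w * float(values[tuple(idx)])
    return out


def enforce_monotone_decreasing(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Project force values onto the monotone non-increasing cone along r.

    This is least-squares isotonic regression (pool-adjacent-violators);
    already-monotone inputs are returned unchanged.
    """
    r = np.asarray(r, dtype=float)
    f = np.asarray(f, dtype=float)
    if r.shape != f.shape or r.ndim != 1:
        raise ValidationError("r and f must be 1-D arrays of equal length")
    if f.size <= 1:
        return f.copy()
    return IsotonicRegression(increasing=False).fit_transform(r, f)


# ---------------------------------------------------------------------------
# strength field
# ---------------------------------------------------------------------------


@dataclass
class StrengthField:
    """Interpolated upward-force field on a regular (alpha, z, r) lattice.

    ``values`` has shape (len(alphas), len(zs), len(rs)) and is monotone
    non-increasing along the r axis; nodes beyond the local reach hold 0.
    ``reach`` has shape (len(alphas), len(zs)).
    """

    alphas: np.ndarray
    zs: np.ndarray
    rs: np.ndarray
    values: np.ndarray
    reach: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.zs = np.asarray(self.zs, dtype=float)
        self.rs = np.asarray(self.rs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.reach = np.asarray(self.reach, dtype=float)
        expect = (self.alphas.size, self.zs.size, self.rs.size)
        if self.values.shape != expect:
            raise ValidationError(f"values shape {self.values.shape} != lattice shape {expect}")
        if self.reach.shape != expect[:2]:
            raise ValidationError(f"reach shape {self.reach.shape} != {expect[:2]}")
        if np.any(self.values < 0):
            raise ValidationError("field values must be non-negative")

    # -- queries ------------------------------------------------------------

    def in_extent(self, alpha: float, z: float) -> bool:
        """Whether (alpha, z) lies inside the modeled angular/height region."""
        tol = 1e-9
        return bool(
            self.alphas[0] - tol <= alpha <= self.alphas[-1] + tol
            and self.zs[0] - tol <= z <= self.zs[-1] + tol
        )

    def value_at(self, alpha: float, z: float, r: float) -> float:
        """Trilinearly interpolated force (N); 0 beyond the radial lattice."""
        if not self.in_extent(alpha, z):
            raise ValidationError(
                f"point (alpha={alpha}, z={z}) is outside the modeled region "
                f"alpha in [{self.alphas[0]}, {self.alphas[-1]}], z in [{self.zs[0]}, {self.zs[-1]}]"
            )
        if r > self.rs[-1] + REACH_TOL:
            return 0.0
        return _grid_eval((self.alphas, self.zs, self.rs), self.values, (alpha, z, r))

    def reach_at(self, alpha: float, z: float) -> float:
        """Bilinearly interpolated reach radius (cm) for a ray."""
        if not self.in_extent(alpha, z):
            raise ValidationError(f"ray (alpha={alpha}, z={z}) is outside the modeled region")
        return _grid_eval((self.alphas, self.zs), self.reach, (alpha, z))

    def boundary_force(self, alpha: float, z: float) -> float:
        """Force at the reach boundary of a ray, evaluated at the last lattice
        radius inside the reach (so at most one radial step short of it)."""
        reach = self.reach_at(alpha, z)
        inside = self.rs[self.rs <= reach + REACH_TOL]
        return self.value_at(alpha, z, float(inside[-1]))

    @property
    def max_force(self) -> float:
        return float(self.values.max())


def build_strength_field(model: ICZModel, grid_spec: GridSpec | None = None) -> StrengthField:
    """Interpolate a measured point cloud onto a regular lattice.

    Along each measured (alpha, z) ray the samples are averaged per radius,
    projected onto the monotone non-increasing cone (isotonic regression),
    and linearly interpolated in r (linearly extrapolated below the
    innermost sample, zero beyond the ray's reach).  Across rays the field
    is bilinearly interpolated in (alpha, z); the measured rays must
    therefore form a complete alpha x z grid.

    Raises :class:`CoverageError` when a ray has fewer than 3 distinct
    radii or the ray grid is incomplete.
    """
    gs = grid_spec or GridSpec()
    rays = model.rays()
    for (a, z), pts in rays.items():
        if len({round(p.r, _RAY_DECIMALS) for p in pts}) < 3:
            raise CoverageError(
                f"ray (alpha={a} deg, z={z} cm) has fewer than 3 distinct radii; "
                "interpolation needs at least 3"
            )
    meas_a = np.array(sorted({a for a, _ in rays}))
    meas_z = np.array(sorted({z for _, z in rays}))
    missing = [(a, z) for a in meas_a for z in meas_z if (float(a), float(z)) not in rays]
    if missing:
        raise CoverageError(
            "measured rays do not form a complete alpha x z grid; "
            f"missing rays include {missing[:5]}"
        )

    reach_grid = np.empty((meas_a.size, meas_z.size))
    for i, a in enumerate(meas_a):
        for j, z in enumerate(meas_z):
            reach_grid[i, j] = model.reach_for(float(a), float(z))

    alphas = _lattice(float(meas_a[0]), float(meas_a[-1]), gs.d_alpha)
    zs = _lattice(float(meas_z[0]), float(meas_z[-1]), gs.d_z)
    rs = _lattice(0.0, float(reach_grid.max()), gs.d_r)

    ray_vals = np.empty((meas_a.size, meas_z.size, rs.size))
    for i, a in enumerate(meas_a):
        for j, z in enumerate(meas_z):
            pts = rays[(float(a), float(z))]
            by_r: dict[float, list[float]] = {}
            for p in pts:
                by_r.setdefault(round(p.r, _RAY_DECIMALS), []).append(p.force)
            r_arr = np.array(sorted(by_r))
            f_arr = np.array([float(np.mean(by_r[r])) for r in r_arr])
            f_mono = enforce_monotone_decreasing(r_arr, f_arr)
            ray_vals[i, j] = _eval_ray(rs, r_arr, f_mono, reach_grid[i, j])

    values = _interp_across_rays(meas_a, meas_z, ray_vals, alphas, zs)
    reach = _interp_across_rays(meas_a, meas_z, reach_grid[:, :, None], alphas, zs)[:, :, 0]

    values[rs[None, None, :] > reach[:, :, None] + REACH_TOL] = 0.0
    values = np.minimum.accumulate(values, axis=2)  # safety: keep monotone after blending
    np.clip(values, 0.0, None, out=values)
    return StrengthField(alphas, zs, rs, values, reach, source_id=model.profile.subject_id)


def _eval_ray(rs: np.ndarray, r_arr: np.ndarray, f_arr: np.ndarray, reach: float) -> np.ndarray:
    """Evaluate one monotone ray on the radial lattice."""
    if r_arr.size == 1:
        vals = np.full(rs.shape, f_arr[0])
    else:
        vals = np.interp(rs, r_arr, f_arr)
        below = rs < r_arr[0]
        if below.any():
            # extrapolate toward the body axis with the innermost slope
            slope = (f_arr[1] - f_arr[0]) / (r_arr[1] - r_arr[0])
            vals[below] = f_arr[0] + slope * (rs[below] - r_arr[0])
    vals[rs > reach + REACH_TOL] = 0.0
    np.clip(vals, 0.0, None, out=vals)
    return vals


def _interp_across_rays(
    meas_a: np.ndarray,
    meas_z: np.ndarray,
    ray_vals: np.ndarray,
    alphas: np.ndarray,
    zs: np.ndarray,
) -> np.ndarray:
    """Bilinear interpolation of per-ray radial profiles onto lattice rays."""
    out = np.empty((alphas.size, zs.size, ray_vals.shape[2]))
    for i, a in enumerate(alphas):
        for j, z in enumerate(zs):
            wa = _lin_weights(meas_a, a)
            wz = _lin_weights(meas_z, z)
            acc = np.zeros(ray_vals.shape[2])
            for ia, ca in wa:
                for iz, cz in wz:
                    if ca * cz:
                        acc += ca * cz * ray_vals[ia, iz]
            out[i, j] = acc
    return out


def _lin_weights(grid: np.ndarray, x: float) -> list[tuple[int, float]]:
    if grid.size == 1:
        return [(0, 1.0)]
    x = min(max(float(x), float(grid[0])), float(grid[-1]))
    i = int(np.searchsorted(grid, x, side="right")) - 1
    i = min(max(i, 0), grid.size - 2)
    t = (x - grid[i]) / (grid[i + 1] - grid[i])
    return [(i, 1.0 - t), (i + 1, t)]


# ---------------------------------------------------------------------------
# constant-strength layers
# ---------------------------------------------------------------------------


@dataclass
class ConstantStrengthLayer:
    """Iso-force surface of a strength field at a fixed level (N).

    ``boundary[i, j]`` is the largest radius (cm) at which the field still
    reaches ``level`` on ray (alphas[i], zs[j]); 0 where it never does.
    ``empty`` flags a level above the field's global maximum.
    """

    level: float
    alphas: np.ndarray
    zs: np.ndarray
    boundary: np.ndarray
    empty: bool = False

    def boundary_at(self, alpha: float, z: float) -> float:
        return _grid_eval((self.alphas, self.zs), self.boundary, (alpha, z))

    def contains(self, alpha: float, z: float, r: float) -> bool:
        """Whether a point lies inside (or on) the layer surface."""
        return r <= self.boundary_at(alpha, z) + REACH_TOL

    # -- mesh export --------------------------------------------------------

    def to_mesh(self):
        """Triangulate the boundary surface (cm, right-handed, z up).

        Returns a ``trimesh.Trimesh``.  Requires at least a 2 x 2
        (alpha, z) grid.
        """
        import trimesh

        na, nz = self.boundary.shape
        if na < 2 or nz < 2:
            raise ValidationError("mesh export needs at least a 2 x 2 (alpha, z) grid")
        ar = np.radians(self.alphas)
        verts = np.empty((na * nz, 3))
        for i in range(na):
            for j in range(nz):
                b = self.boundary[i, j]
                verts[i * nz + j] = (b * math.cos(ar[i]), b * math.sin(ar[i]), self.zs[j])
        faces = []
        for i in range(na - 1):
            for j in range(nz - 1):
                v00 = i * nz + j
                v01 = v00 + 1
                v10 = v00 + nz
                v11 = v10 + 1
                faces.append((v00, v10, v11))
                faces.append((v00, v11, v01))
        return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)

    def export_mesh(self, path: str | Path) -> Path:
        """Write the layer surface as ASCII OBJ or ASCII STL (by extension)."""
        path = Path(path)
        mesh = self.to_mesh()
        if path.suffix.lower() == ".obj":
            text = mesh.export(file_type="obj")
        elif path.suffix.lower() == ".stl":
            text = mesh.export(file_type="stl_ascii")
        else:
            raise ValidationError(f"unsupported mesh format {path.suffix!r}; use .obj or .stl")
        if isinstance(text, bytes):
            text = text.decode()
        path.write_text(text)
        return path


def extract_constant_strength_layer(field: StrengthField, level: float) -> ConstantStrengthLayer:
    """Extract the iso-force surface of ``field`` at ``level`` newtons.

    Per ray the boundary is the largest lattice-interpolated radius with
    field >= level, clamped to the reach boundary; a level above the
    global maximum yields an empty layer (flagged, not an error).
    """
    if not (level > 0):
        raise ValidationError(f"level must be positive, got {level}")
    na, nz, nr = field.values.shape
    boundary = np.zeros((na, nz))
    for i in range(na):
        for j in range(nz):
            v = field.values[i, j]
            mask = v >= level
            if not mask.any():
                continue
            k = int(np.max(np.nonzero(mask)))
            if k == nr - 1:
                b = float(field.rs[-1])
            else:
                # linear crossing between nodes k and k+1
                b = float(
                    field.rs[k]
                    + (v[k] - level) / (v[k] - v[k + 1]) * (field.rs[k + 1] - field.rs[k])
                )
            boundary[i, j] = min(b, float(field.reach[i, j]))
    empty = level > field.max_force
    return ConstantStrengthLayer(
        level=level, alphas=field.alphas.copy(), zs=field.zs.copy(), boundary=boundary, empty=empty
    )


def rescale_forces(obj, k: float):
    """Proportionally rescale limit forces F to allowable forces F_d = k*F.

    ``k`` must lie in (0, 1].  Rescaling a field multiplies every lattice
    value by k; rescaling a layer multiplies its level by k.  Geometry is
    unchanged: the layer of the rescaled field at level k*L coincides with
    the layer of the original field at L.
    """
    if not (0 < k <= 1):
        raise ValidationError(f"F_d scale factor must lie in (0, 1], got {k}")
    if isinstance(obj, StrengthField):
        return StrengthField(
            alphas=obj.alphas.copy(),
            zs=obj.zs.copy(),
            rs=obj.rs.copy(),
            values=obj.values * k,
            reach=obj.reach.copy(),
            source_id=obj.source_id,
        )
    if isinstance(obj, ConstantStrengthLayer):
        return replace(obj, level=obj.level * k, boundary=obj.boundary.copy())
    raise ValidationError(f"cannot rescale object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# simplified features
# ---------------------------------------------------------------------------


def extract_simplified_features(
    model: ICZModel, grid_spec: GridSpec | None = None
) -> SimplifiedFeatures:
    """Compute the five-feature quick characterization from a full model.

    D1 is the reach at (alpha=0, shoulder height); F1/F3 are the forces at
    full and mid reach on that ray; F2 at full reach on the 60-degree ray
    at shoulder height; F4 at full reach at elbow height in the sagittal
    plane.  Raises :class:`CoverageError`, naming the feature, when the
    field does not cover a required ray.
    """
    field = build_strength_field(model, grid_spec)
    shoulder = model.profile.shoulder_height
    elbow = model.profile.elbow_height

    def require(alpha: float, z: float, feature: str) -> None:
        if not field.in_extent(alpha, z):
            raise CoverageError(
                f"feature {feature} needs coverage at (alpha={alpha} deg, z={z} cm); "
                f"model covers alpha in [{field.alphas[0]}, {field.alphas[-1]}], "
                f"z in [{field.zs[0]}, {field.zs[-1]}]"
            )

    require(0.0, shoulder, "D1")
    d1 = field.reach_at(0.0, shoulder)
    f1 = field.boundary_force(0.0, shoulder)
    require(60.0, shoulder, "F2")
    f2 = field.boundary_force(60.0, shoulder)
    f3 = field.value_at(0.0, shoulder, d1 / 2.0)
    require(0.0, elbow, "F4")
    f4 = field.boundary_force(0.0, elbow)
    return SimplifiedFeatures(f1=f1, f2=f2, f3=f3, f4=f4, d1=d1, profile=model.profile)


# ---------------------------------------------------------------------------
# JSON model files
# ---------------------------------------------------------------------------


def save_icz_model(model: ICZModel, path: str | Path) -> Path:
    """Write a full model to a versioned JSON file."""
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "profile": {
            "subject_id": model.profile.subject_id,
            "body_height_cm": model.profile.body_height,
            "shoulder_height_cm": model.profile.shoulder_height,
            "elbow_height_cm": model.profile.elbow_height,
            "body_mass_kg": model.profile.body_mass,
            "age_years": model.profile.age,
            "notes": model.profile.notes,
            "limb_side": model.profile.limb_side,
            "reach_convention": model.profile.reach_convention,
        },
        "samples": [
            {"alpha_deg": s.alpha, "z_cm": s.z, "r_cm": s.r, "force_N": s.force}
            for s in model.samples
        ],
    }
    if model.reach_boundary is not None:
        doc["reach_boundary"] = [
            {"alpha_deg": a, "z_cm": z, "reach_cm": r}
            for (a, z), r in sorted(model.reach_boundary.items())
        ]
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_icz_model(path: str | Path) -> ICZModel:
    """Read a full model from its JSON file, validating the schema."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON ({e})") from e
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a JSON object at top level")
    for key in ("profile", "samples"):
        if key not in doc:
            raise SchemaError(f"{path}: missing required key {key!r}")
    p = doc["profile"]
    try:
        profile = AnthropometricProfile(
            subject_id=str(p["subject_id"]),
            body_height=float(p["body_height_cm"]),
            shoulder_height=float(p["shoulder_height_cm"]),
            elbow_height=float(p["elbow_height_cm"]),
            body_mass=float(p["body_mass_kg"]),
            age=p.get("age_years"),
            notes=p.get("notes"),
            limb_side=p.get("limb_side", "right"),
            reach_convention=p.get("reach_convention", "handgrip"),
        )
        samples = tuple(
            StrengthSample(
                alpha=float(s["alpha_deg"]),
                z=float(s["z_cm"]),
                r=float(s["r_cm"]),
                force=float(s["force_N"]),
            )
            for s in doc["samples"]
        )
    except (KeyError, TypeError, ValueError) as e:
        if isinstance(e, ValidationError):
            raise
        raise SchemaError(f"{path}: malformed profile/samples record ({e})") from e
    reach = None
    if "reach_boundary" in doc and doc["reach_boundary"] is not None:
        try:
            reach = {
                (float(rec["alpha_deg"]), float(rec["z_cm"])): float(rec["reach_cm"])
                for rec in doc["reach_boundary"]
            }
        except (KeyError, TypeError, ValueError) as e:
            raise SchemaError(f"{path}: malformed reach_boundary record ({e})") from e
    return ICZModel(profile=profile, samples=samples, reach_boundary=reach)
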