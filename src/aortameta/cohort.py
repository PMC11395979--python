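"""Synthetic cohort generation: morphometry, hemodynamics, meshes, spheres.

This module emulates the study conditions of a two-class pediatric cohort
(30 normal + 30 coarctation) at desk scale.  Three coupled generators:

* class-conditional landmark diameters (truncated normal, with the
  coarctation class separated mainly through the minimal descending
  diameter D0);
* a mass-balance hemodynamic forward model tying landmark velocities and
  pressures to the diameters (volume-flow continuity in terms of squared
  diameters, a per-station viscous drop and a stenosis loss growing as
  (D3/D0)^4), plus independent additive Gaussian noise;
* parametric "candy-cane" aorta geometries (straight ascending segment,
  planar arch, straight descending segment) swept into watertight surface
  meshes, with optional Gaussian-shaped narrowing and three arch-branch
  stubs (BCA, LCCA, LSCA).

Velocity/pressure fields are probed inside 1 mm spherical domains on a
regular grid of 850-900 points, mirroring how field data are reduced to
discrete landmark features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import trimesh

from .config import (
    COHORT_COLUMNS,
    DIAMETER_NAMES,
    DOMAIN_NAMES,
    LABELS,
    PRESSURE_COLUMNS,
    VELOCITY_COLUMNS,
    CohortConfig,
)
from .surrogate import evaluate_published


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the cohort constraints."""


# ---------------------------------------------------------------------------
# morphometry sampling
# ---------------------------------------------------------------------------

_MAX_REJECT = 100


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   name: str, label: str) -> float:
    """Truncated-at-zero normal draw by rejection."""
    if sd == 0.0:
        if mean <= 0:
            raise GenerationError(
                f"degenerate non-positive mean for {name} ({label})")
        return mean
    for _ in range(_MAX_REJECT):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise GenerationError(
        f"could not draw a positive value for {name} ({label}) "
        f"after {_MAX_REJECT} attempts (mean={mean}, sd={sd})")


def sample_morphometry(cfg: CohortConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw class-conditional landmark diameters for a full cohort.

    Returns a DataFrame with ``patient_id``, ``label`` and the nine diameter
    columns (mm).  Within every record the minimal descending diameter D0 is
    constrained not to exceed D3 or D4 (it is, by definition, the minimum of
    the descending segment); records violating the ordering have D0 redrawn.
    """
    if rng is None:
        rng = cfg.stage_rng("morphometry")
    rows = []
    for label, prefix in zip(LABELS, ("N", "C")):
        params = cfg.diameters[label]
        for i in range(cfg.n_per_class):
            rec: dict[str, object] = {
                "patient_id": f"{prefix}{i + 1:03d}", "label": label}
            for attempt in range(_MAX_REJECT + 1):
                if attempt == _MAX_REJECT:
                    raise GenerationError(
                        f"could not draw a record with D0 <= min(D3, D4) "
                        f"for class {label} (D0 mean={params['D0'][0]})")
                for name in DIAMETER_NAMES:
                    mean, sd = params[name]
                    rec[name] = _draw_positive(rng, mean, sd, name, label)
                if rec["D0"] <= min(rec["D3"], rec["D4"]):  # type: ignore
                    break
            rows.append(rec)
    return pd.DataFrame(rows, columns=["patient_id", "label", *DIAMETER_NAMES])


# ---------------------------------------------------------------------------
# hemodynamic forward model
# ---------------------------------------------------------------------------

def forward_hemodynamics(m: Mapping[str, float], cfg: CohortConfig,
                         rng: np.random.Generator | None = None,
                         v_inlet: float | None = None) -> dict[str, float]:
    """Map one morphometric profile to landmark velocities and pressures.

    In ``"balance"`` mode (default) the noise-free responses satisfy volume
    continuity exactly, ``v(P1) D1^2 = sum_k v(Ok) Dk^2`` over the four
    outlets, and pressures decrease downstream of the inlet with a stenosis
    loss ``stenosis_loss_kpa * ((D3/D0)^4 - 1)`` concentrated between the
    two post-arch stations (so the peak-to-peak gradient p(M3) - p(M4) picks
    it up).  In ``"equation"`` mode the five responses covered by the
    published regressions are generated from those forms instead.
    Independent Gaussian noise (``cfg.noise_sd``) is added last.

    Velocities are m/s, pressures kPa, diameters mm.
    """
    for name in DIAMETER_NAMES:
        if m[name] <= 0:
            raise ValueError(f"diameter {name} must be > 0, got {m[name]}")
    if rng is None:
        rng = cfg.stage_rng("hemodynamics")

    if v_inlet is None:
        v_inlet = _draw_positive(rng, cfg.v_inlet_mean, cfg.v_inlet_sd,
                                 "v_inlet", "inlet")

    D = {k: float(m[k]) for k in DIAMETER_NAMES}
    f = cfg.flow_split
    Q = v_inlet * D["D1"] ** 2           # volume-flow surrogate, m/s * mm^2
    Qd = f["O5"] * Q                     # descending-aorta share

    v = {
        "P1": v_inlet,
        "OBCA": f["OBCA"] * Q / D["DBCA"] ** 2,
        "OLCCA": f["OLCCA"] * Q / D["DLCCA"] ** 2,
        "OLSCA": f["OLSCA"] * Q / D["DLSCA"] ** 2,
        "O5": f["O5"] * Q / D["D5"] ** 2,
        "M1": Q / D["D2"] ** 2,
        "M2": Qd / D["D3"] ** 2,
        "M3": Qd / D["D4"] ** 2,
        "M4": Qd / (0.5 * (D["D4"] + D["D5"])) ** 2,
    }

    # narrowing loss: zero when D0 == D3, steep for tight coarctations
    loss = cfg.stenosis_loss_kpa * ((D["D3"] / D["D0"]) ** 4 - 1.0)
    dp = cfg.friction_kpa
    p: dict[str, float] = {}
    p["O5"] = cfg.p_distal_kpa
    p["M4"] = p["O5"] + dp
    p["M3"] = p["M4"] + dp + loss
    p["M2"] = p["M3"] + dp
    p["M1"] = p["M2"] + dp
    p["P1"] = p["M1"] + dp
    p["OBCA"] = p["M1"] - dp
    p["OLCCA"] = p["M1"] - dp
    p["OLSCA"] = p["M1"] - dp

    out = {f"v_{k}": v[k] for k in DOMAIN_NAMES}
    out.update({f"p_{k}": p[k] for k in DOMAIN_NAMES})

    if cfg.hemodynamics_model == "equation":
        p_hat_p1 = evaluate_published("p_P1", D)
        out["p_P1"] = p_hat_p1
        out["p_M2"] = evaluate_published("p_M2", D)
        for resp in ("v_OBCA", "v_M4", "v_O5"):
            out[resp] = evaluate_published(resp, D, p_hat_P1=p_hat_p1)

    for col in (*VELOCITY_COLUMNS, *PRESSURE_COLUMNS):
        sd = cfg.noise_sd.get(col, 0.0)
        if sd > 0:
            out[col] += rng.normal(0.0, sd)
    return out


def generate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Generate the full cohort table: morphometry + hemodynamics + label.

    Column order follows the cohort CSV schema; identical config and seed
    give a byte-identical table.
    """
    morpho = sample_morphometry(cfg)
    rng = cfg.stage_rng("hemodynamics")
    hemo_rows = [forward_hemodynamics(rec, cfg, rng=rng)
                 for rec in morpho[list(DIAMETER_NAMES)].to_dict("records")]
    hemo = pd.DataFrame(hemo_rows)
    out = pd.concat([morpho.reset_index(drop=True), hemo], axis=1)
    return out[list(COHORT_COLUMNS)]


def continuity_residual(row: Mapping[str, float]) -> float:
    """|v(P1) D1^2 - sum of outlet v Dk^2| for one cohort record (generator units)."""
    inflow = row["v_P1"] * row["D1"] ** 2
    outflow = (row["v_OBCA"] * row["DBCA"] ** 2
               + row["v_OLCCA"] * row["DLCCA"] ** 2
               + row["v_OLSCA"] * row["DLSCA"] ** 2
               + row["v_O5"] * row["D5"] ** 2)
    return abs(inflow - outflow)


# ---------------------------------------------------------------------------
# parametric geometry
# ---------------------------------------------------------------------------

@dataclass
class BranchSpec:
    """One arch branch stub: origin arc length (mm), direction, radius, length."""

    name: str
    s_origin: float
    direction: tuple[float, float, float]
    radius: float
    length: float = 8.0


@dataclass
class SyntheticAorta:
    """Parametric planar "candy-cane" aorta.

    The centerline runs in the x-z plane: a straight ascending segment of
    length ``ascending_mm`` along +z, a half-circle arch of radius
    ``arch_radius_mm``, then a straight descending segment of length
    ``descending_mm`` along -z.  The tube radius tapers linearly from
    ``r_proximal_mm`` to ``r_distal_mm`` and may carry one Gaussian-shaped
    narrowing of relative ``depth`` in [0, 1), width ``width_mm`` at arc
    length ``location_mm``.
    """

    patient_id: str = "synthetic"
    label: str = "normal"
    ascending_mm: float = 15.0
    arch_radius_mm: float = 12.0
    descending_mm: float = 45.0
    r_proximal_mm: float = 6.0
    r_distal_mm: float = 4.5
    narrowing: tuple[float, float, float] | None = None  # (depth, width, location)
    branches: list[BranchSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.narrowing is not None:
            depth, width, loc = self.narrowing
            if not (0.0 <= depth < 1.0):
                raise ValueError("narrowing depth must lie in [0, 1)")
            if width <= 0:
                raise ValueError("narrowing width must be > 0")
        if max(self.r_proximal_mm, self.r_distal_mm) >= self.arch_radius_mm:
            raise ValueError(
                "tube radius >= arch radius: swept surface would self-intersect")
        names = [b.name for b in self.branches]
        if names and (names != sorted(names, key=lambda n: ["BCA", "LCCA", "LSCA"].index(n))
                      or [b.s_origin for b in self.branches]
                      != sorted(b.s_origin for b in self.branches)):
            raise ValueError("branches must be BCA, LCCA, LSCA ordered by arc length")

    @property
    def total_length(self) -> float:
        return self.ascending_mm + np.pi * self.arch_radius_mm + self.descending_mm

    def centerline_point(self, s: float | np.ndarray) -> np.ndarray:
        """Centerline position(s) at arc length ``s`` (mm), shape (..., 3)."""
        s = np.asarray(s, dtype=float)
        L1 = self.ascending_mm
        R = self.arch_radius_mm
        L2 = np.pi * R
        x = np.zeros(s.shape + (3,))
        asc = s <= L1
        x[asc] = np.stack([np.zeros_like(s[asc]), np.zeros_like(s[asc]), s[asc]],
                          axis=-1)
        arc = (s > L1) & (s <= L1 + L2)
        theta = (s[arc] - L1) / R
        x[arc] = np.stack([R * (1 - np.cos(theta)), np.zeros_like(theta),
                           L1 + R * np.sin(theta)], axis=-1)
        desc = s > L1 + L2
        x[desc] = np.stack([np.full(desc.sum(), 2 * R), np.zeros(desc.sum()),
                            L1 - (s[desc] - L1 - L2)], axis=-1)
        return x

    def tangent(self, s: float | np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        L1 = self.ascending_mm
        R = self.arch_radius_mm
        L2 = np.pi * R
        t = np.zeros(s.shape + (3,))
        asc = s <= L1
        t[asc] = [0.0, 0.0, 1.0]
        arc = (s > L1) & (s <= L1 + L2)
        theta = (s[arc] - L1) / R
        t[arc] = np.stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)],
                          axis=-1)
        t[s > L1 + L2] = [0.0, 0.0, -1.0]
        return t

    def radius(self, s: float | np.ndarray) -> np.ndarray:
        """Tube radius (mm) at arc length ``s``, including any narrowing.

        The proximal-to-distal taper completes by mid-vessel, so without a
        narrowing the descending segment has uniform caliber (its minimal
        and maximal stations then coincide with the distal-arch level).
        """
        s = np.asarray(s, dtype=float)
        frac = np.clip(s / (0.5 * self.total_length), 0.0, 1.0)
        r = self.r_proximal_mm + (self.r_distal_mm - self.r_proximal_mm) * frac
        if self.narrowing is not None:
            depth, width, loc = self.narrowing
            r = r * (1.0 - depth * np.exp(-0.5 * ((s - loc) / width) ** 2))
        return r

    def diameter(self, s: float | np.ndarray) -> np.ndarray:
        return 2.0 * self.radius(s)


def default_branches(a: SyntheticAorta,
                     radii: Mapping[str, float] | None = None) -> list[BranchSpec]:
    """Three arch-branch stubs at conventional positions along the arch."""
    radii = dict(radii or {"BCA": 2.5, "LCCA": 1.75, "LSCA": 2.0})
    L1, R = a.ascending_mm, a.arch_radius_mm
    specs = []
    for name, frac in (("BCA", 0.25), ("LCCA", 0.5), ("LSCA", 0.75)):
        s = L1 + frac * np.pi * R
        theta = frac * np.pi
        # outward in-plane normal of the arch, tipped cranially (+z)
        n = np.array([-np.cos(theta) * 0.3, 0.0, 0.95])
        n /= np.linalg.norm(n)
        specs.append(BranchSpec(name, float(s), tuple(n), radii[name]))
    return specs


def coa_aorta(patient_id: str = "synthetic-coa", depth: float = 0.55,
              width_mm: float = 4.0) -> SyntheticAorta:
    """Convenience constructor: an aorta with a descending-segment narrowing."""
    a = SyntheticAorta(patient_id=patient_id, label="coa")
    loc = a.ascending_mm + np.pi * a.arch_radius_mm + 0.25 * a.descending_mm
    return SyntheticAorta(patient_id=patient_id, label="coa",
                          narrowing=(depth, width_mm, float(loc)))


def sweep_tube(centers: np.ndarray, radii: np.ndarray, n_circ: int = 32,
               capped: bool = True) -> trimesh.Trimesh:
    """Sweep circular sections of given radii along a polyline centerline.

    Section frames are parallel-transported along the (finite-difference)
    tangent field so the swept rings never twist.  With ``capped=True`` the
    ends are closed with triangle fans and the result is watertight.
    """
    centers = np.asarray(centers, dtype=float)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), centers.shape[:1]).copy()
    n_axial = len(centers)
    if np.any(radii <= 0):
        raise ValueError("radius profile is non-positive")
    seg = np.diff(centers, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len < 1e-12):
        raise ValueError("degenerate centerline: repeated points")
    seg_dir = seg / seg_len[:, None]
    tangents = np.empty_like(centers)
    tangents[0] = seg_dir[0]
    tangents[-1] = seg_dir[-1]
    mids = seg_dir[:-1] + seg_dir[1:]
    norms = np.linalg.norm(mids, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("self-intersecting or kinked centerline")
    tangents[1:-1] = mids / norms[:, None]

    # parallel transport of an initial normal along the tangent field
    normals = np.zeros_like(tangents)
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    nrm = ref - np.dot(ref, t0) * t0
    nrm /= np.linalg.norm(nrm)
    normals[0] = nrm
    for i in range(1, n_axial):
        t_prev, t_cur = tangents[i - 1], tangents[i]
        v = np.cross(t_prev, t_cur)
        c = float(np.dot(t_prev, t_cur))
        if np.linalg.norm(v) < 1e-12:
            normals[i] = normals[i - 1]
        else:
            # Rodrigues rotation taking t_prev to t_cur
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            Rm = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
            normals[i] = Rm @ normals[i - 1]
        normals[i] /= np.linalg.norm(normals[i])
    binormals = np.cross(tangents, normals)

    phi = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    cphi, sphi = np.cos(phi)[:, None], np.sin(phi)[:, None]
    verts = (centers[:, None, :]
             + radii[:, None, None] * (cphi[None] * normals[:, None, :]
                                       + sphi[None] * binormals[:, None, :]))
    verts = verts.reshape(-1, 3)

    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a0 = i * n_circ + j
            a1 = i * n_circ + (j + 1) % n_circ
            b0 = a0 + n_circ
            b1 = a1 + n_circ
            faces.append([a0, b0, a1])
            faces.append([a1, b0, b1])
    if capped:
        verts = np.vstack([verts, centers[0], centers[-1]])
        c_in = len(verts) - 2
        c_out = len(verts) - 1
        for j in range(n_circ):
            faces.append([c_in, j, (j + 1) % n_circ])
            base = (n_axial - 1) * n_circ
            faces.append([c_out, base + (j + 1) % n_circ, base + j])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    mesh.fix_normals()
    return mesh


def make_tube_mesh(a: SyntheticAorta, n_circ: int = 32,
                   n_axial: int = 200) -> trimesh.Trimesh:
    """Watertight surface mesh of a synthetic aorta's main vessel."""
    if n_circ < 16 or n_axial < 50:
        raise ValueError("resolution too low: need >= 16 circumferential "
                         "and >= 50 axial samples")
    s = np.linspace(0.0, a.total_length, n_axial)
    return sweep_tube(a.centerline_point(s), a.radius(s), n_circ=n_circ)


def make_tube_mesh_straight(radius: float, length: float, n_circ: int = 24,
                            n_axial: int = 50) -> trimesh.Trimesh:
    """Capped straight cylinder of constant radius along +z from the origin."""
    z = np.linspace(0.0, length, n_axial)
    centers = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    return sweep_tube(centers, np.full(n_axial, radius), n_circ=n_circ)


def make_branch_meshes(a: SyntheticAorta, n_circ: int = 24,
                       n_axial: int = 50) -> dict[str, trimesh.Trimesh]:
    """Cylindrical stub meshes for each declared branch, keyed by name."""
    out: dict[str, trimesh.Trimesh] = {}
    for b in a.branches:
        origin = a.centerline_point(b.s_origin)
        d = np.asarray(b.direction, dtype=float)
        d /= np.linalg.norm(d)
        mesh = make_tube_mesh_straight(b.radius, b.length, n_circ, n_axial)
        T = trimesh.geometry.align_vectors([0, 0, 1], d)
        T[:3, 3] = origin
        mesh.apply_transform(T)
        out[b.name] = mesh
    return out


# ---------------------------------------------------------------------------
# spherical-domain field sampling
# ---------------------------------------------------------------------------

#: Grid spacing (mm) chosen once so a 1 mm sphere holds 850-900 grid points.
SPHERE_GRID_SPACING_MM = 0.084


def sample_sphere_points(center, field: Callable[[np.ndarray], np.ndarray],
                         diameter_mm: float = 1.0,
                         spacing_mm: float = SPHERE_GRID_SPACING_MM,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a field on a regular grid strictly inside a landmark sphere.

    Returns ``(points, values)`` where points has shape (n, 3) with
    850 <= n <= 900 at the default spacing, and ``values = field(points)``.
    The grid is symmetric about the center, so the sample mean of any
    affine field equals its value at the center.
    """
    center = np.asarray(center, dtype=float)
    r = diameter_mm / 2.0
    k = int(np.ceil(r / spacing_mm))
    offs = spacing_mm * np.arange(-k, k + 1)
    gx, gy, gz = np.meshgrid(offs, offs, offs, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    inside = np.einsum("ij,ij->i", pts, pts) < r * r
    pts = pts[inside] + center
    values = np.asarray(field(pts), dtype=float)
    if values.shape[0] != pts.shape[0]:
        raise ValueError("field must return one value per point")
    return pts, values
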