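"""Parametric idealized aortic-arch lumens for the four morphological stages.

The study follows one aortic arch through four states: a normal control, the
preoperative lumen with a saccular arch aneurysm, and two postoperative
states (1 week and 6 months after modular inner branched stent-graft
implantation).  No imaging data is available, so each state is encoded as a
parametric lumen that captures the morphological claims that matter
hemodynamically:

* three supra-aortic ostia, the innominate artery (IA) bifurcating into the
  right subclavian (RSA) and right common carotid (RCCA) arteries;
* occlusion of the left subclavian artery (LSA) after surgery;
* proximal relocation of the IA/LCCA ostia after surgery;
* arch curvature radius decreasing at 1 week and partially recovering by
  6 months;
* the aneurysm sac excluded (absent) from both postoperative lumens.

Absolute dimensions are adult-aortic presets (the source imagery carries no
scale): lumen radius 12.5 mm, arch curvature radius 32/32/25/29 mm for
normal/preop/1-week/6-month, branch radii 6/4/4 mm, sac bulge 20 mm.  All of
them are plain dataclass fields and can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np
import yaml

from .meshing import (GeometryError, LabeledMesh, PatchSpec, SweptTubeMesher,
                      graded_wall_stations)

CASE_LABELS = ("normal", "preop", "postop1w", "postop6m")


@dataclass(frozen=True)
class BifurcationSpec:
    """Splitting of the IA into RSA and RCCA after a common trunk."""

    trunk_length: float = 0.02       # m of IA before the split
    names: tuple[str, str] = ("RSA", "RCCA")
    daughter_radius: float = 0.004   # m
    daughter_length: float = 0.02    # m
    tilt_deg: float = 20.0           # half-angle between the daughters


@dataclass(frozen=True)
class BranchSpec:
    name: str                 # IA | LCCA | LSA
    ostium_position: float    # trunk arc-length coordinate of the ostium, m
    radius: float             # m
    length: float = 0.02      # m before the flow extension
    present: bool = True
    ia_bifurcation: BifurcationSpec | None = None


@dataclass(frozen=True)
class AneurysmSpec:
    center_position: float        # trunk arc-length of the sac center, m
    bulge_radius: float = 0.020   # m of extra radial extent at the apex
    neck_half_width: float = 0.012  # m along the trunk
    theta_half_width_deg: float = 70.0  # azimuthal extent of the sac


@dataclass(frozen=True)
class ArchCaseSpec:
    """Full parametric description of one morphological case."""

    case_label: str
    lumen_radius: float = 0.0125
    ascending_length: float = 0.06
    descending_length: float = 0.12
    arch_curvature_radius: float = 0.032
    branch_specs: tuple[BranchSpec, ...] = ()
    aneurysm_spec: AneurysmSpec | None = None
    extension_factor: float = 5.0
    boundary_layer_count: int = 6
    boundary_layer_ratio: float = 1.2
    mesh_size: float = 0.005

    # -- derived ------------------------------------------------------------
    @property
    def arch_arc_length(self) -> float:
        return math.pi * self.arch_curvature_radius

    @property
    def trunk_length(self) -> float:
        return self.ascending_length + self.arch_arc_length + self.descending_length

    @property
    def extension_length(self) -> float:
        return self.extension_factor * 2.0 * self.lumen_radius

    def validate(self) -> None:
        if self.case_label not in CASE_LABELS:
            raise ValueError(f"unknown case label {self.case_label!r}")
        if self.lumen_radius <= 0:
            raise ValueError("lumen_radius must be positive")
        if self.arch_curvature_radius <= self.lumen_radius:
            raise ValueError("arch_curvature_radius must exceed lumen_radius")
        for b in self.branch_specs:
            if b.present and not (0 < b.radius < self.lumen_radius):
                raise ValueError(f"branch {b.name}: radius must be in "
                                 f"(0, lumen_radius)")
        if self.case_label in ("postop1w", "postop6m"):
            lsa = [b for b in self.branch_specs if b.name == "LSA"]
            if any(b.present for b in lsa):
                raise ValueError("LSA must be occluded in postoperative cases")
        if self.boundary_layer_count < 1 or self.mesh_size <= 0:
            raise ValueError("invalid meshing parameters")


def default_case_specs(mesh_size: float = 0.005) -> dict[str, ArchCaseSpec]:
    """The four study cases with their morphological orderings built in.

    Ostium positions are fractions of the (case-specific) arch arc measured
    from the arch start; postoperative ostia sit strictly more proximal than
    the preoperative ones, the 1-week arch is the tightest, and only the
    preoperative case carries the aneurysm sac.
    """
    def branches(spec_arc_start, arc, fractions, lsa_present, bif=True):
        out = []
        f_ia, f_lcca, f_lsa = fractions
        out.append(BranchSpec("IA", spec_arc_start + f_ia * arc, 0.006,
                              length=0.02,
                              ia_bifurcation=BifurcationSpec() if bif else None))
        out.append(BranchSpec("LCCA", spec_arc_start + f_lcca * arc, 0.004))
        out.append(BranchSpec("LSA", spec_arc_start + f_lsa * arc, 0.004,
                              present=lsa_present))
        return tuple(out)

    l_asc = 0.06
    specs = {}
    for label, r_arch, fracs, lsa in (
            ("normal", 0.032, (0.12, 0.42, 0.68), True),
            ("preop", 0.032, (0.12, 0.42, 0.68), True),
            ("postop1w", 0.025, (0.06, 0.40, 0.68), False),
            ("postop6m", 0.029, (0.06, 0.40, 0.68), False)):
        arc = math.pi * r_arch
        aneurysm = None
        if label == "preop":
            aneurysm = AneurysmSpec(center_position=l_asc + 0.88 * arc,
                                    neck_half_width=0.010)
        specs[label] = ArchCaseSpec(
            case_label=label,
            arch_curvature_radius=r_arch,
            branch_specs=branches(l_asc, arc, fracs, lsa),
            aneurysm_spec=aneurysm,
            mesh_size=mesh_size,
        )
    for s in specs.values():
        s.validate()
    _validate_family(specs)
    return specs


def _validate_family(specs: dict[str, ArchCaseSpec]) -> None:
    """Inter-case morphological orderings of the study."""
    r = {k: v.arch_curvature_radius for k, v in specs.items()}
    if not (r["postop1w"] < r["normal"] and r["postop1w"] < r["postop6m"]
            and r["postop6m"] <= r["normal"]):
        raise ValueError("arch curvature ordering violated")

    def ostium(label, name):
        return next(b.ostium_position for b in specs[label].branch_specs
                    if b.name == name)
    for name in ("IA", "LCCA"):
        for post in ("postop1w", "postop6m"):
            if not ostium(post, name) < ostium("preop", name):
                raise ValueError(f"{name} ostium not proximal in {post}")


# ---------------------------------------------------------------------------
# centerline


def centerline_frame(spec: ArchCaseSpec, sigma: np.ndarray):
    """Centerline point, tangent, in-plane normal, binormal at arc coords sigma.

    sigma runs from -extension_length (inlet extension) through ascending
    (0..L_asc), arch (semicircular torus arc) and descending segments to
    trunk_length + extension_length.  The centerline lies in the x-z plane;
    the frame normal points away from the arch center (outer curvature) so
    that azimuth theta = 0 marks the greater curvature.
    """
    sigma = np.asarray(sigma, dtype=float)
    R = spec.arch_curvature_radius
    l_asc = spec.ascending_length
    arc = spec.arch_arc_length
    l_tot = spec.trunk_length

    pos = np.empty(sigma.shape + (3,))
    tan = np.empty_like(pos)
    nrm = np.empty_like(pos)

    a = sigma < l_asc  # includes inlet extension (sigma < 0)
    pos[a] = np.stack([np.full(a.sum(), -R), np.zeros(a.sum()),
                       sigma[a] - l_asc], axis=-1)
    tan[a] = [0.0, 0.0, 1.0]
    nrm[a] = [-1.0, 0.0, 0.0]

    m = (sigma >= l_asc) & (sigma <= l_asc + arc)
    phi = (sigma[m] - l_asc) / R
    pos[m] = np.stack([-R * np.cos(phi), np.zeros(phi.shape), R * np.sin(phi)],
                      axis=-1)
    tan[m] = np.stack([np.sin(phi), np.zeros(phi.shape), np.cos(phi)], axis=-1)
    nrm[m] = np.stack([-np.cos(phi), np.zeros(phi.shape), np.sin(phi)], axis=-1)

    d = sigma > l_asc + arc  # includes outlet extension (sigma > trunk_length)
    pos[d] = np.stack([np.full(d.sum(), R), np.zeros(d.sum()),
                       -(sigma[d] - (l_asc + arc))], axis=-1)
    tan[d] = [0.0, 0.0, -1.0]
    nrm[d] = [1.0, 0.0, 0.0]

    bnm = np.broadcast_to([0.0, 1.0, 0.0], pos.shape).copy()
    del l_tot
    return pos, tan, nrm, bnm


def _region_of_s(spec: ArchCaseSpec):
    l_asc, arc, l_tot = (spec.ascending_length, spec.arch_arc_length,
                         spec.trunk_length)

    def region(s):
        if s < 0:
            return "extension_inlet"
        if s < l_asc:
            return "ascending"
        if s <= l_asc + arc:
            return "arch"
        if s <= l_tot:
            return "descending"
        return "extension_outlet"
    return region


# ---------------------------------------------------------------------------
# meshing of a case


def _patch_for_branch(spec: ArchCaseSpec, b: BranchSpec) -> PatchSpec:
    h = spec.mesh_size
    w = math.sqrt(math.pi) * b.radius       # square patch matching pi r^2
    if b.ia_bifurcation is not None:
        bif = b.ia_bifurcation
        half_s = max(w / 2, 2.0 * h)        # need >= 4 cells to split in two
        length = bif.trunk_length + bif.daughter_length
        ext = spec.extension_factor * 2.0 * bif.daughter_radius
        split = (bif.trunk_length, bif.names, math.radians(bif.tilt_deg))
        min_s = 4
    else:
        half_s = max(w / 2, h)
        length = b.length
        ext = spec.extension_factor * 2.0 * b.radius
        split = None
        min_s = 2
    half_t = max(w / 2, h) / spec.lumen_radius
    return PatchSpec(name=b.name, s_center=b.ostium_position,
                     half_width_s=half_s, half_width_theta=half_t,
                     direction_theta=0.0, length=length, extension=ext,
                     mesh_size=h, split=split, min_cells_s=min_s)


def _check_feasible(spec: ArchCaseSpec, patches: list[PatchSpec]) -> None:
    h = spec.mesh_size / 2
    windows = [(p.name, p.s_center - p.half_width_s - h,
                p.s_center + p.half_width_s + h) for p in patches]
    if spec.aneurysm_spec is not None:
        a = spec.aneurysm_spec
        windows.append(("aneurysm", a.center_position - a.neck_half_width,
                        a.center_position + a.neck_half_width))
    windows.sort(key=lambda w: w[1])
    for (na, _, hi), (nb, lo, _) in zip(windows[:-1], windows[1:]):
        if hi > lo:
            raise GeometryError(
                f"infeasible geometry: {na} overlaps {nb} along the trunk")


def _radius_scale(spec: ArchCaseSpec):
    a = spec.aneurysm_spec
    if a is None:
        return None
    amp = a.bulge_radius / spec.lumen_radius
    th_hw = math.radians(a.theta_half_width_deg)

    def scale(s, theta):
        ds = np.abs(s - a.center_position)
        w_s = np.where(ds < a.neck_half_width,
                       np.cos(0.5 * np.pi * ds / a.neck_half_width) ** 2, 0.0)
        th = np.mod(theta + np.pi, 2 * np.pi) - np.pi
        w_t = np.where(np.abs(th) < th_hw,
                       np.cos(0.5 * np.pi * th / th_hw) ** 2, 0.0)
        return 1.0 + amp * w_s * w_t
    return scale


def _core_stations(spec: ArchCaseSpec, h: float) -> np.ndarray:
    """Axial stations on [0, trunk_length]: spacing h, refined 3x under the sac.

    The sac wall slopes steeply at its neck; without local refinement the
    sheared prisms between consecutive (rotating) arch cross-sections can
    fold into inverted tetrahedra.
    """
    L = spec.trunk_length
    if spec.aneurysm_spec is None:
        n = max(8, int(math.ceil(L / h)))
        return np.linspace(0.0, L, n + 1)
    a = spec.aneurysm_spec
    lo = max(0.0, a.center_position - a.neck_half_width - h)
    hi = min(L, a.center_position + a.neck_half_width + h)
    parts = []
    for x0, x1, step in ((0.0, lo, h), (lo, hi, h / 3.0), (hi, L, h)):
        if x1 > x0:
            n = max(1, int(math.ceil((x1 - x0) / step)))
            parts.append(np.linspace(x0, x1, n + 1)[:-1])
    parts.append(np.array([L]))
    return np.concatenate(parts)


def build_case_geometry(spec: ArchCaseSpec) -> LabeledMesh:
    """Mesh one case: swept trunk with extensions, branch columns, sac bulge.

    Deterministic: identical specs give bitwise-identical meshes.  Raises
    GeometryError when requested components overlap along the trunk.
    """
    spec.validate()
    h = spec.mesh_size
    patches = [_patch_for_branch(spec, b) for b in spec.branch_specs if b.present]
    _check_feasible(spec, patches)

    ext = spec.extension_length
    s_core = _core_stations(spec, h)
    n_ext = max(2, int(math.ceil(ext / (2.5 * h))))
    s_in = np.linspace(-ext, 0.0, n_ext + 1)[:-1]
    s_out = np.linspace(spec.trunk_length, spec.trunk_length + ext, n_ext + 1)[1:]
    s = np.concatenate([s_in, s_core, s_out])

    pos, tan, nrm, bnm = centerline_frame(spec, s)
    n_theta = max(12, 2 * int(round(math.pi * spec.lumen_radius / h)))
    n_theta += n_theta % 2
    stations = graded_wall_stations(spec.lumen_radius, h,
                                    n_bl=spec.boundary_layer_count,
                                    bl_ratio=spec.boundary_layer_ratio)
    mesher = SweptTubeMesher(s, pos, tan, nrm, bnm, stations, n_theta,
                             radius_scale=_radius_scale(spec),
                             region_of_s=_region_of_s(spec))
    mesh = mesher.build(patches)

    # mark the sac: wall facets whose nodes carry a significant bulge
    bulge = mesh.node_data["aneurysm_factor"]
    if bulge.max() > 0.1:
        if "aneurysm" not in mesh.region_names:
            mesh.region_names.append("aneurysm")
        rid = mesh.region_names.index("aneurysm")
        fac_bulge = bulge[mesh.boundary_facets].mean(axis=1)
        mesh.facet_regions[fac_bulge > 0.1] = rid
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# synthetic wall-shear fixtures


@dataclass(frozen=True)
class SyntheticWssSeries:
    """Closed-form tangential traction series on a unit wall patch."""

    kind: str                 # constant | reversing | offset_sinusoid
    amplitude: float = 0.0    # Pa
    offset: float = 0.0       # Pa
    n_timesteps: int = 256
    period: float = 1.0       # s

    def validate(self):
        if self.kind not in ("constant", "reversing", "offset_sinusoid"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_timesteps < 4:
            raise ValueError("n_timesteps must be >= 4")
        if self.period <= 0:
            raise ValueError("period must be positive")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Traction vectors (len(t), 3) of the underlying continuous signal."""
        t = np.asarray(t, dtype=float)
        tau = np.zeros(t.shape + (3,))
        if self.kind == "constant":
            tau[..., 0] = self.offset
        elif self.kind == "reversing":
            # cycle time on (0, T]: t = T is the end of the cycle, not t = 0
            tc = np.mod(t, self.period)
            tc = np.where(tc == 0.0, self.period, tc)
            tau[..., 0] = np.where(tc <= self.period / 2,
                                   self.amplitude, -self.amplitude)
        else:
            tau[..., 0] = self.offset + self.amplitude * np.sin(
                2 * np.pi * t / self.period)
        return tau


def synthetic_wss_series(fixture: SyntheticWssSeries, oversample: int = 1):
    """Sample the fixture on its time grid t_k = k T/n, k = 1..n.

    Returns a WallShearField on one unit-area facet with normal +z (so the
    x-directed tractions are exactly tangential).  ``oversample`` multiplies
    the number of samples, which is how the quadrature oracle is built.
    """
    from .wallshear import WallShearField

    fixture.validate()
    n = fixture.n_timesteps * oversample
    times = fixture.period * np.arange(1, n + 1) / n
    tau = fixture.evaluate(times)[:, None, :]  # (S, 1, 3)
    return WallShearField(
        facet_ids=np.array([0]),
        times=times,
        tractions=tau,
        facet_areas=np.array([1.0]),
        facet_normals=np.array([[0.0, 0.0, 1.0]]),
        period=fixture.period,
    )


# ---------------------------------------------------------------------------
# plain-text (YAML) round-trip


def spec_to_dict(spec: ArchCaseSpec) -> dict:
    def plain(x):
        if isinstance(x, dict):
            return {k: plain(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [plain(v) for v in x]
        return x
    return plain(asdict(spec))


def spec_from_dict(d: dict) -> ArchCaseSpec:
    d = dict(d)
    branches = []
    for b in d.pop("branch_specs", ()):
        b = dict(b)
        bif = b.pop("ia_bifurcation", None)
        if bif is not None:
            bif = BifurcationSpec(**{**bif, "names": tuple(bif["names"])})
        branches.append(BranchSpec(**b, ia_bifurcation=bif))
    an = d.pop("aneurysm_spec", None)
    spec = ArchCaseSpec(branch_specs=tuple(branches),
                        aneurysm_spec=AneurysmSpec(**an) if an else None, **d)
    spec.validate()
    return spec


def save_spec(spec: ArchCaseSpec, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(spec_to_dict(spec), f, sort_keys=False)


def load_spec(path) -> ArchCaseSpec:
    with open(path) as f:
        return spec_from_dict(yaml.safe_load(f))


def scaled_spec(spec: ArchCaseSpec, mesh_size: float) -> ArchCaseSpec:
    """The same case at a different target element size."""
    return replace(spec, mesh_size=mesh_size)
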