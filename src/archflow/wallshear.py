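"""Wall shear stress extraction from a solved flow field.

The WSS vector on a wall facet is the tangential part of the viscous traction
mu (grad u + grad u^T) · n, with n the outward wall normal.  With linear
elements the velocity gradient is constant in each cell, so the traction on a
boundary facet is reconstructed from its single adjacent volume cell — a
first-order estimate that is exact for linear velocity fields (plane Couette)
and, on the graded wall layers, a thin-secant approximation of the true wall
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fem
from .meshing import LabeledMesh


@dataclass
class WallShearField:
    """Tangential viscous traction per wall facet per snapshot time."""

    facet_ids: np.ndarray      # indices into mesh.boundary_facets
    times: np.ndarray          # (S,) s, the analyzed cycle
    tractions: np.ndarray      # (S, F, 3) Pa (S, F, 2) in planar mode
    facet_areas: np.ndarray    # (F,)
    facet_normals: np.ndarray  # (F, dim) outward
    period: float = 1.0
    excluded_facets: int = 0   # degenerate-cell facets dropped, with count
    facet_regions: np.ndarray | None = None
    region_names: list[str] = field(default_factory=list)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.tractions, axis=2)

    def to_frame(self, time_stride: int = 1):
        """Long-form table (facet, time, tau components, |tau|) for export."""
        import pandas as pd
        S, F, d = self.tractions.shape
        sel = np.arange(0, S, time_stride)
        rows = {
            "facet": np.tile(self.facet_ids, len(sel)),
            "time_s": np.repeat(self.times[sel], F),
        }
        for a, name in enumerate(("tau_x_Pa", "tau_y_Pa", "tau_z_Pa")[:d]):
            rows[name] = self.tractions[sel, :, a].ravel()
        rows["tau_mag_Pa"] = self.magnitudes[sel].ravel()
        return pd.DataFrame(rows)

    def max_normal_residual(self) -> float:
        """max |tau·n| - should vanish: tractions are tangential by design."""
        dots = np.abs(np.einsum("sfd,fd->sf", self.tractions, self.facet_normals))
        scale = 1e-8 * self.magnitudes + 1e-12
        return float((dots - scale).max())


def compute_wss(field, mesh: LabeledMesh, props,
                wall_tag: str = "wall", flip_normals: bool = False) -> WallShearField:
    """Viscous tangential traction on wall-tagged facets for every snapshot.

    ``field`` is a FlowField; ``props`` a FluidProperties.  Facets whose
    adjacent cell is geometrically degenerate (volume below 1e-9 of the mean)
    are excluded and counted in ``excluded_facets``.
    """
    mu = props.dynamic_viscosity
    wall = mesh.facets_where(wall_tag)
    owners = mesh.facet_owners[wall]
    vols, grads = fem.cell_geometry(mesh.nodes, mesh.cells)
    good = vols[owners] > 1e-9 * vols.mean()
    excluded = int((~good).sum())
    wall = wall[good]
    owners = owners[good]

    areas = mesh.facet_areas[wall]
    normals = mesh.facet_normals[wall].copy()
    if flip_normals:
        normals = -normals

    cells_w = mesh.cells[owners]
    grads_w = grads[owners]
    S = len(field.times)
    F = len(wall)
    d = mesh.dim
    tractions = np.empty((S, F, d))
    for si in range(S):
        u = field.velocities[si]
        G = np.einsum("fia,fib->fab", u[cells_w], grads_w)  # (F, d, d)
        sym = G + np.transpose(G, (0, 2, 1))
        t_full = mu * np.einsum("fab,fb->fa", sym, normals)
        t_n = np.einsum("fa,fa->f", t_full, normals)
        tractions[si] = t_full - t_n[:, None] * normals

    regions = mesh.facet_regions[wall] if mesh.facet_regions is not None else None
    return WallShearField(
        facet_ids=wall, times=np.asarray(field.times), tractions=tractions,
        facet_areas=areas, facet_normals=normals, period=field.period,
        excluded_facets=excluded, facet_regions=regions,
        region_names=list(mesh.region_names),
    )
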