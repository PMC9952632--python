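import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def props():
    from archflow.solver import FluidProperties
    return FluidProperties()


@pytest.fixture(scope="session")
def small_tube(props):
    """Short straight tube at modest resolution plus its steady Poiseuille flow.

    Re ~ 30 with a parabolic inlet, so the analytic Poiseuille solution holds
    from the inlet on.
    """
    from archflow.meshing import straight_tube_mesh
    from archflow.solver import solve_steady

    R, L = 0.004, 0.016
    U = 30 * props.dynamic_viscosity / (props.density * 2 * R)
    Q = U * np.pi * R ** 2
    mesh = straight_tube_mesh(R, L, 0.001)
    field = solve_steady(mesh, Q, props)
    return {"mesh": mesh, "field": field, "R": R, "L": L, "Q": Q, "U": U}


@pytest.fixture(scope="session")
def four_case_run(tmp_path_factory):
    """Coarse-tier pipeline run of all four morphological cases.

    Session-scoped: the transient solves dominate the suite's runtime, and
    both the pipeline contract tests and the cross-case ordering checks read
    from the same bundles.
    """
    from archflow.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(output_dir=str(out), verbosity=0)
    bundles = run_pipeline(cfg)
    return {"config": cfg, "bundles": bundles, "outdir": out}


@pytest.fixture(scope="session")
def couette_2d(props):
    """Plane Couette fixture: linear shear imposed directly on the nodes."""
    from archflow.meshing import channel_mesh_2d
    from archflow.solver import FlowField

    H, L = 0.002, 0.008
    gdot = 25.0
    mesh = channel_mesh_2d(L, H, 8, 6)
    u = np.zeros((len(mesh.nodes), 2))
    u[:, 0] = gdot * mesh.nodes[:, 1]
    times = np.array([0.5, 1.0])
    field = FlowField(times=times,
                      velocities=np.stack([u, u]),
                      pressures=np.zeros((2, len(mesh.nodes))),
                      period=1.0)
    return {"mesh": mesh, "field": field, "gdot": gdot}
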