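import numpy as np
import pandas as pd
import pytest

from strokeaccess import (
    DecayConfig,
    Instance,
    TravelTimeMatrix,
    build_problem,
    japan_scale_fixture,
    solve_allocation,
)

BETA = 0.07
W10 = np.exp(-0.7)  # decay weight of a 10-minute trip at beta=0.07


def make_instance(meshes, facilities, triplets, threshold=120.0, regions=None):
    """Assemble an Instance from plain tuples.

    meshes: (mesh_id, x, y, population[, region_id]) tuples
    facilities: (facility_id, x, y, staff[, region_id]) tuples
    triplets: (mesh_id, facility_id, minutes) tuples
    """
    mrows = [(m + ("r0",))[:5] for m in meshes]
    frows = [(f + ("r0",))[:5] for f in facilities]
    mesh_df = pd.DataFrame(mrows, columns=["mesh_id", "x", "y", "population", "region_id"])
    fac_df = pd.DataFrame(frows, columns=["facility_id", "x", "y", "staff", "region_id"])
    ttm = TravelTimeMatrix(
        mesh_ids=np.array([t[0] for t in triplets]),
        facility_ids=np.array([t[1] for t in triplets]),
        minutes=np.array([t[2] for t in triplets], dtype=float),
        threshold_minutes=threshold,
    )
    if regions is None:
        regions = pd.DataFrame({"region_id": ["r0"], "urban_proportion": [0.5]})
    return Instance(mesh_df, fac_df, ttm, regions)


@pytest.fixture
def toy_2x2():
    """Two meshes (D=100 each), two facilities (S=2, 1), cross travel of 10 min.

    Closed-form surface values (V = 100 * (1 + w10)):
      R1 = 2/V, R2 = 1/V, A1 = R1 + w10*R2, A2 = w10*R1 + R2
      r1 = 100/(2 + w10), r2 = 100/(2*w10 + 1), C1 = r1 + w10*r2, C2 = w10*r1 + r2
    """
    return make_instance(
        meshes=[("m1", 0.0, 0.0, 100), ("m2", 7.5, 0.0, 100)],
        facilities=[("h1", 0.0, 0.0, 2), ("h2", 7.5, 0.0, 1)],
        triplets=[("m1", "h1", 0.0), ("m1", "h2", 10.0), ("m2", "h1", 10.0), ("m2", "h2", 0.0)],
    )


def toy_expected():
    """Hand-evaluated two-step quantities for the toy instance."""
    V = 100.0 * (1.0 + W10)
    R1, R2 = 2.0 / V, 1.0 / V
    A1, A2 = R1 + W10 * R2, W10 * R1 + R2
    r1, r2 = 100.0 / (2.0 + W10), 100.0 / (2.0 * W10 + 1.0)
    C1, C2 = r1 + W10 * r2, W10 * r1 + r2
    return dict(V=V, R1=R1, R2=R2, A1=A1, A2=A2, r1=r1, r2=r2, C1=C1, C2=C2)


def random_instance(rng, n_meshes, n_facilities, threshold=120.0, span_km=60.0):
    """Small random instance with all pairs inside the catchment."""
    mxy = rng.uniform(0, span_km, size=(n_meshes, 2))
    fxy = rng.uniform(0, span_km, size=(n_facilities, 2))
    pop = rng.integers(10, 500, size=n_meshes)
    staff = rng.integers(0, 5, size=n_facilities)
    staff[rng.integers(n_facilities)] += 1  # at least one physician
    meshes = [(f"m{i}", mxy[i, 0], mxy[i, 1], int(pop[i])) for i in range(n_meshes)]
    facilities = [(f"f{j}", fxy[j, 0], fxy[j, 1], int(staff[j])) for j in range(n_facilities)]
    triplets = []
    for i in range(n_meshes):
        for j in range(n_facilities):
            minutes = float(np.hypot(*(mxy[i] - fxy[j])) / 0.75)
            if minutes < threshold:
                triplets.append((f"m{i}", f"f{j}", minutes))
    return make_instance(meshes, facilities, triplets, threshold)


@pytest.fixture(scope="session")
def japan_fixture():
    """National-scale synthetic instance with its solved reallocation QP."""
    instance = japan_scale_fixture(seed=1, n_meshes=5000)
    problem = build_problem(
        instance.meshes, instance.facilities, instance.travel_times, DecayConfig()
    )
    solution = solve_allocation(problem)
    return {"instance": instance, "problem": problem, "solution": solution}
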