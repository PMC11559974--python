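"""Shared fixtures: a scaled two-gyre basin run once per session.

The basin is the package's default fixture geometry at reduced extent
(300 km) and seeding density so the full cohort lifecycle stays fast; all
physical parameters (speeds, PLD, clip rules, time step) keep their
defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

import larvanet as ln
from larvanet.synthfields import make_mld_and_bathy


@pytest.fixture(scope="session")
def gyre_fields():
    fields = ln.make_double_gyre(domain_km=300.0, cell_km=10.0)
    return make_mld_and_bathy(fields)


@pytest.fixture(scope="session")
def grid(gyre_fields):
    return ln.HexGrid(
        resolution=5,
        center=(float(np.mean(gyre_fields.lon)), float(np.mean(gyre_fields.lat))),
    )


@pytest.fixture(scope="session")
def sim_config():
    return ln.SimConfig(seed_density=0.08, rng_seed=7)


@pytest.fixture(scope="session")
def fd_cohort(gyre_fields, sim_config):
    beh = ln.BehaviorConfig(mode="fixed_depth")
    cohort = ln.seed_cohort(gyre_fields, None, sim_config, beh)
    return ln.run_simulation(cohort, gyre_fields)


@pytest.fixture(scope="session")
def pd_cohort(gyre_fields, sim_config):
    beh = ln.BehaviorConfig(mode="preferred_depth")
    cohort = ln.seed_cohort(gyre_fields, None, sim_config, beh)
    return ln.run_simulation(cohort, gyre_fields)


@pytest.fixture(scope="session")
def habitat(gyre_fields, grid):
    from larvanet.synthfields import gyre_habitat_seeds

    return ln.make_habitat_patches(
        gyre_fields, grid, n_lineages=3,
        patch_seeds=gyre_habitat_seeds(gyre_fields, grid, 3),
        rng_seed=0, growth_steps=3,
    )


@pytest.fixture(scope="session")
def fd_resolved(fd_cohort, grid):
    return ln.resolve_settlement(fd_cohort, "FD", grid=grid)


@pytest.fixture(scope="session")
def pd_resolved(pd_cohort, grid):
    return ln.resolve_settlement(pd_cohort, "PD", grid=grid)


@pytest.fixture(scope="session")
def sh_resolved(pd_cohort, habitat, grid):
    return ln.resolve_settlement(pd_cohort, "SH", habitat=habitat, grid=grid)


@pytest.fixture(scope="session")
def pd_flow_map(pd_resolved, grid):
    return ln.prune_to_closed(ln.build_flow_map(pd_resolved, grid))


@pytest.fixture(scope="session")
def pd_network(pd_flow_map):
    return ln.to_network(pd_flow_map)


@pytest.fixture(scope="session")
def pd_partition(pd_network):
    best, ensemble = ln.ensemble_detect(pd_network, ln.MapEqConfig(n_seeds=4))
    return best, ensemble


@pytest.fixture(scope="session")
def zero_fields():
    """All-water, all-zero velocity and diffusivity; steady."""
    n = 8
    dlat = 10_000.0 / 111_194.93
    lat = 45.0 + dlat * (np.arange(n) - (n - 1) / 2)
    lon = -63.0 + dlat / np.cos(np.radians(45.0)) * (np.arange(n) - (n - 1) / 2)
    depth = np.array([0.0, 50.0])
    shape = (1, 2, n, n)
    return ln.EnvironmentFields(
        lon=lon,
        lat=lat,
        depth=depth,
        u=np.zeros(shape),
        v=np.zeros(shape),
        K=np.zeros(shape),
        mld=np.full((1, n, n), 20.0),
        bathy=np.full((n, n), 100.0),
        land_mask=np.zeros((n, n), dtype=bool),
        months=None,
    )
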