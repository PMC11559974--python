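"""Lagrangian simulation of larval cohorts from spawn to settlement.

Particles drift in the horizontal under fourth-order Runge-Kutta advection
and first-order Milstein diffusion, while the vertical position follows one
of two behaviors:

* ``fixed_depth`` — buoyant larvae pinned at a fixed depth (default 1 m);
* ``preferred_depth`` — simultaneous gravitational sinking and swimming
  toward a per-particle preferred depth drawn around the local mixed-layer
  depth; swimming stops on reaching the preferred depth within a step, and
  depths are clamped just below the surface and just above the bathymetry.

Per-particle traits (sinking speed, maximum swimming speed, preferred
depth) are drawn once at spawn from clipped normal distributions and held
constant through dispersal.  Particles that enter a region of exactly zero
interpolated velocity (land) beach and are excluded from all downstream
analysis; particles leaving the lateral domain are likewise excluded.

The simulation runs for a fixed maximum pelagic larval duration (PLD,
default 45 days) with daily position output.  Settlement is resolved in
post-processing: fixed- and preferred-depth cases settle wherever they are
at the end of the PLD, while the suitable-habitat case settles on the first
daily output within the competency window (the final 7 days of the PLD)
spent over suitable habitat, and requires a suitable spawn cell.  One
simulation serves both the preferred-depth and suitable-habitat cases so
stochastic transport is identical between them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .hexgrid import HexGrid
from .synthfields import METERS_PER_DEGREE, HabitatMap, day_of_year

# particle status codes (transitions are monotone: active -> terminal)
ACTIVE = 0
BEACHED = 1
EXITED = 2
SETTLED = 3
NONVIABLE = 4
STATUS_NAMES = {ACTIVE: "active", BEACHED: "beached", EXITED: "exited",
                SETTLED: "settled", NONVIABLE: "nonviable"}

FIXED_DEPTH = "fixed_depth"
PREFERRED_DEPTH = "preferred_depth"


@dataclass(frozen=True)
class BehaviorConfig:
    """Vertical behavior parameters.

    Speeds are in m/s: sinking 0.6(3) mm/s and maximum swimming
    2.4(20) mm/s for bivalve larvae, drawn from clipped normals (1 SD band;
    2 SD for the depth preference around the local MLD).
    """

    mode: str = PREFERRED_DEPTH
    fixed_depth_value: float = 1.0
    sink_mean: float = 0.6e-3
    sink_sd: float = 0.3e-3
    swim_mean: float = 2.4e-3
    swim_sd: float = 2.0e-3
    trait_clip_nsd: float = 1.0
    pref_depth_sd: float = 5.0
    pref_clip_nsd: float = 2.0
    surface_clearance: float = 0.1
    bottom_clearance: float = 0.1

    def __post_init__(self):
        if self.mode not in (FIXED_DEPTH, PREFERRED_DEPTH):
            raise ValueError(f"unknown behavior mode {self.mode!r}")
        if self.trait_clip_nsd <= 0 or self.pref_clip_nsd <= 0:
            raise ValueError("clip bounds must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Simulation schedule: 30-min steps, daily output, 45-day PLD,
    7-day competency window, mid-September spawn, 1.3 particles/km**2."""

    dt: float = 1800.0
    output_interval: float = 86400.0
    pld_days: int = 45
    competency_days: int = 7
    spawn_month: int = 9
    spawn_day: int = 15
    seed_density: float = 1.3
    rng_seed: int = 0

    def __post_init__(self):
        if self.output_interval % self.dt != 0:
            raise ValueError("dt must divide output_interval")
        if not self.competency_days < self.pld_days:
            raise ValueError("competency_days must be less than pld_days")

    @property
    def spawn_t_days(self) -> float:
        return day_of_year(self.spawn_month, self.spawn_day)

    @property
    def steps_per_output(self) -> int:
        return int(self.output_interval // self.dt)

    @property
    def n_steps(self) -> int:
        return int(self.pld_days * 86400 // self.dt)

    @property
    def competency_window(self) -> range:
        """Daily output indices checked for suitable-habitat settlement."""
        return range(self.pld_days - self.competency_days + 1, self.pld_days + 1)


@dataclass
class ParticleCohort:
    """Arrays of per-particle state; one row per particle."""

    lon: np.ndarray
    lat: np.ndarray
    z: np.ndarray
    spawn_lon: np.ndarray
    spawn_lat: np.ndarray
    spawn_z: np.ndarray
    w_sink: np.ndarray
    w_swim: np.ndarray
    z_pref: np.ndarray
    status: np.ndarray
    history: np.ndarray | None = None  # (n, pld_days, 3): lon, lat, z
    death_day: np.ndarray | None = None  # fractional day of beaching/exit
    settle_lon: np.ndarray | None = None
    settle_lat: np.ndarray | None = None
    settle_day: np.ndarray | None = None
    case: str | None = None
    sim_config: SimConfig | None = None
    behavior: BehaviorConfig | None = None

    def __len__(self) -> int:
        return len(self.lon)

    def copy(self) -> "ParticleCohort":
        kw = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            kw[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return ParticleCohort(**kw)

    def fate_counts(self) -> dict:
        vals, counts = np.unique(self.status, return_counts=True)
        return {STATUS_NAMES[int(s)]: int(c) for s, c in zip(vals, counts)}

    # -- I/O ---------------------------------------------------------------

    def settlement_table(self, grid: HexGrid | None = None) -> pd.DataFrame:
        n = len(self)
        df = pd.DataFrame(
            {
                "id": np.arange(n),
                "status": [STATUS_NAMES[int(s)] for s in self.status],
                "settle_day": self.settle_day if self.settle_day is not None else -1,
            }
        )
        if grid is not None:
            df["spawn_cell"] = grid.cell(self.spawn_lon, self.spawn_lat)
            settled = self.status == SETTLED
            cells = np.full(n, -1, dtype=np.int64)
            if self.settle_lon is not None and settled.any():
                cells[settled] = grid.cell(self.settle_lon[settled], self.settle_lat[settled])
            df["settle_cell"] = cells
        return df

    def trajectories_to_netcdf(self, path) -> None:
        if self.history is None:
            raise ValueError("cohort has no recorded history")
        ds = xr.Dataset(
            {
                "lon": (("particle", "day"), self.history[:, :, 0]),
                "lat": (("particle", "day"), self.history[:, :, 1]),
                "z": (("particle", "day"), self.history[:, :, 2]),
                "status": (("particle",), self.status.astype(np.int8)),
            },
            coords={
                "particle": np.arange(len(self)),
                "day": np.arange(1, self.history.shape[1] + 1),
            },
        )
        ds.to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def sample_clipped_normal(mean, sd, clip_nsd, n, rng) -> np.ndarray:
    """Normal draws with out-of-band values redistributed uniformly.

    Draws outside ``mean +/- clip_nsd * sd`` are replaced by uniform draws
    on that interval, which keeps the distribution symmetric about the mean
    (and hence mean-preserving) while bounding every sample.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if clip_nsd <= 0:
        raise ValueError("clip_nsd must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    x = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
    lo, hi = mean - clip_nsd * sd, mean + clip_nsd * sd
    out = (x < lo) | (x > hi)
    if out.any():
        x[out] = rng.uniform(lo, hi, size=int(out.sum()))
    return x


def _deg_rates(fields, lon, lat, z, t_days):
    """Velocity sampled in m/s, converted to deg/s at the local latitude."""
    u, v = fields.velocity(lon, lat, z, t_days)
    dlon = u / (METERS_PER_DEGREE * np.cos(np.radians(lat)))
    dlat = v / METERS_PER_DEGREE
    return dlon, dlat


def rk4_advect(fields, lon, lat, z, t_days, dt):
    """Classical four-stage Runge-Kutta step of the horizontal position.

    Velocities are sampled in space and time at each stage and converted to
    angular rates at the stage latitude.  ``t_days`` is in days, ``dt`` in
    seconds.  Returns the new (lon, lat).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dt_days = dt / 86400.0
    k1x, k1y = _deg_rates(fields, lon, lat, z, t_days)
    k2x, k2y = _deg_rates(fields, lon + k1x * dt / 2, lat + k1y * dt / 2, z, t_days + dt_days / 2)
    k3x, k3y = _deg_rates(fields, lon + k2x * dt / 2, lat + k2y * dt / 2, z, t_days + dt_days / 2)
    k4x, k4y = _deg_rates(fields, lon + k3x * dt, lat + k3y * dt, z, t_days + dt_days)
    new_lon = lon + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    new_lat = lat + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
    return new_lon, new_lat


def milstein_diffuse(fields, lon, lat, z, t_days, dt, rng=None, dW=None):
    """First-order Milstein step for horizontal diffusion.

    Per axis, with Wiener increment dW ~ N(0, dt):
    ``dx = sqrt(2 K) dW + (dK/dx) (dW**2 + dt) / 2``.  The deterministic
    half of the gradient term is the well-mixed drift correction, so for
    linear K the expected displacement is (dK/dx) dt.
    """
    if dW is None:
        if rng is None:
            raise ValueError("provide rng or dW")
        dW = rng.normal(0.0, np.sqrt(dt), size=(2,) + np.shape(lon))
    dWx, dWy = dW
    K = fields.diffusivity(lon, lat, z, t_days)
    if np.any(K < 0):
        raise ValueError("negative diffusivity")
    dKdx, dKdy = fields.diffusivity_gradient(lon, lat, z, t_days)
    amp = np.sqrt(2.0 * K)
    disp_x = amp * dWx + 0.5 * dKdx * (dWx**2 + dt)
    disp_y = amp * dWy + 0.5 * dKdy * (dWy**2 + dt)
    new_lon = lon + disp_x / (METERS_PER_DEGREE * np.cos(np.radians(lat)))
    new_lat = lat + disp_y / METERS_PER_DEGREE
    return new_lon, new_lat


def vertical_step(z, z_pref, w_sink, w_swim_max, bathy, dt,
                  surface_clearance=0.1, bottom_clearance=0.1):
    """Preferred-depth vertical update: sink + swim toward z_pref.

    Sinking acts always; swimming is directed toward the preferred depth
    with magnitude at most ``w_swim_max`` and covers only the remaining
    distance if the preferred depth is reached within the step.  The result
    is clamped just below the surface and just above the bathymetry.
    Depths are positive down, so sinking increases z.
    """
    delta = z_pref - z  # positive: preferred depth below particle
    swim = np.sign(delta) * np.minimum(np.abs(delta), w_swim_max * dt)
    new_z = z + w_sink * dt + swim
    floor = np.maximum(bathy - bottom_clearance, surface_clearance)
    return np.clip(new_z, surface_clearance, floor)


# ---------------------------------------------------------------------------
# cohort lifecycle
# ---------------------------------------------------------------------------


def _rng_streams(seed: int):
    ss = np.random.SeedSequence(seed)
    place_ss, trait_ss, diff_ss = ss.spawn(3)
    return (
        np.random.default_rng(place_ss),
        np.random.default_rng(trait_ss),
        np.random.Philox(diff_ss),
    )


def seed_cohort(
    fields,
    habitat: HabitatMap | list | None,
    sim_config: SimConfig,
    behavior: BehaviorConfig,
    grid: HexGrid | None = None,
) -> ParticleCohort:
    """Quasi-uniform Poisson seeding of particles over water.

    The particle count is Poisson with mean ``seed_density * water area``;
    positions are uniform over water cells (weighted by true cell area).
    If ``habitat`` is given together with ``grid``, seeding is restricted
    to suitable cells.  Traits are drawn from the clipped normals of
    ``behavior``; preferred depths center on the MLD at the spawn location.
    """
    if sim_config.seed_density <= 0:
        raise ValueError("seed density must be positive")
    place_rng, trait_rng, _ = _rng_streams(sim_config.rng_seed)

    areas = fields.cell_areas_km2()
    water = ~fields.land_mask
    if habitat is not None:
        if grid is None:
            raise ValueError("habitat-restricted seeding requires a grid")
        suitable = _suitable_set(habitat)
        LON, LAT = np.meshgrid(fields.lon, fields.lat)
        in_hab = np.isin(grid.cell(LON.ravel(), LAT.ravel()), list(suitable)).reshape(water.shape)
        water = water & in_hab
    if not water.any():
        raise ValueError("empty water domain")
    cell_area = np.where(water, areas, 0.0)
    total_area = cell_area.sum()

    n = int(place_rng.poisson(sim_config.seed_density * total_area))
    if n == 0:
        raise ValueError("seeding produced zero particles; increase density")
    flat_p = (cell_area / total_area).ravel()
    choice = place_rng.choice(len(flat_p), size=n, p=flat_p)
    iy, ix = np.unravel_index(choice, cell_area.shape)
    dlon = fields.lon[1] - fields.lon[0]
    dlat = fields.lat[1] - fields.lat[0]
    lon = fields.lon[ix] + (place_rng.random(n) - 0.5) * dlon
    lat = fields.lat[iy] + (place_rng.random(n) - 0.5) * dlat

    w_sink = sample_clipped_normal(
        behavior.sink_mean, behavior.sink_sd, behavior.trait_clip_nsd, n, trait_rng
    )
    w_swim = sample_clipped_normal(
        behavior.swim_mean, behavior.swim_sd, behavior.trait_clip_nsd, n, trait_rng
    )
    t0 = sim_config.spawn_t_days
    mld = fields.mixed_layer_depth(lon, lat, np.full(n, t0))
    z_noise = sample_clipped_normal(
        0.0, behavior.pref_depth_sd, behavior.pref_clip_nsd, n, trait_rng
    )
    z_pref = np.maximum(mld + z_noise, behavior.surface_clearance)

    if behavior.mode == FIXED_DEPTH:
        z0 = np.full(n, behavior.fixed_depth_value)
    else:
        bathy = fields.bathymetry(lon, lat)
        z0 = np.clip(z_pref, behavior.surface_clearance,
                     np.maximum(bathy - behavior.bottom_clearance, behavior.surface_clearance))

    return ParticleCohort(
        lon=lon.copy(), lat=lat.copy(), z=z0.copy(),
        spawn_lon=lon, spawn_lat=lat, spawn_z=z0.copy(),
        w_sink=w_sink, w_swim=w_swim, z_pref=z_pref,
        status=np.zeros(n, dtype=np.int8),
        sim_config=sim_config, behavior=behavior,
    )


def run_simulation(cohort: ParticleCohort, fields, sim_config: SimConfig | None = None,
                   behavior: BehaviorConfig | None = None) -> ParticleCohort:
    """Advance the cohort through the full PLD, recording daily positions.

    Per step and active particle: RK4 advection, Milstein diffusion, then
    the vertical update (or a pinned fixed depth).  Particles whose new
    position has exactly zero interpolated speed are beached; particles
    leaving the lateral extent are exited; both freeze and are excluded
    downstream.  Diffusion noise for step k comes from a counter-derived
    stream so runs are reproducible and particle draws never reshuffle.
    """
    cfg = sim_config or cohort.sim_config
    beh = behavior or cohort.behavior
    n = len(cohort)
    spo = cfg.steps_per_output
    n_out = cfg.pld_days
    cohort.history = np.full((n, n_out, 3), np.nan)
    cohort.death_day = np.full(n, np.inf)
    _, _, diff_bg = _rng_streams(cfg.rng_seed)
    t0 = cfg.spawn_t_days

    lon, lat, z = cohort.lon, cohort.lat, cohort.z
    status = cohort.status
    fixed = beh.mode == FIXED_DEPTH
    if fixed:
        z[:] = beh.fixed_depth_value

    for k in range(cfg.n_steps):
        t = t0 + k * cfg.dt / 86400.0
        idx = np.flatnonzero(status == ACTIVE)
        if idx.size == 0:
            break
        # counter-based noise: step k's generator, slots (2i, 2i+1) per particle
        step_rng = np.random.Generator(diff_bg.jumped(k + 1))
        dW_all = step_rng.normal(0.0, np.sqrt(cfg.dt), size=(n, 2))

        alon, alat = rk4_advect(fields, lon[idx], lat[idx], z[idx], t, cfg.dt)
        alon, alat = milstein_diffuse(
            fields, alon, alat, z[idx], t, cfg.dt, dW=(dW_all[idx, 0], dW_all[idx, 1])
        )
        inside = np.asarray(fields.in_domain(alon, alat))
        day_frac = (k + 1) * cfg.dt / 86400.0

        out = idx[~inside]
        status[out] = EXITED
        cohort.death_day[out] = day_frac

        stay = idx[inside]
        alon, alat = alon[inside], alat[inside]
        if fixed:
            az = np.full(stay.size, beh.fixed_depth_value)
        else:
            bathy = fields.bathymetry(alon, alat)
            az = vertical_step(
                z[stay], cohort.z_pref[stay], cohort.w_sink[stay], cohort.w_swim[stay],
                bathy, cfg.dt, beh.surface_clearance, beh.bottom_clearance,
            )
        lon[stay], lat[stay], z[stay] = alon, alat, az

        # land is exactly the zero-interpolated-velocity region (the fields
        # contract), so the beach test is the land-cell test; this avoids
        # false positives at interior stagnation points of symmetric flows
        beach = stay[np.asarray(fields.is_land(alon, alat))]
        status[beach] = BEACHED
        cohort.death_day[beach] = day_frac

        if (k + 1) % spo == 0:
            day = (k + 1) // spo
            live = np.flatnonzero(status == ACTIVE)
            cohort.history[live, day - 1, 0] = lon[live]
            cohort.history[live, day - 1, 1] = lat[live]
            cohort.history[live, day - 1, 2] = z[live]
    return cohort


def _suitable_set(habitat) -> frozenset:
    if isinstance(habitat, HabitatMap):
        return habitat.cells
    cells = frozenset()
    for h in habitat:
        cells = cells | h.cells
    return cells


def resolve_settlement(
    cohort: ParticleCohort,
    case: str,
    habitat: HabitatMap | list | None = None,
    grid: HexGrid | None = None,
) -> ParticleCohort:
    """Assign settlement outcomes; returns a resolved copy.

    ``case`` is 'FD', 'PD' (settle at the final-day position) or 'SH'
    (suitable spawn required; settle at the first daily output in the
    competency window over suitable habitat, else nonviable).  The same
    simulated cohort may be resolved under several cases.
    """
    case = case.upper()
    if case not in ("FD", "PD", "SH"):
        raise ValueError("case must be FD, PD or SH")
    if cohort.history is None:
        raise ValueError("run_simulation before resolving settlement")
    out = cohort.copy()
    out.case = case
    n = len(out)
    cfg = out.sim_config
    out.settle_lon = np.full(n, np.nan)
    out.settle_lat = np.full(n, np.nan)
    out.settle_day = np.full(n, -1, dtype=np.int32)

    if case in ("FD", "PD"):
        idx = np.flatnonzero(out.status == ACTIVE)
        out.status[idx] = SETTLED
        out.settle_lon[idx] = out.lon[idx]
        out.settle_lat[idx] = out.lat[idx]
        out.settle_day[idx] = cfg.pld_days
        return out

    if habitat is None or grid is None:
        raise ValueError("SH case requires a habitat map and a grid")
    suitable = np.array(sorted(_suitable_set(habitat)), dtype=np.int64)
    spawn_cells = grid.cell(out.spawn_lon, out.spawn_lat)
    eligible = np.isin(spawn_cells, suitable)

    undecided = eligible & (out.settle_day < 0)
    for day in cfg.competency_window:
        cand = np.flatnonzero(undecided)
        if cand.size == 0:
            break
        plon = out.history[cand, day - 1, 0]
        plat = out.history[cand, day - 1, 1]
        alive = np.isfinite(plon)
        cand = cand[alive]
        if cand.size == 0:
            continue
        cells = grid.cell(out.history[cand, day - 1, 0], out.history[cand, day - 1, 1])
        hit = np.isin(cells, suitable)
        settlers = cand[hit]
        out.status[settlers] = SETTLED
        out.settle_lon[settlers] = out.history[settlers, day - 1, 0]
        out.settle_lat[settlers] = out.history[settlers, day - 1, 1]
        out.settle_day[settlers] = day
        undecided[settlers] = False

    fail = (out.status == ACTIVE) & (out.settle_day < 0)
    out.status[fail] = NONVIABLE
    return out
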