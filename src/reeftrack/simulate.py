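"""Synthetic seascape, trajectory and observation generator.

Every pipeline stage needs a closed-loop test with known ground truth,
so this module emulates the study system end to end: a ~15 km^2 array of
point reefs over gently sloping sand bottom, reef-attracted fish whose
activity is modulated by time of day, stochastic switching between
reefs, emigration from the array as exponential decay, and a
positioning-system observation layer with spatially varying error and a
precision score (HPE) linearly related to true error.

Movement model.  While resident at a reef the fish follows an
Ornstein-Uhlenbeck process per horizontal axis: attraction rate ``beta``
(1/s) toward the reef, instantaneous volatility ``sigma_b * m(hour)``
(m/sqrt(s)) with a diel multiplier profile ``m``.  Transitions are
sampled exactly (the OU transition density is Gaussian with mean
``r + (x - r) exp(-beta dt)`` and variance ``sigma^2 (1 - exp(-2 beta
dt)) / (2 beta)``), so the truth grid step ``truth_dt`` introduces no
discretisation error; 1 s is the default, and large cohort runs may use
a coarser grid.  Reef switches arrive at hazard ``switch_rate`` per day
(new reef drawn with probability ~ exp(-distance/switch_scale));
emigration arrives at hazard ``emigration_rate`` per day, after which
the fish walks out of the array and is lost.  Depth follows an
hour-of-day height-above-bottom profile above the local seabed.

Observation model.  Fix times are drawn with uniform random intervals;
horizontal error is isotropic Gaussian with a per-axis sd interpolating
from the array centre to its edge; the HPE score is generated by
inverting the assumed linear 2DRMS model, ``hpe = (2*sqrt(2)*s(x) -
intercept)/slope``, times lognormal noise — so calibration recovery is
well-posed by construction.  Surveyed receivers emit self-fixes the same
way, providing the calibration input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BathymetryGrid

__all__ = [
    "SimConfig",
    "Seascape",
    "TruthBundle",
    "SimStudy",
    "generate_seascape",
    "simulate_fish",
    "simulate_observations",
    "simulate_study",
]


def _default_diel() -> tuple:
    # crepuscular-peaked activity multiplier by UTC hour
    hours = np.arange(24)
    m = 0.7 + 0.45 * (
        np.exp(-0.5 * ((hours - 11) / 1.5) ** 2)
        + np.exp(-0.5 * ((hours - 23) / 1.5) ** 2)
        + np.exp(-0.5 * ((hours + 1) / 1.5) ** 2)
    )
    return tuple(np.round(m, 4))


def _default_hab() -> tuple:
    # height above bottom (m) by UTC hour: near-bottom at night, higher midday
    hours = np.arange(24)
    return tuple(np.round(2.0 + 6.0 * np.exp(-0.5 * ((hours - 18) / 4.0) ** 2), 3))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic system (defaults emulate a
    15 km^2, 30-m-depth array)."""

    seed: int = 0
    # seascape
    extent_m: float = 3900.0          # square array side; 3900^2 ~ 15.2 km^2
    n_reefs: int = 30
    min_reef_spacing_m: float = 88.0  # minimum observed reef separation
    reef_margin_m: float = 250.0      # keep reefs off the array edge
    receiver_spacing_m: float = 500.0
    receiver_reef_clearance_m: float = 10.0
    depth_range_m: tuple = (28.0, 35.0)  # sloping seabed across the extent
    bathy_cell_m: float = 30.0
    # behaviour
    n_fish: int = 25
    study_days: float = 120.0
    truth_dt_s: float = 1.0
    attraction_beta: float = 0.005       # 1/s
    base_step_sd: float = 0.6            # m / sqrt(s)
    diel_multiplier: tuple = field(default_factory=_default_diel)
    switch_rate_per_day: float = 0.2
    switch_scale_m: float = 500.0
    emigration_rate_per_day: float = float(np.log(2) / 43.0)
    removal_rate_per_day: float = 0.006  # predation / tag loss / harvest ...
    fate_mix: tuple = (
        ("predation", 0.4), ("tag_loss", 0.3), ("harvest", 0.15), ("unknown", 0.15),
    )
    hab_profile_m: tuple = field(default_factory=_default_hab)
    hab_noise_m: float = 0.5
    # observation
    fix_interval_s: tuple = (60.0, 180.0)
    error_sd_centre_m: float = 0.5   # per-axis positional error sd
    error_sd_edge_m: float = 4.0
    error_sd_lognorm_sd: float = 0.25  # per-fix condition variability of the sd
    hpe_slope: float = 0.5           # 2DRMS = slope * HPE + intercept
    hpe_intercept: float = 0.3
    hpe_noise_sd: float = 0.02       # extra lognormal sd on generated HPE
    depth_noise_m: float = 0.3
    n_receiver_fixes: int = 200
    depth_sensor_only: bool = False
    epoch: str = "2016-05-01T00:00:00Z"


@dataclass
class Seascape:
    stations: pd.DataFrame
    bathymetry: BathymetryGrid
    boundary: tuple  # (x_min, x_max, y_min, y_max)

    @property
    def reefs(self) -> pd.DataFrame:
        return (
            self.stations[self.stations["kind"] == "reef"]
            .sort_values("station_id", kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def centre(self) -> tuple:
        x0, x1, y0, y1 = self.boundary
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def generate_seascape(config: SimConfig, rng: np.random.Generator | None = None) -> Seascape:
    """Reefs by min-spacing rejection sampling + a receiver grid + sloping bed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.extent_m
    lo, hi = config.reef_margin_m, L - config.reef_margin_m
    if not hi > lo:
        raise ValueError("reef margin leaves no room inside the extent")

    reefs: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * config.n_reefs
    while len(reefs) < config.n_reefs:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {config.n_reefs} reefs at "
                f"{config.min_reef_spacing_m} m spacing after {max_attempts} draws"
            )
        x, y = rng.uniform(lo, hi, size=2)
        if all(
            (x - rx) ** 2 + (y - ry) ** 2 >= config.min_reef_spacing_m**2
            for rx, ry in reefs
        ):
            reefs.append((float(x), float(y)))

    rows = [
        {"station_id": f"R{i:02d}", "kind": "reef", "x": x, "y": y, "surveyed": False}
        for i, (x, y) in enumerate(reefs)
    ]

    # receivers: regular grid, nudged clear of reefs
    g = np.arange(config.receiver_spacing_m / 2.0, L, config.receiver_spacing_m)
    k = 0
    for gy in g:
        for gx in g:
            x, y = float(gx), float(gy)
            for rx, ry in reefs:
                if (x - rx) ** 2 + (y - ry) ** 2 < config.receiver_reef_clearance_m**2:
                    x += config.receiver_reef_clearance_m + 5.0
            rows.append(
                {"station_id": f"V{k:02d}", "kind": "receiver",
                 "x": x, "y": y, "surveyed": True}
            )
            k += 1
    stations = pd.DataFrame(rows)

    d0, d1 = config.depth_range_m
    cell = config.bathy_cell_m
    n = int(np.ceil(L / cell)) + 2
    xc = (np.arange(n) + 0.5) * cell - cell  # grid starts one cell before 0
    depth_row = d0 + (d1 - d0) * np.clip(xc / L, 0.0, 1.0)
    depth = np.tile(depth_row, (n, 1))
    bathy = BathymetryGrid(x0=-cell, y0=-cell, cell=cell, depth=depth)
    return Seascape(stations=stations, bathymetry=bathy, boundary=(0.0, L, 0.0, L))


@dataclass
class TruthBundle:
    """Ground truth for a simulated cohort.

    ``pos[i, f]`` is (x, y, depth) of fish ``f`` at ``times[i]`` seconds
    after the epoch (NaN once the fish is gone).  ``switch_log`` records
    behavioural reef re-assignments; ``fates`` records each fish's
    terminal event in seconds.  Truth is never given to pipeline stages
    under test — observations are derived from it.
    """

    times: np.ndarray
    pos: np.ndarray  # (n_times, n_fish, 3) float32
    fish_ids: list
    release_reef: dict
    switch_log: pd.DataFrame  # fish_id, t_s, from_reef, to_reef
    fates: pd.DataFrame       # fish_id, fate, t_s
    last_active_s: dict
    epoch: pd.Timestamp
    config: SimConfig

    def seabed_depth(self, x, y):
        d0, d1 = self.config.depth_range_m
        return d0 + (d1 - d0) * np.clip(
            np.asarray(x, dtype=float) / self.config.extent_m, 0.0, 1.0
        )


def simulate_fish(
    seascape: Seascape, config: SimConfig, seed: int | None = None
) -> TruthBundle:
    """Simulate the whole cohort's true trajectories on the truth grid."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    reefs = seascape.reefs
    reef_ids = reefs["station_id"].to_numpy()
    reef_xy = reefs[["x", "y"]].to_numpy(dtype=float)
    n_reef = len(reefs)
    nf = config.n_fish
    dt = config.truth_dt_s
    n_steps = int(round(config.study_days * 86400.0 / dt))
    L = config.extent_m

    diel = np.asarray(config.diel_multiplier, dtype=float)
    hab = np.asarray(config.hab_profile_m, dtype=float)
    beta = config.attraction_beta
    decay = np.exp(-beta * dt)
    # exact OU transition sd for unit volatility
    ou_scale = np.sqrt((1.0 - decay**2) / (2.0 * beta))

    # hazards (per second)
    sw = config.switch_rate_per_day / 86400.0
    em = config.emigration_rate_per_day / 86400.0
    rm = config.removal_rate_per_day / 86400.0

    release_idx = rng.integers(0, n_reef, size=nf)
    xy = reef_xy[release_idx] + rng.normal(0.0, 2.0, size=(nf, 2))
    current = release_idx.copy()
    emigrating = np.zeros(nf, dtype=bool)
    alive = np.ones(nf, dtype=bool)
    exit_target = np.zeros((nf, 2))

    def exp_draw(rate, size):
        return (rng.exponential(1.0 / rate, size=size)
                if rate > 0 else np.full(size, np.inf))

    next_switch = exp_draw(sw, nf) if sw > 0 else np.full(nf, np.inf)
    t_emig = exp_draw(em, nf)
    t_removal = exp_draw(rm, nf)
    fate_names = [f for f, _ in config.fate_mix]
    fate_p = np.array([p for _, p in config.fate_mix], dtype=float)
    fate_p = fate_p / fate_p.sum()
    removal_fate = rng.choice(len(fate_names), size=nf, p=fate_p)

    times = np.arange(n_steps, dtype=float) * dt
    pos = np.full((n_steps, nf, 3), np.nan, dtype=np.float32)
    switch_rows = []
    fate_rows: dict[int, tuple[str, float]] = {}
    last_active = np.zeros(nf)

    d0, d1 = config.depth_range_m

    for i in range(n_steps):
        t = times[i]
        if not alive.any():
            break
        hour = int(t / 3600.0) % 24
        m = diel[hour]
        sd = config.base_step_sd * m * ou_scale

        # removals (predation, tag loss, ...)
        gone = alive & (t >= t_removal)
        for f in np.flatnonzero(gone):
            fate_rows[f] = (fate_names[removal_fate[f]], float(t_removal[f]))
            alive[f] = False

        # emigration trigger: head for the nearest boundary, then exit
        trig = alive & ~emigrating & (t >= t_emig)
        for f in np.flatnonzero(trig):
            emigrating[f] = True
            fate_rows[f] = ("emigration", float(t_emig[f]))
            x, y = xy[f]
            edges = np.array(
                [[-300.0, y], [L + 300.0, y], [x, -300.0], [x, L + 300.0]]
            )
            exit_target[f] = edges[np.argmin(np.abs([x, L - x, y, L - y]))]

        # reef switches (distance-weighted choice of a different reef)
        do_switch = alive & ~emigrating & (t >= next_switch)
        for f in np.flatnonzero(do_switch):
            d = np.hypot(*(reef_xy - xy[f]).T)
            w = np.exp(-d / config.switch_scale_m)
            w[current[f]] = 0.0
            w = w / w.sum()
            new = int(rng.choice(n_reef, p=w))
            switch_rows.append(
                (reef_ids[current[f]], reef_ids[new], float(t), f)
            )
            current[f] = new
            next_switch[f] = t + float(exp_draw(sw, 1)[0])

        act = np.flatnonzero(alive)
        if len(act):
            target = np.where(
                emigrating[act, None], exit_target[act], reef_xy[current[act]]
            )
            xy[act] = target + (xy[act] - target) * decay + sd * rng.standard_normal(
                (len(act), 2)
            )
            # emigrated fish past the boundary are lost to the array
            out = (
                (xy[act, 0] < 0) | (xy[act, 0] > L)
                | (xy[act, 1] < 0) | (xy[act, 1] > L)
            )
            for f in act[out]:
                alive[f] = False

            act = np.flatnonzero(alive)
            if len(act):
                seabed = d0 + (d1 - d0) * np.clip(xy[act, 0] / L, 0.0, 1.0)
                h = hab[hour] + rng.normal(0.0, config.hab_noise_m, size=len(act))
                depth = np.clip(seabed - h, 0.3, seabed - 0.1)
                pos[i, act, 0] = xy[act, 0]
                pos[i, act, 1] = xy[act, 1]
                pos[i, act, 2] = depth
                last_active[act] = t

    fish_ids = [f"F{i:02d}" for i in range(nf)]
    for f in range(nf):
        if f not in fate_rows:
            fate_rows[f] = ("at_large", float(times[-1]))
    fates = pd.DataFrame(
        [
            {"fish_id": fish_ids[f], "fate": fate_rows[f][0], "t_s": fate_rows[f][1]}
            for f in range(nf)
        ]
    )
    switch_log = pd.DataFrame(
        [
            {"fish_id": fish_ids[f], "t_s": t, "from_reef": a, "to_reef": b}
            for a, b, t, f in switch_rows
        ],
        columns=["fish_id", "t_s", "from_reef", "to_reef"],
    )
    return TruthBundle(
        times=times,
        pos=pos,
        fish_ids=fish_ids,
        release_reef={fish_ids[f]: reef_ids[release_idx[f]] for f in range(nf)},
        switch_log=switch_log,
        fates=fates,
        last_active_s={fish_ids[f]: float(last_active[f]) for f in range(nf)},
        epoch=pd.Timestamp(config.epoch),
        config=config,
    )


def _error_sd(x, y, config: SimConfig):
    """Per-axis positional error sd, interpolating centre -> edge."""
    c = config.extent_m / 2.0
    d_norm = np.clip(
        np.maximum(np.abs(np.asarray(x) - c), np.abs(np.asarray(y) - c)) / c, 0.0, 1.0
    )
    return config.error_sd_centre_m + (
        config.error_sd_edge_m - config.error_sd_centre_m
    ) * d_norm


def _per_fix_sd(x, y, config: SimConfig, rng: np.random.Generator):
    """Per-fix error sd: spatial mean times lognormal condition variability.

    The positioning system's per-fix precision score tracks this same
    per-fix scale (see :func:`_hpe_from_sd`), which is what makes the
    2DRMS-on-HPE regression linear in expectation and the calibration
    recoverable.
    """
    base = _error_sd(x, y, config)
    n = np.shape(base) if np.ndim(base) else None
    if config.error_sd_lognorm_sd > 0:
        base = base * np.exp(
            rng.normal(0.0, config.error_sd_lognorm_sd, size=n)
        )
    return base


def _hpe_from_sd(s, config: SimConfig, rng: np.random.Generator):
    """Invert the linear 2DRMS model (+ lognormal noise) to generate HPE."""
    true_2drms = 2.0 * np.sqrt(2.0) * np.asarray(s, dtype=float)
    hpe = np.maximum((true_2drms - config.hpe_intercept) / config.hpe_slope, 0.0)
    if config.hpe_noise_sd > 0:
        hpe = hpe * np.exp(rng.normal(0.0, config.hpe_noise_sd, size=np.shape(hpe)))
    return hpe


def simulate_observations(
    truth: TruthBundle,
    seascape: Seascape,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the positioning-system output from ground truth.

    Returns ``(positions, receiver_fixes)``.  ``positions`` is a
    pipeline-ready fix table (``fish_id, t, x, y, depth, hpe``) that also
    carries the truth columns ``true_x, true_y, true_depth, true_error``
    for closed-loop checks.  ``receiver_fixes`` holds surveyed-receiver
    self-fixes with deviations ``dx, dy`` for calibration.
    """
    config = truth.config if config is None else config
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    lo_i, hi_i = config.fix_interval_s
    frames = []
    for f, fish_id in enumerate(truth.fish_ids):
        t_end = truth.last_active_s[fish_id]
        if t_end <= lo_i:
            continue
        n_max = int(t_end / lo_i) + 2
        ft = np.cumsum(rng.uniform(lo_i, hi_i, size=n_max))
        ft = ft[ft <= t_end]
        if len(ft) == 0:
            continue
        tx = np.interp(ft, truth.times, truth.pos[:, f, 0])
        ty = np.interp(ft, truth.times, truth.pos[:, f, 1])
        tz = np.interp(ft, truth.times, truth.pos[:, f, 2])
        ok = ~(np.isnan(tx) | np.isnan(ty))
        ft, tx, ty, tz = ft[ok], tx[ok], ty[ok], tz[ok]
        if len(ft) == 0:
            continue
        s = _per_fix_sd(tx, ty, config, rng)
        ex = rng.normal(0.0, 1.0, size=len(ft)) * s
        ey = rng.normal(0.0, 1.0, size=len(ft)) * s
        hpe = _hpe_from_sd(s, config, rng)
        depth = tz + rng.normal(0.0, config.depth_noise_m, size=len(ft))
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": fish_id,
                    "t": truth.epoch + pd.to_timedelta(ft, unit="s"),
                    "x": tx + ex,
                    "y": ty + ey,
                    "depth": np.maximum(depth, 0.0),
                    "hpe": hpe,
                    "true_x": tx,
                    "true_y": ty,
                    "true_depth": tz,
                    "true_error": np.hypot(ex, ey),
                }
            )
        )
    positions = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["fish_id", "t", "x", "y", "depth", "hpe"])
    )

    recv = seascape.stations[
        (seascape.stations["kind"] == "receiver") & seascape.stations["surveyed"]
    ]
    rows = []
    span = config.study_days * 86400.0
    for _, r in recv.iterrows():
        n = config.n_receiver_fixes
        s = _per_fix_sd(
            np.full(n, r["x"]), np.full(n, r["y"]), config, rng
        )
        rt = np.sort(rng.uniform(0.0, span, size=n))
        dx = rng.normal(0.0, s, size=n)
        dy = rng.normal(0.0, s, size=n)
        hpe = _hpe_from_sd(s, config, rng)
        rows.append(
            pd.DataFrame(
                {
                    "station_id": r["station_id"],
                    "t": truth.epoch + pd.to_timedelta(rt, unit="s"),
                    "x": r["x"] + dx,
                    "y": r["y"] + dy,
                    "dx": dx,
                    "dy": dy,
                    "hpe": hpe,
                }
            )
        )
    receiver_fixes = pd.concat(rows, ignore_index=True)
    return positions, receiver_fixes


@dataclass
class SimStudy:
    """Everything one closed-loop run needs, in pipeline dialects."""

    config: SimConfig
    seascape: Seascape
    truth: TruthBundle
    positions: pd.DataFrame
    receiver_fixes: pd.DataFrame

    @property
    def fates(self) -> pd.DataFrame:
        f = self.truth.fates
        return pd.DataFrame(
            {
                "fish_id": f["fish_id"],
                "fate": f["fate"],
                "t": self.truth.epoch + pd.to_timedelta(f["t_s"], unit="s"),
            }
        )

    @property
    def release_time(self) -> dict:
        return {fid: self.truth.epoch for fid in self.truth.fish_ids}

    @property
    def last_time(self) -> dict:
        return {
            fid: self.truth.epoch + pd.Timedelta(seconds=s)
            for fid, s in self.truth.last_active_s.items()
        }


def simulate_study(config: SimConfig) -> SimStudy:
    """Seascape + cohort + observations from one seeded configuration."""
    rng = np.random.default_rng(config.seed)
    seascape = generate_seascape(config, rng)
    truth = simulate_fish(seascape, config, seed=config.seed + 10_000)
    positions, receiver_fixes = simulate_observations(
        truth, seascape, config, seed=config.seed + 20_000
    )
    return SimStudy(
        config=config,
        seascape=seascape,
        truth=truth,
        positions=positions,
        receiver_fixes=receiver_fixes,
    )
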