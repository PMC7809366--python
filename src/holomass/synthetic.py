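"""Synthetic single-cell dry-mass dynamics and lens-free imaging phantoms.

This module generates the inputs the analysis chain is designed for,
with known ground truth:

* dry-mass trajectories sampled every 5 minutes over a cell-cycle
  interphase: a linear growth background, plus a train of symmetric
  mass pulses (the injected ultradian rhythm), plus 1/f ("pink")
  biological noise, plus white measurement noise;
* cohorts of such trajectories with heterogeneous, lognormal cycle
  lengths, uniformly random pulse phases (asynchronous culture),
  division events and daughter tracks;
* two-dimensional optical phantoms of adherent cells whose integrated
  optical path difference encodes the instantaneous ground-truth mass,
  rendered into intensity-only inline holograms by Fresnel propagation;
* negative controls (residual-shuffled and constant-mass traces).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .drymass import ALPHA, DryMassTrace
from .holography import (ComplexField, SensorIntensity, propagate,
                         DEFAULT_PIXEL_PITCH, DEFAULT_WAVELENGTH)

__all__ = [
    "RhythmParams",
    "GrowthNoiseParams",
    "CohortConfig",
    "CellPhantom",
    "CellTruth",
    "GroundTruth",
    "pulse_train",
    "pink_noise",
    "generate_trace",
    "generate_cohort",
    "negative_control",
    "phantom_opd",
    "peak_opd_for_mass",
    "render_hologram",
    "render_phase_frames",
    "generate_scene",
    "write_ground_truth_json",
]


@dataclass
class RhythmParams:
    """Parameters of the injected ultradian mass rhythm.

    The default period of 250 min corresponds to the reported dominant
    frequency of 0.004 min^-1 (4.17 h).  The default pulse is a raised
    cosine of full width 60 min, i.e. 30 min full width at half
    maximum — the reported width of the reconstructed spikes — and
    100 pg amplitude.  ``pulse_sign`` selects mass rise (+1) or drop
    (-1); intensity-only cohort statistics cannot distinguish the two.
    """

    period: float = 250.0
    pulse_width: float = 60.0
    pulse_amplitude: float = 100.0
    pulse_shape: str = "raised-cosine"
    pulse_sign: int = 1

    def __post_init__(self) -> None:
        if not (self.period > self.pulse_width > 0):
            raise ValueError("require period > pulse_width > 0")
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be >= 0")
        if self.pulse_shape not in ("raised-cosine", "triangular"):
            raise ValueError(f"unknown pulse_shape {self.pulse_shape!r}")
        if self.pulse_sign not in (1, -1):
            raise ValueError("pulse_sign must be +1 or -1")


@dataclass
class GrowthNoiseParams:
    """Growth background and noise levels of a dry-mass trace.

    ``pink_noise_rms`` sets the standard deviation (pg) of the 1/f
    biological fluctuation per trace; ``measurement_noise_sd`` the white
    instrumental noise (pg), defaulting to the 35 pg precision of the
    lens-free dry-mass measurement.
    """

    initial_mass: float = 300.0        # pg
    growth_rate: float = 0.25          # pg / min
    pink_noise_rms: float = 100.0      # pg
    pink_noise_exponent: float = 2.0   # power-law slope of the power spectrum
    measurement_noise_sd: float = 35.0 # pg

    def __post_init__(self) -> None:
        if self.initial_mass <= 0:
            raise ValueError("initial_mass must be positive")
        if self.measurement_noise_sd < 0 or self.pink_noise_rms < 0:
            raise ValueError("noise levels must be >= 0")


@dataclass
class CohortConfig:
    """Cohort of asynchronously cycling cells observed at fixed cadence."""

    n_cells: int = 300
    sampling_interval: float = 5.0     # minutes
    cycle_distribution: str = "lognormal"
    cycle_median: float = 1200.0       # minutes
    cycle_sigma_log: float = 0.25
    duration: float = 4320.0           # minutes of total observation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.cycle_distribution != "lognormal":
            raise ValueError("only the lognormal cycle distribution is implemented")


@dataclass
class CellPhantom:
    """A radially symmetric optical phantom of one adherent cell."""

    center: tuple[float, float]        # (row, col) pixel coordinates
    radius: float                      # micrometres
    peak_opd: float                    # micrometres
    profile: str = "cosine-dome"       # or "uniform-disc"

    def __post_init__(self) -> None:
        if self.peak_opd < 0:
            raise ValueError("peak_opd must be >= 0")
        if self.profile not in ("cosine-dome", "uniform-disc"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass
class CellTruth:
    """Ground truth for one generated cell."""

    cell_id: int
    birth_time: float
    division_time: float | None
    duration: float
    phase_offset: float
    initial_mass: float
    growth_rate: float
    clean_masses: np.ndarray
    positions: np.ndarray | None = None   # (n_samples, 2) pixel coords
    parent: int | None = None


@dataclass
class GroundTruth:
    """Cohort-level ground truth."""

    rhythm: RhythmParams
    growth_noise: GrowthNoiseParams
    seed: int
    cells: list = field(default_factory=list)

    @property
    def durations(self) -> np.ndarray:
        return np.array([c.duration for c in self.cells])

    @property
    def phase_offsets(self) -> np.ndarray:
        return np.array([c.phase_offset for c in self.cells])


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------

def pulse_train(t: np.ndarray, rhythm: RhythmParams, phase_offset: float = 0.0) -> np.ndarray:
    """Periodic train of symmetric mass pulses evaluated at times ``t``.

    Pulses are centered at ``phase_offset + k * period``.  The raised
    cosine is ``A/2 (1 + cos(2 pi x / w))`` on ``|x| < w/2`` (full width
    ``w``, FWHM ``w/2``); the triangle is ``A (1 - 2|x|/w)``.
    """
    t = np.asarray(t, dtype=float)
    x = np.mod(t - phase_offset + rhythm.period / 2.0, rhythm.period) - rhythm.period / 2.0
    inside = np.abs(x) < rhythm.pulse_width / 2.0
    if rhythm.pulse_shape == "raised-cosine":
        p = 0.5 * (1.0 + np.cos(2.0 * np.pi * x / rhythm.pulse_width))
    else:
        p = 1.0 - 2.0 * np.abs(x) / rhythm.pulse_width
    return rhythm.pulse_sign * rhythm.pulse_amplitude * np.where(inside, p, 0.0)


def pink_noise(n: int, dt: float, rms: float, rng: np.random.Generator,
               exponent: float = 1.0) -> np.ndarray:
    """Zero-mean 1/f noise by spectral shaping of white Gaussian noise.

    The amplitude spectrum is proportional to ``f**(-exponent/2)`` (so
    the power spectrum falls as ``1/f**exponent``); the realization is
    rescaled to the requested standard deviation.
    """
    if rms == 0 or n < 2:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=dt)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal(n)
    x = np.fft.irfft(shape * np.fft.rfft(white), n)
    x -= x.mean()
    # normalize by the ensemble standard deviation (not the realization's,
    # which for red spectra is dominated by a single random slow component)
    s2 = shape ** 2
    ens_var = (s2[0] + (s2[-1] if n % 2 == 0 else 2 * s2[-1])
               + 2 * s2[1:-1].sum()) / n
    return x * (rms / np.sqrt(ens_var))


def generate_trace(rhythm: RhythmParams, gn: GrowthNoiseParams, T: float,
                   dt: float = 5.0, seed=None, phase_offset: float = 0.0,
                   track_id: int = 0) -> tuple[DryMassTrace, DryMassTrace]:
    """One interphase dry-mass trace plus its noise-free twin.

    ``T`` must cover at least two rhythm periods, otherwise the rhythm
    is not detectable and the request is rejected.  Samples run from 0
    to ``T`` inclusive in steps of ``dt`` (``dt`` must divide ``T``).
    """
    if T < 2.0 * rhythm.period:
        raise ValueError("trace duration must be at least two rhythm periods")
    n_steps = T / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("dt must divide T")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(int(round(n_steps)) + 1) * dt
    clean = gn.initial_mass + gn.growth_rate * t + pulse_train(t, rhythm, phase_offset)
    pink = pink_noise(t.size, dt, gn.pink_noise_rms, rng, gn.pink_noise_exponent)
    # anchor the biological fluctuation at birth so the trace starts at
    # the configured mass (a constant offset; removed by detrending)
    if pink.size:
        pink = pink - pink[0]
    noisy = clean + pink + gn.measurement_noise_sd * rng.standard_normal(t.size)
    return (DryMassTrace(track_id, t, noisy),
            DryMassTrace(track_id, t, clean.copy()))


def _random_walk(n: int, rng: np.random.Generator, shape: tuple[int, int],
                 start: np.ndarray | None = None, step_sd: float = 1.2,
                 margin: float = 20.0,
                 drift: np.ndarray | None = None) -> np.ndarray:
    """Reflected 2-D random walk in pixel coordinates.

    ``drift``, when given, is an (n-1, 2) deterministic displacement
    added to the random steps (used for post-division separation).
    """
    lo = np.array([margin, margin])
    hi = np.array([shape[0] - margin, shape[1] - margin])
    if start is None:
        start = rng.uniform(lo, hi)
    pos = np.empty((n, 2))
    pos[0] = np.clip(start, lo, hi)
    steps = step_sd * rng.standard_normal((n - 1, 2)) if n > 1 else np.empty((0, 2))
    if drift is not None and len(steps):
        steps[:drift.shape[0]] += drift[:steps.shape[0]]
    for i in range(1, n):
        p = pos[i - 1] + steps[i - 1]
        p = np.where(p < lo, 2 * lo - p, p)
        p = np.where(p > hi, 2 * hi - p, p)
        pos[i] = np.clip(p, lo, hi)
    return pos


def _draw_cycle_length(cfg: CohortConfig, rhythm: RhythmParams,
                       rng: np.random.Generator) -> float:
    T = float(np.exp(np.log(cfg.cycle_median) + cfg.cycle_sigma_log
                     * rng.standard_normal()))
    T = min(max(T, 2.0 * rhythm.period), cfg.duration)
    # snap to the sampling grid
    return round(T / cfg.sampling_interval) * cfg.sampling_interval


def generate_cohort(config: CohortConfig, rhythm: RhythmParams | None = None,
                    gn: GrowthNoiseParams | None = None,
                    with_positions: bool = False,
                    fov: tuple[int, int] = (256, 256),
                    ) -> tuple[list[DryMassTrace], GroundTruth]:
    """Generate an asynchronous cohort of interphase traces.

    Each cell draws its interphase duration from the configured
    lognormal distribution, a uniform pulse phase offset (asynchronous
    culture), and mild heterogeneity in birth mass; the growth rate is
    set so the cell doubles its mass over its cycle.  Division ends the
    interphase: the ground truth records the division time, and the
    mass discontinuity (drop to a fraction u ~ U(0.45, 0.55)) is what a
    continued track would show.

    Per-cell random substreams are spawned deterministically from the
    master seed, so a fixed seed reproduces the cohort bitwise.
    """
    rhythm = rhythm or RhythmParams()
    gn = gn or GrowthNoiseParams()
    streams = np.random.default_rng(config.seed).spawn(config.n_cells)
    traces: list[DryMassTrace] = []
    truth = GroundTruth(rhythm, gn, config.seed)
    dt = config.sampling_interval
    for j, rng in enumerate(streams):
        T = _draw_cycle_length(config, rhythm, rng)
        phase = float(rng.uniform(0.0, rhythm.period))
        m0 = float(gn.initial_mass * rng.uniform(0.85, 1.15))
        cell_gn = GrowthNoiseParams(m0, m0 / T, gn.pink_noise_rms,
                                    gn.pink_noise_exponent,
                                    gn.measurement_noise_sd)
        trace, clean = generate_trace(rhythm, cell_gn, T, dt, rng, phase,
                                      track_id=j)
        positions = (_random_walk(trace.times.size, rng, fov)
                     if with_positions else None)
        truth.cells.append(CellTruth(j, 0.0, T, T, phase, m0, m0 / T,
                                     clean.masses, positions))
        traces.append(trace)
    return traces, truth


def negative_control(trace: DryMassTrace, mode: str,
                     rng: np.random.Generator | int | None = None,
                     measurement_noise_sd: float = 35.0) -> DryMassTrace:
    """Rhythm-destroying control variants of a trace.

    ``shuffle`` permutes the detrended residuals and re-adds the linear
    trend (preserving the residual value multiset exactly); ``constant``
    emulates a fixed (non-growing) cell: flat mass plus measurement
    noise only.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t, m = trace.times, trace.masses
    if mode == "shuffle":
        coef = np.polyfit(t, m, 1)
        trend = np.polyval(coef, t)
        residuals = m - trend
        return DryMassTrace(trace.track_id, t, trend + rng.permutation(residuals))
    if mode == "constant":
        level = float(np.mean(m))
        noise = measurement_noise_sd * rng.standard_normal(t.size)
        return DryMassTrace(trace.track_id, t, level + noise)
    raise ValueError(f"unknown control mode {mode!r}")


# ---------------------------------------------------------------------------
# optical phantoms and holograms
# ---------------------------------------------------------------------------

# integral of the unit-peak cosine dome over its footprint, in units of R^2:
# int_0^R (1 + cos(pi r / R))/2 * 2 pi r dr = R^2 (pi/2 - 2/pi)
_DOME_INTEGRAL = np.pi / 2.0 - 2.0 / np.pi


def peak_opd_for_mass(mass: float, radius: float, profile: str = "cosine-dome",
                      alpha: float = ALPHA) -> float:
    """Peak OPD (um) so the phantom's integrated OPD equals ``mass * alpha``."""
    if profile == "cosine-dome":
        return mass * alpha / (_DOME_INTEGRAL * radius ** 2)
    return mass * alpha / (np.pi * radius ** 2)


def phantom_opd(shape: tuple[int, int], phantoms: list[CellPhantom],
                pixel_pitch: float = DEFAULT_PIXEL_PITCH) -> np.ndarray:
    """Render phantoms into a 2-D OPD map (um); overlapping OPDs add."""
    opd = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for ph in phantoms:
        rho = np.hypot(yy - ph.center[0], xx - ph.center[1]) * pixel_pitch
        if ph.profile == "cosine-dome":
            prof = np.where(rho < ph.radius,
                            0.5 * (1.0 + np.cos(np.pi * rho / ph.radius)), 0.0)
        else:
            # one-pixel soft edge keeps the integrated OPD accurate on
            # the discrete grid
            prof = np.clip((ph.radius - rho) / pixel_pitch + 0.5, 0.0, 1.0)
        opd += ph.peak_opd * prof
    return opd


def render_hologram(phantoms: list[CellPhantom], shape: tuple[int, int] = (256, 256),
                    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
                    wavelength: float = DEFAULT_WAVELENGTH, z: float = 1500.0,
                    shot_noise_photons: float | None = None,
                    rng: np.random.Generator | None = None) -> SensorIntensity:
    """Simulate the inline hologram of a phantom scene.

    The object field is the unit plane wave delayed by the phantom OPD,
    ``A_0 = exp(i 2 pi OPD / wavelength)``; it is Fresnel-propagated to
    the sensor at distance ``z`` and the intensity ``|A_Z|^2`` returned.
    With ``shot_noise_photons`` the intensity is Poisson-sampled at that
    mean photon count per unit-intensity pixel.
    """
    if z <= 0 or wavelength <= 0:
        raise ValueError("wavelength and z must be positive")
    opd = phantom_opd(shape, phantoms, pixel_pitch)
    a0 = ComplexField(np.exp(2j * np.pi * opd / wavelength), pixel_pitch, wavelength)
    intensity = np.abs(propagate(a0, z).values) ** 2
    if shot_noise_photons:
        rng = rng or np.random.default_rng()
        intensity = rng.poisson(intensity * shot_noise_photons) / shot_noise_photons
    return SensorIntensity(intensity, pixel_pitch, wavelength)


# ---------------------------------------------------------------------------
# imaging scenes with divisions
# ---------------------------------------------------------------------------

def generate_scene(n_cells: int = 5, n_frames: int = 180, shape=(288, 288),
                   rhythm: RhythmParams | None = None,
                   gn: GrowthNoiseParams | None = None,
                   dt: float = 5.0, peak_opd_um: float = 0.5,
                   round_peak_opd_um: float = 0.9,
                   cycle_median: float = 900.0, cycle_sigma_log: float = 0.2,
                   pixel_pitch: float = DEFAULT_PIXEL_PITCH, seed: int = 0,
                   step_sd: float = 1.2) -> GroundTruth:
    """A time-lapse scene of moving, growing, dividing cells.

    Cells are born at uniformly random cycle phases, so divisions are
    spread over the record.  At division the mother keeps a fraction
    ``u ~ U(0.45, 0.55)`` of her mass (her trajectory continues in
    place) and a daughter track is born on the next frame within 15
    pixels carrying the complement; the siblings then drift apart for a
    few frames, as freshly divided cells do.  Masses carry pink
    biological noise but no instrumental noise — that arises from the
    imaging chain.

    Each cell's phantom radius is set from its mid-life mass so the
    peak OPD stays near ``peak_opd_um`` (default 0.18 um, i.e. a phase
    of ~1.7 rad at 647 nm): heavier cells are wider, daughters are
    smaller, and phases stay below the wrapping point.

    The returned ground truth holds, per cell: birth/division frames,
    per-frame positions, per-frame true masses and radii.  Use
    :func:`render_phase_frames` (or :func:`render_hologram` per frame)
    to image it.
    """
    rhythm = rhythm or RhythmParams()
    gn = gn or GrowthNoiseParams()
    master = np.random.default_rng(seed)
    truth = GroundTruth(rhythm, gn, seed)
    times = np.arange(n_frames) * dt

    def spawn(cell_id, birth_frame, mass0, parent, rng, age_min=0.0):
        T = float(np.exp(np.log(cycle_median) + cycle_sigma_log * rng.standard_normal()))
        T = max(T, 2 * rhythm.period)
        remaining = max(T - age_min, 10 * dt)
        div_frame = birth_frame + int(round(remaining / dt))
        # the mother's last rendered frame is div_frame - 1; her
        # continuation takes over in place at div_frame
        last = min(div_frame - 1 if div_frame < n_frames else div_frame,
                   n_frames - 1)
        n = last - birth_frame + 1
        if n < 2:
            return None
        t_local = times[birth_frame:last + 1] - times[birth_frame]
        growth = mass0 / T
        phase = float(rng.uniform(0, rhythm.period))
        clean = mass0 + growth * t_local + pulse_train(t_local, rhythm, phase)
        pink = pink_noise(n, dt, gn.pink_noise_rms, rng, gn.pink_noise_exponent)
        # anchored at birth: mass is continuous through divisions
        clean = np.maximum(clean + (pink - pink[0] if pink.size else 0.0), 50.0)
        cell = CellTruth(cell_id, times[birth_frame],
                         times[div_frame] if div_frame < n_frames else None,
                         t_local[-1], phase, mass0, growth, clean, None, parent)
        cell.birth_frame = birth_frame
        cell.last_frame = last
        cell.division_frame = div_frame if div_frame < n_frames else None
        cell.radius = float(np.sqrt(np.mean(clean) * ALPHA
                                    / (_DOME_INTEGRAL * peak_opd_um)))
        # freshly divided cells are rounded (compact, optically dense)
        # and re-spread over ~30 min; mass is conserved throughout
        radii = np.full(n, cell.radius)
        if parent is not None:
            r_round = float(np.sqrt(clean[0] * ALPHA
                                    / (_DOME_INTEGRAL * round_peak_opd_um)))
            k = min(10, n)
            radii[:k] = r_round + (cell.radius - r_round) * np.linspace(0, 1, k)
        cell.radii = radii
        return cell

    # ---- lineage and masses (positions come from the joint walk below)
    queue = []
    for i in range(n_cells):
        rng = np.random.default_rng(int(master.integers(2 ** 31)))
        # cells start mid-cycle so divisions are spread over the record
        age_min = float(rng.uniform(0, cycle_median))
        mass0 = float(gn.initial_mass * rng.uniform(0.85, 1.15))
        mass0 *= 1.0 + 0.5 * age_min / cycle_median  # grown since birth
        queue.append((0, mass0, None, rng, age_min, ("free", None, None)))
    next_id = 0
    init_rule: dict[int, tuple] = {}
    while queue:
        birth_frame, mass0, parent, rng, age_min, rule = queue.pop(0)
        cell = spawn(next_id, birth_frame, mass0, parent, rng, age_min)
        init_rule[next_id] = rule
        next_id += 1
        if cell is None:
            continue
        truth.cells.append(cell)
        if cell.division_frame is not None and cell.division_frame + 1 < n_frames:
            u = float(rng.uniform(0.45, 0.55))
            m_div = cell.clean_masses[-1]
            ang = float(rng.uniform(0, 2 * np.pi))
            unit = np.array([np.sin(ang), np.cos(ang)])
            # mother continues in place with fraction u (same physical track)
            cont_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
            queue.insert(0, (cell.division_frame, u * m_div, cell.cell_id,
                             cont_rng, 0.0, ("inherit", cell.cell_id, None)))
            # flag set after spawn: peek at the id it will get
            d_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
            queue.insert(1, (cell.division_frame + 1, (1 - u) * m_div,
                             cell.cell_id, d_rng, 0.0,
                             ("offset", cell.cell_id, unit)))

    by_id = {c.cell_id: c for c in truth.cells}
    for c in truth.cells:
        if init_rule[c.cell_id][0] == "inherit":
            c.is_continuation = True

    # ---- joint position simulation with soft contact repulsion
    walk_rng = np.random.default_rng(int(master.integers(2 ** 31)))
    margin = 25.0
    lo = np.array([margin, margin])
    hi = np.array(shape, float) - margin
    starts: list[np.ndarray] = []
    tries = 0
    while len(starts) < n_cells:
        p = walk_rng.uniform(lo, hi)
        tries += 1
        if all(np.hypot(*(p - q)) >= 55.0 for q in starts) or tries > 50 * n_cells:
            starts.append(p)
    roots = [c for c in truth.cells if c.parent is None]
    for c in truth.cells:
        c.positions = np.empty((c.clean_masses.size, 2))
    pos: dict[int, np.ndarray] = {}
    for F in range(n_frames):
        # activate cells born at F
        for c in truth.cells:
            if c.birth_frame != F:
                continue
            kind, src, unit = init_rule[c.cell_id]
            if kind == "free":
                p0 = starts[roots.index(c)]
            elif kind == "inherit":
                p0 = by_id[src].positions[-1].copy()
            else:  # daughter: appears within 15 px of the mother's last spot
                p0 = by_id[src].positions[-1] + 13.0 * unit
            pos[c.cell_id] = np.clip(p0, lo, hi)
        live = [c for c in truth.cells
                if c.birth_frame <= F <= c.last_frame and c.cell_id in pos]
        # advance positions (random motility plus contact repulsion)
        for c in sorted(live, key=lambda c: c.cell_id):
            if F == c.birth_frame:
                continue
            step = step_sd * walk_rng.standard_normal(2)
            p = pos[c.cell_id]
            for other in live:
                if other.cell_id == c.cell_id:
                    continue
                q = pos[other.cell_id]
                d = float(np.hypot(*(p - q)))
                # cells exclude each other a little beyond their optical
                # footprint (lamellipodia), which keeps neighbours
                # resolvable at the blob-detection scale
                r_int = (c.radii[F - c.birth_frame]
                         + other.radii[min(F - other.birth_frame,
                                           other.radii.size - 1)]) / pixel_pitch + 8.0
                if 0 < d < r_int:
                    step += min(1.0 * (r_int - d), 3.0) * (p - q) / d
            p = p + step
            p = np.where(p < lo, 2 * lo - p, p)
            p = np.where(p > hi, 2 * hi - p, p)
            pos[c.cell_id] = np.clip(p, lo, hi)
        for c in live:
            c.positions[F - c.birth_frame] = pos[c.cell_id]
        for c in live:
            if c.last_frame == F:
                del pos[c.cell_id]
    truth.n_frames = n_frames
    truth.shape = shape
    truth.dt = dt
    truth.pixel_pitch = pixel_pitch
    return truth


def truth_trajectories(truth: GroundTruth) -> tuple[dict, dict]:
    """Merge each cell and its in-place continuations into one physical
    trajectory, the object a tracker is expected to reproduce.

    Returns ``(positions, frames)``: per-trajectory (n, 2) pixel
    positions and the matching frame indices.
    """
    by_id = {c.cell_id: c for c in truth.cells}
    children: dict[int, int] = {}
    for c in truth.cells:
        if getattr(c, "is_continuation", False) and c.parent in by_id:
            children[c.parent] = c.cell_id
    roots = [c for c in truth.cells if not getattr(c, "is_continuation", False)]
    positions, frames = {}, {}
    for root in roots:
        pos = [root.positions]
        frs = [np.arange(root.positions.shape[0]) + getattr(root, "birth_frame", 0)]
        k = root.cell_id
        while k in children:
            k = children[k]
            c = by_id[k]
            pos.append(c.positions)
            frs.append(np.arange(c.positions.shape[0]) + getattr(c, "birth_frame", 0))
        positions[root.cell_id] = np.concatenate(pos)
        frames[root.cell_id] = np.concatenate(frs)
    return positions, frames


def render_phase_frames(truth: GroundTruth, profile: str = "cosine-dome") -> np.ndarray:
    """Render a scene's ground truth into object-plane phase images.

    Each cell becomes a phantom whose integrated OPD encodes its
    instantaneous true mass; the result is the ideal (noise-free,
    retrieval-free) phase stack, radians.
    """
    shape = truth.shape
    wavelength = DEFAULT_WAVELENGTH
    stack = np.zeros((truth.n_frames,) + tuple(shape))
    for cell in truth.cells:
        bf = getattr(cell, "birth_frame", 0)
        if getattr(cell, "is_continuation", False):
            bf = bf  # continuations render like any cell
        for i in range(cell.clean_masses.size):
            f = bf + i
            if f >= truth.n_frames:
                break
            radius = float(cell.radii[i]) if hasattr(cell, "radii") else cell.radius
            ph = CellPhantom(tuple(cell.positions[i]), radius,
                             peak_opd_for_mass(cell.clean_masses[i], radius,
                                               profile), profile)
            stack[f] += 2 * np.pi * phantom_opd(shape, [ph], truth.pixel_pitch) \
                / wavelength
    return stack


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    doc = {
        "seed": truth.seed,
        "rhythm": asdict(truth.rhythm),
        "growth_noise": asdict(truth.growth_noise),
        "cells": [
            {
                "cell_id": c.cell_id,
                "birth_time": c.birth_time,
                "division_time": c.division_time,
                "duration": c.duration,
                "phase_offset": c.phase_offset,
                "initial_mass": c.initial_mass,
                "growth_rate": c.growth_rate,
            }
            for c in truth.cells
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
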