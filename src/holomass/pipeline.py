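"""End-to-end orchestration: simulate, reconstruct, track, mass, spectrum.

Two run modes:

``traces-only``
    The generator feeds the spectral analysis directly, which makes the
    cohort-statistics claims testable at desk scale.

``full-imaging``
    Phantom scenes are rendered into holograms, phases are retrieved by
    the TV-regularized inversion, cells are detected, segmented and
    tracked, dry-mass traces are assembled, and the spectral analysis
    runs on the result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import drymass, holography, segtrack, spectral, synthetic

__all__ = [
    "SpectralConfig",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "compare_conditions",
    "load_config",
    "save_config",
]


@dataclass
class SpectralConfig:
    n_f: int = 1
    band_low: float = 0.001
    band_high: float = 0.02
    threshold: float = spectral.SIGNIFICANCE_THRESHOLD
    reconstruction_duration: float = 2880.0

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_low, self.band_high)


@dataclass
class ImagingConfig:
    n_cells: int = 5
    n_frames: int = 40
    shape: tuple[int, int] = (256, 256)
    phase_threshold: float = 0.15
    apply_correction: bool = True
    #: peak OPD of spread cells, kept below the pi wrapping point so the
    #: retrieval + unwrap chain stays quantitative
    peak_opd_um: float = 0.30
    round_peak_opd_um: float = 0.45


@dataclass
class PipelineConfig:
    """Nested configuration for a full run; defaults follow the
    reference setup (5-min sampling, M = 25, 15 iterations, epsilon
    1e-4, alpha 0.18, LAP linker defaults)."""

    mode: str = "traces-only"            # or "full-imaging"
    seed: int = 0
    outdir: str = "holomass_run"
    rhythm: synthetic.RhythmParams = field(default_factory=synthetic.RhythmParams)
    growth_noise: synthetic.GrowthNoiseParams = field(
        default_factory=synthetic.GrowthNoiseParams)
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    linking: segtrack.LinkingConfig = field(default_factory=segtrack.LinkingConfig)
    retrieval: holography.RetrievalConfig = field(
        default_factory=holography.RetrievalConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("traces-only", "full-imaging"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.cohort.n_cells < 1:
            raise ValueError("cohort must contain at least one cell")


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    seed: int
    mode: str
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, wall_time: float, **info) -> None:
        self.stages.append({"stage": name, "wall_time_s": round(wall_time, 3),
                            **info})


def _config_to_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["imaging"]["shape"] = list(d["imaging"]["shape"])
    return d


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    def build(cls, key):
        sub = doc.get(key, {}) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in sub.items() if k in names})
    imaging = build(ImagingConfig, "imaging")
    imaging.shape = tuple(imaging.shape)
    return PipelineConfig(
        mode=doc.get("mode", "traces-only"),
        seed=doc.get("seed", 0),
        outdir=doc.get("outdir", "holomass_run"),
        rhythm=build(synthetic.RhythmParams, "rhythm"),
        growth_noise=build(synthetic.GrowthNoiseParams, "growth_noise"),
        cohort=build(synthetic.CohortConfig, "cohort"),
        linking=build(segtrack.LinkingConfig, "linking"),
        retrieval=build(holography.RetrievalConfig, "retrieval"),
        spectral=build(SpectralConfig, "spectral"),
        imaging=imaging,
    )


def _hash_config(config: PipelineConfig) -> str:
    blob = json.dumps(_config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def measure_track_masses(phases: np.ndarray, tracks, phase_threshold: float,
                         pixel_pitch: float, wavelength: float,
                         apply_correction: bool = False):
    """Segment every tracked spot and integrate dry mass per frame.

    All seeds of a frame are segmented jointly so touching cells are
    watershed-split.  Returns ``(masks, mass_by_track, opd_stack)``.
    """
    opd_stack = phases * wavelength / (2.0 * np.pi)
    by_frame: dict[int, list] = {}
    for tr in tracks:
        for i, s in enumerate(tr.spots):
            by_frame.setdefault(s.frame, []).append((tr.track_id, i, s))
    masks: dict = {}
    mass_by_track = {tr.track_id: np.full(len(tr.spots), np.nan) for tr in tracks}
    for frame, items in by_frame.items():
        seeds = [s for _, _, s in items]
        seg_masks = segtrack.segment_cells(phases[frame], seeds, phase_threshold)
        opd = drymass.OPDImage(opd_stack[frame], pixel_pitch)
        for (tid, i, _), mask in zip(items, seg_masks):
            masks[(tid, frame)] = mask
            samp = drymass.ovd_to_cdm(drymass.integrate_ovd(opd, mask),
                                      apply_correction)
            mass_by_track[tid][i] = np.nan if samp.empty else samp.cdm
    return masks, mass_by_track, opd_stack


def _traces_only(config: PipelineConfig, outdir: Path, manifest: RunManifest):
    t0 = time.perf_counter()
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    traces, truth = synthetic.generate_cohort(cohort_cfg, config.rhythm,
                                              config.growth_noise)
    manifest.add_stage("simulate", time.perf_counter() - t0,
                       n_traces=len(traces))
    drymass.write_traces_csv(traces, outdir / "traces.csv")
    synthetic.write_ground_truth_json(truth, outdir / "ground_truth.json")
    return traces


def _full_imaging(config: PipelineConfig, outdir: Path, manifest: RunManifest):
    img = config.imaging
    t0 = time.perf_counter()
    truth = synthetic.generate_scene(
        n_cells=img.n_cells, n_frames=img.n_frames, shape=img.shape,
        rhythm=config.rhythm, gn=config.growth_noise,
        dt=config.cohort.sampling_interval,
        peak_opd_um=img.peak_opd_um,
        round_peak_opd_um=img.round_peak_opd_um,
        pixel_pitch=config.retrieval.pixel_pitch, seed=config.seed)
    phase_truth = synthetic.render_phase_frames(truth)
    holos = np.empty_like(phase_truth)
    for i in range(phase_truth.shape[0]):
        a0 = holography.ComplexField(np.exp(1j * phase_truth[i]),
                                     config.retrieval.pixel_pitch,
                                     config.retrieval.wavelength)
        holos[i] = np.abs(holography.propagate(a0, config.retrieval.z).values) ** 2
    holography.write_stack(outdir / "holograms.tif", holos)
    manifest.add_stage("simulate", time.perf_counter() - t0,
                       n_frames=int(holos.shape[0]), n_cells=len(truth.cells))

    t0 = time.perf_counter()
    phases = np.empty_like(holos)
    for i in range(holos.shape[0]):
        res = holography.retrieve_phase(
            holography.SensorIntensity(holos[i], config.retrieval.pixel_pitch,
                                       config.retrieval.wavelength),
            config=config.retrieval)
        phases[i] = holography.unwrap_phase(res.phase,
                                            min_depth=np.pi / 2).values
        phases[i] = drymass.subtract_background(phases[i])
    holography.write_stack(outdir / "phases.tif", phases)
    manifest.add_stage("reconstruct", time.perf_counter() - t0)

    t0 = time.perf_counter()
    det_by_frame = {}
    for i in range(phases.shape[0]):
        spots = segtrack.detect_spots(phases[i], config.linking)
        for s in spots:
            s.frame = i
        det_by_frame[i] = spots
    tracks = segtrack.link_tracks(det_by_frame, config.linking)
    segtrack.write_spots_csv(tracks, outdir / "spots_in_tracks.csv")
    manifest.add_stage("track", time.perf_counter() - t0, n_tracks=len(tracks))

    t0 = time.perf_counter()
    masks, mass_by_track, opd_stack = measure_track_masses(
        phases, tracks, img.phase_threshold, config.retrieval.pixel_pitch,
        config.retrieval.wavelength, img.apply_correction)
    divisions = segtrack.detect_divisions(tracks, mass_by_track, config.linking)
    traces = drymass.build_traces(tracks, opd_stack, masks,
                                  config.retrieval.pixel_pitch,
                                  config.cohort.sampling_interval, divisions,
                                  apply_correction=img.apply_correction,
                                  min_samples=config.linking.min_spots)
    drymass.write_traces_csv(traces, outdir / "traces.csv")
    manifest.add_stage("mass", time.perf_counter() - t0,
                       n_traces=len(traces), n_divisions=len(divisions))
    return traces


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, dict]:
    """Run the configured chain and write artifacts to ``config.outdir``.

    Returns the manifest and a results dict with the peak report, spike
    metrics, and (in traces-only mode) a deterministic summary that is
    bit-identical across reruns with the same config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__
    manifest = RunManifest(_hash_config(config), __version__, config.seed,
                           config.mode)
    save_config(config, outdir / "config.yaml")

    if config.mode == "traces-only":
        traces = _traces_only(config, outdir, manifest)
    else:
        traces = _full_imaging(config, outdir, manifest)

    t0 = time.perf_counter()
    spectra = spectral.compute_cell_spectra(traces)
    if not spectra:
        raise RuntimeError("spectrum stage: no trace was long enough")
    cohort = spectral.average_spectra(spectra, config.spectral.n_f)
    report = spectral.find_fundamental(cohort, config.spectral.band,
                                       config.spectral.threshold)
    recon = spectral.inverse_reconstruct(
        report, config.spectral.reconstruction_duration)
    spikes = spectral.measure_spikes(recon)
    manifest.add_stage("spectrum", time.perf_counter() - t0,
                       n_spectra=len(spectra))

    results = {
        "f0_per_min": report.f0,
        "period_h": (1.0 / report.f0) / 60.0 if report.f0 > 0 else None,
        "significance": report.significance,
        "detected": report.detected,
        "af_pg": report.af,
        "af_corrected_pg": report.af_corrected,
        "harmonics_pg": [float(a) for a in report.harmonics],
        "interspike_h": spikes["interspike_min"] / 60.0,
        "fwhm_min": spikes["fwhm_min"],
        "amplitude_pg": spikes["amplitude_pg"],
    }
    with open(outdir / "peak_report.json", "w") as fh:
        json.dump(results, fh, indent=2)
    spectral.plot_cohort_spectrum(cohort, report, outdir / "cohort_spectrum.png")
    spectral.plot_reconstruction(recon, outdir / "reconstruction.png")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    np.savetxt(outdir / "cohort_spectrum.csv",
               np.column_stack([cohort.frequencies, np.nan_to_num(cohort.mean),
                                np.nan_to_num(cohort.sd), cohort.count]),
               delimiter=",", header="frequency_per_min,mean_pg,sd_pg,count",
               comments="")
    return manifest, results


# ---------------------------------------------------------------------------
# condition comparison (oscillator strength)
# ---------------------------------------------------------------------------

def compare_conditions(traces_a, traces_b, n_boot: int = 200, seed: int = 0,
                       n_f: int = 1, band=spectral.DEFAULT_BAND,
                       f0: float | None = None) -> dict:
    """Oscillator-strength ratio AF_b / AF_a with a bootstrap interval.

    The AF of each cohort is the background-corrected fundamental
    amplitude; cells are resampled with replacement and the cohort
    spectra recomputed to produce a percentile confidence interval.
    When ``f0`` is given the fundamental bin is fixed, which makes the
    ratio meaningful even when condition b has no detectable peak
    (complete suppression).
    """
    spec_a = spectral.compute_cell_spectra(traces_a)
    spec_b = spectral.compute_cell_spectra(traces_b)

    cohort_a = spectral.average_spectra(spec_a, n_f)
    if f0 is None:
        f0_a = spectral.find_fundamental(cohort_a, band).f0
    else:
        f0_a = f0

    def af_of(spectra):
        cohort = spectral.average_spectra(spectra, n_f)
        return spectral.fundamental_amplitude(cohort, f0_a, band)

    af_a = af_of(spec_a)
    af_b = af_of(spec_b)
    ratio = af_b / af_a if af_a > 0 else np.inf
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        sa = [spec_a[i] for i in rng.integers(len(spec_a), size=len(spec_a))]
        sb = [spec_b[i] for i in rng.integers(len(spec_b), size=len(spec_b))]
        a = af_of(sa)
        b = af_of(sb)
        boots.append(b / a if a > 0 else np.nan)
    boots = np.asarray(boots)
    boots = boots[np.isfinite(boots)]
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots.size else (np.nan, np.nan))
    return {"af_a": af_a, "af_b": af_b, "ratio": float(ratio),
            "ci_low": float(lo), "ci_high": float(hi), "f0": f0_a}
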