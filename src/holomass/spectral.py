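"""Cohort Fourier analysis of single-cell dry-mass traces.

Each cell contributes a windowed Fourier spectrum computed over its own
interphase duration T(j): the linear growth background is removed by
least squares, the residual is apodized with a half-period sine window
(vanishing at both ends), and the discrete Fourier amplitude is
evaluated on the oversampled grid ``k / (T(j) * M)`` with M = 25.
Amplitudes are normalized by trace length so a unit-amplitude sinusoid
scores the same regardless of T(j).

The cohort spectrum bins all per-cell amplitudes on the grid defined by
the longest trace, ``df = n_f / (T_max * M)``, recording per-bin mean,
standard deviation, count, and mean squared amplitude.  Rhythm
detection fits a power-law 1/f background, scores bins by their
standardized excess, and identifies the fundamental as the first peak
supported by its harmonic comb; the waveform is rebuilt by an inverse
Fourier sum over the background-corrected harmonic amplitudes, which —
absolute amplitudes carrying no phase — yields exactly two solutions
(sign pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drymass import DryMassTrace

__all__ = [
    "OVERSAMPLING",
    "CellSpectrum",
    "CohortSpectrum",
    "PeakReport",
    "ReconstructedSignal",
    "detrend_and_window",
    "cell_ft",
    "compute_cell_spectra",
    "average_spectra",
    "find_fundamental",
    "fundamental_amplitude",
    "inverse_reconstruct",
    "plot_cohort_spectrum",
    "plot_reconstruction",
    "measure_spikes",
    "cohort_size_scan",
]

#: frequency oversampling factor M of the per-cell transforms
OVERSAMPLING = 25
#: default frequency band searched for the rhythm, min^-1
DEFAULT_BAND = (0.001, 0.02)
#: standardized-excess threshold for calling a peak significant
SIGNIFICANCE_THRESHOLD = 3.0
#: minimum number of samples for a trace to enter the analysis
MIN_SAMPLES = 16


@dataclass
class CellSpectrum:
    """Windowed Fourier amplitudes of one cell on its own grid."""

    cell_id: int
    duration: float                 # T(j), minutes
    frequencies: np.ndarray         # k * df(j), min^-1
    amplitudes: np.ndarray          # pg, length-normalized

    @property
    def df(self) -> float:
        """Grid increment df(j) = 1 / (T(j) * M)."""
        return 1.0 / (self.duration * OVERSAMPLING)


@dataclass
class CohortSpectrum:
    """Bin-averaged absolute amplitude over a cohort."""

    frequencies: np.ndarray         # bin centers, min^-1
    mean: np.ndarray                # pg
    sd: np.ndarray
    count: np.ndarray
    mean_sq: np.ndarray             # pg^2, for unbiased amplitude recovery
    t_max: float
    n_f: int
    n_cells: int

    @property
    def df(self) -> float:
        return self.n_f / (self.t_max * OVERSAMPLING)


@dataclass
class PeakReport:
    """Fundamental-peak detection summary."""

    f0: float                       # min^-1
    af: float                       # mean amplitude of the fundamental bin, pg
    af_corrected: float             # background-corrected amplitude, pg
    significance: float             # (peak - background) / SE at the peak bin
    detected: bool
    harmonics: np.ndarray           # background-corrected amplitude at m*f0
    background_coeff: float
    background_exponent: float
    band: tuple = DEFAULT_BAND
    bin_width: float = 0.0
    n_cells: int = 0
    message: str = ""


@dataclass
class ReconstructedSignal:
    """Inverse-FT waveform; the two sign solutions about the baseline."""

    times: np.ndarray               # minutes
    solution_plus: np.ndarray       # pg
    solution_minus: np.ndarray
    f0: float
    harmonic_amplitudes: np.ndarray


# ---------------------------------------------------------------------------
# per-cell transform
# ---------------------------------------------------------------------------

def detrend_and_window(trace: DryMassTrace) -> tuple[np.ndarray, np.ndarray, float]:
    """Remove the linear growth background and apodize.

    Returns ``(times, windowed_residuals, T)``.  The window is
    ``sin(pi (t - t0) / T)`` with T the last minus first sample time, so
    both endpoints are exactly zero.  Traces shorter than
    ``MIN_SAMPLES`` samples are rejected.
    """
    seg = trace.interphase_segment()
    t, m = seg.times, seg.masses
    good = np.isfinite(m)
    t, m = t[good], m[good]
    if t.size < MIN_SAMPLES:
        raise ValueError(f"trace {trace.track_id}: too short for spectral "
                         f"analysis ({t.size} < {MIN_SAMPLES} samples)")
    T = float(t[-1] - t[0])
    coef = np.polyfit(t, m, 1)
    residual = m - np.polyval(coef, t)
    window = np.sin(np.pi * (t - t[0]) / T)
    return t, residual * window, T


def cell_ft(times: np.ndarray, windowed: np.ndarray, T: float,
            M: int = OVERSAMPLING, cell_id: int = 0) -> CellSpectrum:
    """Fourier amplitudes at increments ``df = 1/(T*M)`` up to Nyquist.

    Implemented by zero-padding the windowed series to ``M * (N - 1)``
    samples, which evaluates the DFT exactly on the required grid.
    Absolute amplitudes are normalized by the window sum (a length
    normalization) so an on-grid cosine of amplitude ``a`` peaks at
    ``~a`` irrespective of trace length.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    n = windowed.size
    dt = float(times[1] - times[0])
    window = np.sin(np.pi * (times - times[0]) / T)
    wsum = window.sum()
    nfft = M * (n - 1)
    spec = np.fft.rfft(windowed, nfft)
    freqs = np.arange(spec.size) / (nfft * dt)     # = k / (T * M)
    nyquist = 1.0 / (2.0 * dt)
    keep = freqs <= nyquist
    amps = 2.0 * np.abs(spec) / wsum
    return CellSpectrum(cell_id, T, freqs[keep], amps[keep])


def compute_cell_spectra(traces: list[DryMassTrace],
                         M: int = OVERSAMPLING) -> list[CellSpectrum]:
    """Per-cell spectra for all traces long enough to analyze."""
    out = []
    for tr in traces:
        try:
            t, w, T = detrend_and_window(tr)
        except ValueError:
            continue
        out.append(cell_ft(t, w, T, M, cell_id=tr.track_id))
    return out


# ---------------------------------------------------------------------------
# cohort averaging
# ---------------------------------------------------------------------------

def average_spectra(spectra: list[CellSpectrum], n_f: int = 1) -> CohortSpectrum:
    """Accumulate per-cell amplitudes into common frequency bins.

    Bins have width ``n_f / (T_max * M)`` with T_max the longest
    duration; every per-cell frequency up to Nyquist lands in exactly
    one bin; per-bin mean, SD, count and mean square are recorded.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    t_max = max(s.duration for s in spectra)
    df_bin = n_f / (t_max * OVERSAMPLING)
    f_hi = max(s.frequencies[-1] for s in spectra)
    n_bins = int(np.floor(f_hi / df_bin)) + 1
    acc = np.zeros(n_bins)
    acc2 = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    for s in spectra:
        sel = s.frequencies > 0
        b = np.minimum((s.frequencies[sel] / df_bin).astype(int), n_bins - 1)
        a = s.amplitudes[sel]
        np.add.at(acc, b, a)
        np.add.at(acc2, b, a ** 2)
        np.add.at(cnt, b, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        mean_sq = np.where(cnt > 0, acc2 / np.maximum(cnt, 1), np.nan)
        sd = np.sqrt(np.maximum(mean_sq - mean ** 2, 0.0))
    centers = (np.arange(n_bins) + 0.5) * df_bin
    return CohortSpectrum(centers, mean, sd, cnt, mean_sq, t_max, n_f,
                          len(spectra))


# ---------------------------------------------------------------------------
# background fit and peak finding
# ---------------------------------------------------------------------------

def _fit_power_law(freqs, values, mask, n_rounds: int = 5, order: int = 1):
    """Iterative log-log polynomial fit with peak masking.

    Bins whose residual exceeds three residual-SDs are excluded and the
    fit repeated, so sharp peaks do not bias the background.  ``order``
    1 is a pure power law; order 2 allows the gentle curvature that the
    windowed 1/f noise background shows near the low-frequency end of
    the band.  Returns ``(background array, coeff, exponent)`` with the
    coeff/exponent of the best pure power law (the reported summary).
    """
    base = mask & np.isfinite(values) & (values > 0) & (freqs > 0)
    cur = base.copy()
    lx = np.log(np.where(freqs > 0, freqs, np.nan))
    coefs = None
    for _ in range(n_rounds):
        if cur.sum() < max(10, order + 2):
            cur = base
        coefs = np.polyfit(lx[cur], np.log(values[cur]), order)
        bg = np.exp(np.polyval(coefs, lx))
        resid = values - bg
        rsd = resid[cur].std()
        nxt = base & (resid < 3.0 * rsd)
        if (nxt == cur).all():
            break
        cur = nxt
    bg = np.exp(np.polyval(coefs, lx))
    slope, inter = np.polyfit(lx[cur], np.log(values[cur]), 1)
    return bg, float(np.exp(inter)), float(-slope)


def _smooth(x: np.ndarray, k: int) -> np.ndarray:
    k = max(int(k), 1)
    return np.convolve(np.nan_to_num(x), np.ones(k) / k, mode="same")


def find_fundamental(cohort: CohortSpectrum,
                     band: tuple[float, float] = DEFAULT_BAND,
                     threshold: float = SIGNIFICANCE_THRESHOLD,
                     n_harmonics: int = 6) -> PeakReport:
    """Locate the rhythm's fundamental frequency in a cohort spectrum.

    A power-law background is fitted to the mean amplitude over the
    band (iteratively masking outliers).  Bins are scored by the
    standardized excess ``z = (mean - background) / SE``; since the
    per-cell grids oversample the spectral resolution ~M-fold, ``z`` is
    averaged over M/2 adjacent bins before peak picking.  The
    fundamental is chosen by a harmonic-comb score (the z-profile
    stacked over four harmonics with 1/sqrt(m) weights, with a
    subharmonic walk-down), matching the identification of the first
    sharp peak together with its higher harmonics; ``f0`` is then
    refined by per-harmonic centroids.  Harmonic amplitudes are
    recovered unbiasedly from the mean squared amplitude,
    ``a_m = sqrt(mean_sq - background_sq)`` at the local peak near
    ``m * f0``.

    If no bin in the band exceeds the detection rule the report carries
    ``detected=False`` and the best bin's significance.
    """
    M = OVERSAMPLING
    f, mean, sd, cnt = cohort.frequencies, cohort.mean, cohort.sd, cohort.count
    n_bins_band = int((band[1] - band[0]) / cohort.df)
    if n_bins_band < 10:
        raise ValueError("fewer than 10 cohort bins in the search band")
    valid = cnt >= max(3.0, 0.2 * cohort.n_cells)
    in_band = (f >= band[0]) & (f <= band[1]) & valid
    if in_band.sum() < 10:
        raise ValueError("not enough populated bins in the search band")
    bg, coeff, expo = _fit_power_law(f, mean, in_band, order=2)
    excess = np.where(valid, mean - bg, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(valid & (cnt > 0), sd / np.sqrt(np.maximum(cnt, 1)), np.inf)
    floor = 0.02 * np.nanmedian(mean[in_band])
    se = np.maximum(np.nan_to_num(se, nan=np.inf), floor)
    z = np.where(valid, excess / se, 0.0)
    k = max(M // 2, 3)
    zs = _smooth(z, k)

    # harmonic-comb score over candidate fundamentals in the lower half-band
    w = 1.0 / np.sqrt(np.arange(1, 5))
    cand = np.where((f >= band[0]) & (f <= band[1] / 2.0) & valid)[0]
    if cand.size == 0:
        cand = np.where(in_band)[0]
    comb = np.full(f.size, -np.inf)
    for i in cand:
        idx = np.minimum(((i + 0.5) * np.arange(1, 5)).astype(int), f.size - 1)
        comb[i] = float((w * zs[idx]).sum() / w.sum())
    i0 = int(np.argmax(comb))
    # prefer an integer subharmonic when it stands on its own (the comb
    # maximum can land on the 2nd or 3rd harmonic in strong 1/f noise)
    moved = True
    while moved:
        moved = False
        for k in (2, 3):
            ih = int((i0 + 0.5) / k)
            if ih >= 1 and comb[ih] > 0.75 * comb[i0] and zs[ih] > 1.0:
                i0 = ih
                moved = True
                break

    # refine f0 by per-harmonic centroids of the smoothed excess
    es = _smooth(np.clip(excess, 0.0, None), k)
    f0 = f[i0]
    half_res = int(1.5 * M)
    for _ in range(3):
        num = den = 0.0
        for m in range(1, 5):
            c = int(m * f0 / cohort.df)
            lo, hi = max(c - half_res, 0), min(c + half_res, f.size - 1)
            wts = es[lo:hi + 1] ** 2
            tot = wts.sum()
            if tot <= 0:
                continue
            fm = float((f[lo:hi + 1] * wts).sum() / tot)
            wm = m * float(np.sqrt(wts.max()))
            num += wm * (fm / m)
            den += wm
        if den > 0:
            f0 = num / den
    ib = min(int(f0 / cohort.df), f.size - 1)
    significance = float(zs[ib])
    i2 = min(int(2 * f0 / cohort.df), f.size - 1)
    detected = bool(significance > threshold and zs[i2] > 1.0)

    # unbiased harmonic amplitudes from the mean squared amplitude; the
    # power-law fit extends above the detection band so the background
    # under the upper harmonics is interpolated, not extrapolated
    sq_band = (f >= band[0]) & (f <= min(2.5 * band[1], f[-1])) & valid
    bg_sq, _, _ = _fit_power_law(f, cohort.mean_sq, sq_band, order=2)
    es_sq = _smooth(np.clip(cohort.mean_sq - bg_sq, 0.0, None), max(M // 4, 3))
    win = M // 2
    harmonics = np.zeros(n_harmonics)
    for m in range(1, n_harmonics + 1):
        c = int(m * f0 / cohort.df)
        if c >= f.size:
            break
        lo, hi = max(c - win, 0), min(c + win, f.size - 1)
        j = lo + int(np.argmax(es_sq[lo:hi + 1]))
        if cnt[j] > 0 and np.isfinite(cohort.mean_sq[j]):
            harmonics[m - 1] = np.sqrt(max(cohort.mean_sq[j] - bg_sq[j], 0.0))
    af = float(mean[ib]) if np.isfinite(mean[ib]) else 0.0
    return PeakReport(
        f0=float(f0), af=af, af_corrected=float(harmonics[0]),
        significance=significance, detected=detected, harmonics=harmonics,
        background_coeff=coeff, background_exponent=expo, band=band,
        bin_width=cohort.df, n_cells=cohort.n_cells,
        message="" if detected else "no significant peak",
    )


def fundamental_amplitude(cohort: CohortSpectrum, f0: float,
                          band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Background-corrected amplitude (pg) at a known fundamental.

    Used for dose-response comparisons, where the rhythm frequency is
    known from the control condition and the oscillator strength is
    read at that fixed frequency even when the treated cohort shows no
    detectable peak.
    """
    f, cnt, msq = cohort.frequencies, cohort.count, cohort.mean_sq
    M = OVERSAMPLING
    c = min(int(f0 / cohort.df), f.size - 1)
    # peak power: mean squared amplitude right at the known frequency;
    # background: median over sidebands flanking the peak outside its
    # spectral resolution width (~M bins), which cancels any local
    # mismatch of a global background model
    pk_lo, pk_hi = max(c - 2, 0), min(c + 2, f.size - 1)
    pk_sel = slice(pk_lo, pk_hi + 1)
    sb_idx = np.concatenate([np.arange(max(c - 3 * M, 0), max(c - M, 0)),
                             np.arange(min(c + M, f.size - 1),
                                       min(c + 3 * M, f.size - 1))])
    ok = (cnt[sb_idx] > 0) & np.isfinite(msq[sb_idx]) & (msq[sb_idx] > 0)
    if ok.sum() < 4 or not np.isfinite(msq[pk_sel]).any():
        return 0.0
    peak = float(np.nanmean(msq[pk_sel]))
    # local power-law fit of the sidebands, evaluated at f0 (a flank
    # median would over-subtract on a convex 1/f background)
    slope, inter = np.polyfit(np.log(f[sb_idx][ok]),
                              np.log(msq[sb_idx][ok]), 1)
    bg = float(np.exp(inter) * f[c] ** slope)
    return float(np.sqrt(max(peak - bg, 0.0)))


# ---------------------------------------------------------------------------
# inverse reconstruction
# ---------------------------------------------------------------------------

def inverse_reconstruct(peak: PeakReport, duration: float = 2880.0,
                        n_harmonics: int | None = None,
                        dt: float = 1.0) -> ReconstructedSignal:
    """Rebuild the rhythm waveform from the harmonic amplitudes.

    ``signal(t) = +/- sum_m a_m cos(2 pi m f0 t)`` using the
    background-corrected amplitudes; cohort averaging retains only
    absolute amplitudes, so the harmonics are cosine-aligned at t = 0
    and the sign is unknowable — both solutions are returned.
    Harmonics beyond the report (or with zero corrected amplitude)
    contribute nothing.
    """
    if peak.f0 <= 0:
        raise ValueError("no fundamental frequency to reconstruct from")
    amps = peak.harmonics
    if n_harmonics is not None:
        if n_harmonics > amps.size:
            import warnings
            warnings.warn("n_harmonics exceeds available harmonics; truncating")
        amps = amps[:n_harmonics]
    t = np.arange(0.0, duration, dt)
    s = np.zeros_like(t)
    for m, a in enumerate(amps, start=1):
        s += a * np.cos(2.0 * np.pi * m * peak.f0 * t)
    return ReconstructedSignal(t, s, -s, peak.f0, np.asarray(amps))


def measure_spikes(signal: ReconstructedSignal) -> dict:
    """Spike metrics of the reconstructed waveform.

    Returns the mean inter-spike interval (minutes), the full width at
    half maximum of the spike nearest the record midpoint (minutes) and
    the peak-to-baseline amplitude (pg), the baseline being the
    waveform minimum between spikes.
    """
    t, s = signal.times, signal.solution_plus
    smax, smin = float(s.max()), float(s.min())
    half = 0.5 * (smax + smin)
    above = np.where(s >= half)[0]
    if above.size == 0:
        return {"interspike_min": np.nan, "fwhm_min": np.nan, "amplitude_pg": 0.0}
    groups = np.split(above, np.where(np.diff(above) > 1)[0] + 1)
    centers = np.array([t[g].mean() for g in groups])
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    if centers.size > 2:
        interspike = float(np.diff(centers).mean())
    else:
        interspike = 1.0 / signal.f0
    mid = t[t.size // 2]
    g = groups[int(np.argmin(np.abs(centers - mid)))]
    fwhm = float(t[g[-1]] - t[g[0]] + dt)
    return {"interspike_min": interspike, "fwhm_min": fwhm,
            "amplitude_pg": smax - smin}


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_cohort_spectrum(cohort: CohortSpectrum, report: PeakReport, path) -> None:
    """Cohort amplitude spectrum with the 1/f fit and the fundamental
    marked by an asterisk."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    sel = (cohort.count > 0) & (cohort.frequencies > 0)
    ax.loglog(cohort.frequencies[sel], cohort.mean[sel], lw=0.8,
              color="steelblue", label="cohort mean amplitude")
    bg = report.background_coeff * cohort.frequencies[sel] ** (-report.background_exponent)
    ax.loglog(cohort.frequencies[sel], bg, "k--", lw=1, label="1/f background")
    ax.plot([report.f0], [report.af], "r*", ms=14,
            label=f"fundamental {report.f0:.4f} min$^{{-1}}$")
    ax.set_xlabel("frequency (min$^{-1}$)")
    ax.set_ylabel("amplitude (pg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_reconstruction(signal: ReconstructedSignal, path) -> None:
    """The two inverse-FT waveform solutions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 3))
    t_h = signal.times / 60.0
    ax.plot(t_h, signal.solution_plus, lw=1, label="solution +")
    ax.plot(t_h, signal.solution_minus, lw=1, label="solution −")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("dry mass change (pg)")
    ax.set_xlim(0, min(24, t_h[-1]))
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# cohort-size emergence
# ---------------------------------------------------------------------------

def cohort_size_scan(traces: list[DryMassTrace], sizes: list[int],
                     n_rep: int = 10, seed: int = 0, n_f: int = 1,
                     band: tuple[float, float] = DEFAULT_BAND) -> list[dict]:
    """Significance of the rhythm peak versus cohort size.

    For each requested size, subsample that many traces ``n_rep`` times
    (without replacement) and report the mean and SD of the detection
    significance.  When the size equals the full cohort the subsample
    is the cohort itself.
    """
    spectra = compute_cell_spectra(traces)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > len(spectra):
            raise ValueError(f"requested size {size} exceeds cohort "
                             f"({len(spectra)})")
        sigs, dets = [], []
        reps = 1 if size == len(spectra) and n_rep == 1 else n_rep
        for _ in range(reps):
            if size == len(spectra):
                sub = spectra
            else:
                idx = rng.choice(len(spectra), size=size, replace=False)
                sub = [spectra[i] for i in idx]
            report = find_fundamental(average_spectra(sub, n_f), band)
            sigs.append(report.significance)
            dets.append(report.detected)
        rows.append({"size": size, "mean_significance": float(np.mean(sigs)),
                     "sd_significance": float(np.std(sigs)),
                     "detection_rate": float(np.mean(dets))})
    return rows
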