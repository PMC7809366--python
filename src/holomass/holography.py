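"""Fresnel propagation and TV-regularized phase retrieval for lens-free inline holography.

A lens-free microscope records only the intensity of the diffracted
field at a sensor a short distance ``Z`` behind the sample.  The sample
image is recovered by solving an inverse problem: find the sensor-plane
phase ``phi_Z`` such that the back-propagated field
``A_0 = (sqrt(I_Z) * exp(i*phi_Z)) conv h_{-Z}`` minimizes a total-variation
(TV) criterion.  By construction the solution reproduces the measured
intensity exactly; the TV prior selects, among all intensity-consistent
fields, the one with sparse spatial gradients, which suppresses the
twin-image artifact of inline holography.

The optimizer is nonlinear conjugate gradients (Hestenes-Stiefel) with a
second-order line search, stopped after a fixed number of iterations
(default 15).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
import yaml
from scipy import ndimage

__all__ = [
    "ComplexField",
    "SensorIntensity",
    "PhaseImage",
    "RetrievalConfig",
    "RetrievalResult",
    "fresnel_transfer",
    "propagate",
    "tv_criterion",
    "tv_gradient",
    "retrieve_phase",
    "unwrap_phase",
    "backpropagate_intensity",
    "load_retrieval_config",
    "save_retrieval_config",
    "read_stack",
    "write_stack",
]

#: default regularization constant of the TV criterion
DEFAULT_EPSILON = 1e-4
#: default number of NLCG iterations
DEFAULT_ITERATIONS = 15
#: default sensor pixel pitch, micrometres (typical CMOS)
DEFAULT_PIXEL_PITCH = 1.67
#: default illumination wavelength, micrometres (red LED)
DEFAULT_WAVELENGTH = 0.647


@dataclass
class ComplexField:
    """A 2-D complex optical amplitude on a regular pixel grid.

    Attributes
    ----------
    values : ndarray, complex
        Field amplitude sample per pixel.
    pixel_pitch : float
        Pixel spacing in micrometres.
    wavelength : float
        Illumination wavelength in micrometres.
    """

    values: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    wavelength: float = DEFAULT_WAVELENGTH

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("field must be 2-D")
        if self.pixel_pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pixel_pitch and wavelength must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def power(self) -> float:
        """Total optical power, sum of |A|^2 over the grid."""
        return float(np.sum(np.abs(self.values) ** 2))

    def phase(self) -> "PhaseImage":
        return PhaseImage(np.angle(self.values), self.pixel_pitch)


@dataclass
class SensorIntensity:
    """Intensity image |A_Z|^2 recorded by the sensor."""

    values: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    wavelength: float = DEFAULT_WAVELENGTH

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity must be finite")
        if np.any(self.values < 0):
            raise ValueError("intensity must be nonnegative")


@dataclass
class PhaseImage:
    """A 2-D real phase map in radians."""

    values: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class RetrievalConfig:
    """Parameters of the TV phase retrieval.

    ``epsilon`` is the small constant that smooths the TV criterion and
    prevents division by zero in its gradient; ``iterations`` is the
    fixed NLCG stopping count.
    """

    wavelength: float = DEFAULT_WAVELENGTH
    z: float = 1500.0
    iterations: int = DEFAULT_ITERATIONS
    epsilon: float = DEFAULT_EPSILON
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class RetrievalResult:
    """Output of :func:`retrieve_phase`."""

    object_field: ComplexField
    phase: PhaseImage
    sensor_phase: np.ndarray
    criterion_history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def fresnel_transfer(shape: tuple[int, int], pixel_pitch: float,
                     wavelength: float, z: float) -> np.ndarray:
    """Fresnel (paraxial) transfer function on the FFT frequency grid.

    ``H(f) = exp(-i * pi * wavelength * z * |f|^2)``; the constant piston
    ``exp(i k z)`` is omitted since only phase differences matter here.
    The kernel for ``-z`` is the complex conjugate of the kernel for
    ``+z`` and the modulus is one everywhere, so propagation is unitary.
    """
    fy = np.fft.fftfreq(shape[0], d=pixel_pitch)
    fx = np.fft.fftfreq(shape[1], d=pixel_pitch)
    fx2, fy2 = np.meshgrid(fx ** 2, fy ** 2)
    return np.exp(-1j * np.pi * wavelength * z * (fx2 + fy2))


def _propagate_values(values: np.ndarray, pixel_pitch: float,
                      wavelength: float, z: float) -> np.ndarray:
    H = fresnel_transfer(values.shape, pixel_pitch, wavelength, z)
    return np.fft.ifft2(np.fft.fft2(values) * H)


def propagate(fld: ComplexField, z: float) -> ComplexField:
    """Propagate a field over a signed distance ``z`` (micrometres).

    Positive ``z`` maps the object plane to the sensor plane; negative
    ``z`` back-propagates.  Implemented as multiplication by the Fresnel
    transfer function in Fourier space (periodic boundaries).
    """
    if z == 0:
        warnings.warn("propagate called with Z=0; returning field unchanged")
        return replace(fld, values=fld.values.copy())
    out = _propagate_values(fld.values, fld.pixel_pitch, fld.wavelength, z)
    return replace(fld, values=out)


def backpropagate_intensity(intensity: SensorIntensity, z: float) -> ComplexField:
    """Plain back-propagation of ``sqrt(I_Z)`` (zero sensor phase).

    This is the initialization of the iterative retrieval and the
    baseline it is compared against.
    """
    amp = np.sqrt(intensity.values)
    values = _propagate_values(amp.astype(complex), intensity.pixel_pitch,
                               intensity.wavelength, -z)
    return ComplexField(values, intensity.pixel_pitch, intensity.wavelength)


# ---------------------------------------------------------------------------
# TV criterion and gradient
# ---------------------------------------------------------------------------

def _forward_diffs(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # forward differences with periodic wrap, consistent with FFT periodicity
    gx = np.roll(A, -1, axis=1) - A
    gy = np.roll(A, -1, axis=0) - A
    return gx, gy


def tv_criterion(field_values: np.ndarray | ComplexField,
                 epsilon: float = DEFAULT_EPSILON) -> float:
    """Smoothed isotropic total variation of a complex field.

    ``sum over pixels of sqrt(epsilon + |dA/dx|^2 + |dA/dy|^2)`` with
    forward differences and periodic wrap.  For a constant field of N
    pixels this equals ``N * sqrt(epsilon)`` exactly.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    A = field_values.values if isinstance(field_values, ComplexField) else field_values
    gx, gy = _forward_diffs(np.asarray(A))
    return float(np.sum(np.sqrt(epsilon + np.abs(gx) ** 2 + np.abs(gy) ** 2)))


def tv_gradient(phi_z: np.ndarray, intensity: SensorIntensity, z: float,
                epsilon: float = DEFAULT_EPSILON) -> tuple[np.ndarray, float]:
    """Gradient of the TV criterion with respect to the sensor phase.

    The criterion is evaluated on the back-propagated field
    ``A_0 = P_{-z}(sqrt(I_Z) e^{i phi_Z})``.  Writing ``s = sqrt(eps +
    |gx|^2 + |gy|^2)`` per pixel, the cogradient with respect to ``A_0``
    is a discrete divergence of ``g/s``; pulling it back through the
    (unitary) propagation and the phase parametrization gives

    ``grad(phi) = Im( conj(B) * P_{+z}(V) )``,   ``B = sqrt(I) e^{i phi}``.

    Returns ``(gradient, criterion_value)``.
    """
    amp = np.sqrt(intensity.values)
    B = amp * np.exp(1j * phi_z)
    A0 = _propagate_values(B, intensity.pixel_pitch, intensity.wavelength, -z)
    gx, gy = _forward_diffs(A0)
    s = np.sqrt(epsilon + np.abs(gx) ** 2 + np.abs(gy) ** 2)
    ux = gx / s
    uy = gy / s
    V = np.roll(ux, 1, axis=1) - ux + np.roll(uy, 1, axis=0) - uy
    Vb = _propagate_values(V, intensity.pixel_pitch, intensity.wavelength, z)
    grad = np.imag(np.conj(B) * Vb)
    return grad, float(np.sum(s))


# ---------------------------------------------------------------------------
# NLCG retrieval
# ---------------------------------------------------------------------------

def retrieve_phase(intensity: SensorIntensity, z: float | None = None,
                   config: RetrievalConfig | None = None) -> RetrievalResult:
    """TV-regularized phase retrieval by nonlinear conjugate gradients.

    Parameters
    ----------
    intensity : SensorIntensity
        Recorded hologram ``I_Z``; must be finite and nonnegative.
    z : float, optional
        Object-sensor distance in micrometres (assumed known).  Taken
        from ``config`` when omitted.
    config : RetrievalConfig, optional
        Iteration count, epsilon and grid metadata; defaults reproduce
        the reference setup (15 iterations, epsilon 1e-4).

    Returns
    -------
    RetrievalResult
        Object-plane field ``A_0``, its phase image, the sensor phase
        estimate and the criterion history.  The data term is hard:
        ``|P_{+z}(A_0)|^2`` equals the measured intensity exactly for
        any sensor phase, so the criterion value is the only objective.

    Notes
    -----
    Search directions use Hestenes-Stiefel conjugation with the
    restart clamp ``beta = max(beta, 0)``; the step comes from a
    second-order (quadratic) expansion of the criterion along the
    direction, with backtracking halving as a safeguard.  The criterion
    is non-increasing across accepted iterations.
    """
    if config is None:
        config = RetrievalConfig(pixel_pitch=intensity.pixel_pitch,
                                 wavelength=intensity.wavelength)
    if z is None:
        z = config.z
    if not np.all(np.isfinite(intensity.values)):
        raise ValueError("intensity contains non-finite values")
    eps = config.epsilon
    amp = np.sqrt(intensity.values)
    pitch, lam = intensity.pixel_pitch, intensity.wavelength

    def criterion_at(phi: np.ndarray) -> float:
        A0 = _propagate_values(amp * np.exp(1j * phi), pitch, lam, -z)
        return tv_criterion(A0, eps)

    phi = np.zeros_like(amp, dtype=float)
    g_prev: np.ndarray | None = None
    D = np.zeros_like(phi)
    sigma_prev = 1.0
    history: list[float] = []

    for _ in range(config.iterations):
        g, crit = tv_gradient(phi, intensity, z, eps)
        history.append(crit)
        if g_prev is None:
            D = -g
        else:
            y = g - g_prev
            denom = float(np.sum(D * y))
            beta = float(np.sum(g * y)) / denom if abs(denom) > 1e-300 else 0.0
            beta = max(beta, 0.0)
            D = -g + beta * D
            if float(np.sum(D * g)) >= 0.0:  # lost descent: restart
                D = -g
        d0 = float(np.sum(g * D))
        if d0 == 0.0:
            break
        # second-order expansion of the criterion along D: curvature by
        # symmetric differencing at a small step (~0.05 rad max phase)
        hs = 0.05 / max(float(np.max(np.abs(D))), 1e-30)
        e_plus = criterion_at(phi + hs * D)
        e_minus = criterion_at(phi - hs * D)
        curv = (e_plus - 2.0 * crit + e_minus) / hs ** 2
        step = -d0 / curv if curv > 0 else hs
        e_step = criterion_at(phi + step * D)
        halvings = 0
        while e_step > crit and halvings < 10:
            step *= 0.5
            e_step = criterion_at(phi + step * D)
            halvings += 1
        if e_step > crit:
            step = 0.0
        phi = phi + step * D
        sigma_prev = max(step, 1e-3)
        g_prev = g

    A0 = _propagate_values(amp * np.exp(1j * phi), pitch, lam, -z)
    fld = ComplexField(A0, pitch, lam)
    return RetrievalResult(fld, fld.phase(), phi, history)


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------

def unwrap_phase(phase: PhaseImage, min_depth: float = 0.0) -> PhaseImage:
    """Heuristic unwrapping of locally wrapped cell phases.

    Cells inducing a phase shift beyond +pi wrap to negative values in
    the reconstruction.  Every 4-connected region of strictly negative
    pixels is set to +pi; nonnegative pixels are unchanged.

    With ``min_depth > 0`` only regions reaching at least that far
    below zero are promoted; shallow negative ripples of the
    reconstruction background are left untouched.  (On a noisy
    background the literal rule would promote about half the field.)
    """
    vals = phase.values.copy()
    negative = vals < 0
    labels, n = ndimage.label(negative,
                              structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if n:
        if min_depth > 0:
            mins = ndimage.minimum(vals, labels, index=np.arange(1, n + 1))
            deep = np.flatnonzero(mins <= -min_depth) + 1
            vals[np.isin(labels, deep)] = np.pi
        else:
            vals[labels > 0] = np.pi
    return PhaseImage(vals, phase.pixel_pitch)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def save_retrieval_config(config: RetrievalConfig, path) -> None:
    doc = {
        "wavelength_um": float(config.wavelength),
        "z_um": float(config.z),
        "iterations": int(config.iterations),
        "epsilon": float(config.epsilon),
        "pixel_pitch_um": float(config.pixel_pitch),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_retrieval_config(path) -> RetrievalConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RetrievalConfig(
        wavelength=doc.get("wavelength_um", DEFAULT_WAVELENGTH),
        z=doc.get("z_um", 1500.0),
        iterations=doc.get("iterations", DEFAULT_ITERATIONS),
        epsilon=doc.get("epsilon", DEFAULT_EPSILON),
        pixel_pitch=doc.get("pixel_pitch_um", DEFAULT_PIXEL_PITCH),
    )


def write_stack(path, frames: np.ndarray) -> None:
    """Write a (n_frames, ny, nx) array as a multi-page 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)
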