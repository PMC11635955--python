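"""Synthetic scenes and the incoherent capture model.

Phantoms are transmitted-flux maps: 1.0 is a blank (fully transmitting)
field and lower values mean stronger absorption, matching the
darker-is-denser convention of absorption-contrast imaging.  Four
families emulate typical test samples: etched glyph digits, periodic
micrometre-pitch fringes, random fiber textures, and a two-region scene
(a smooth tube-like area next to a textured tissue-like area).

Capture follows the incoherent-imaging model: the detector never sees
the coherent per-wavelength amplitudes, only their aggregated intensity,
so the frame is the scene convolved with the system point-spread
function, scaled by the photon budget, Poisson shot noise and Gaussian
read noise applied, then block-binned to the detector resolution:

    S = BIN( Poisson(t_cap · flux · (I ⊗ K)) + N(0, σ_read) ) clipped at 0

Convolution is FFT-accelerated with reflective boundary padding.  All
randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
from ``ExposureSettings.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .optics import PSFKernel

__all__ = [
    "SourceImage",
    "ExposureSettings",
    "CapturedImage",
    "make_fringe_phantom",
    "make_glyph_phantom",
    "make_two_region_phantom",
    "make_fiber_phantom",
    "capture",
    "long_exposure_reference",
    "convolve_reflect",
]

DEFAULT_PIXEL_PITCH_UM = 0.5


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SourceImage:
    """Ground-truth scene: relative transmitted flux in [0, 1]."""

    intensity: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    spectral_stack: np.ndarray | None = None  # optional per-λ layers

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2D")
        if np.any(self.intensity < 0) or np.any(self.intensity > 1 + 1e-12):
            raise ValueError("intensity must lie in [0, 1]")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.spectral_stack is not None:
            stack = np.asarray(self.spectral_stack, dtype=float)
            if not np.allclose(stack.sum(axis=0), self.intensity,
                               atol=1e-9):
                raise ValueError("spectral_stack layers must sum to the "
                                 "intensity image")
            self.spectral_stack = stack

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def save(self, path: str | Path, provenance: dict | None = None) -> None:
        import tifffile
        path = Path(path)
        scaled = np.clip(self.intensity, 0, 1) * 65535.0
        tifffile.imwrite(path, scaled.astype(np.uint16))
        path.with_suffix(path.suffix + ".json").write_text(json.dumps({
            "pixel_pitch_um": self.pixel_pitch_um,
            "scale": 65535.0,
            "provenance": provenance or {},
        }, indent=2))


@dataclass
class ExposureSettings:
    """Photon budget and detector model for one capture.

    ``photons_per_pixel_per_ms`` is the blank-field detected rate of the
    plain reference system; 50 photons/px/ms makes a 20 ms frame noisy
    (~1000 photons/px) and a 100 ms frame clean, the two quality regimes
    exercised throughout.  ``bin_factor`` block-sums detector pixels to
    model a resolution-limited camera.
    """

    t_cap_ms: float = 20.0
    photons_per_pixel_per_ms: float = 50.0
    read_noise_sd: float = 2.0
    bin_factor: int = 2
    seed: int = 0
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.t_cap_ms <= 0 or self.photons_per_pixel_per_ms <= 0:
            raise ValueError("exposure time and photon rate must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read noise sd must be nonnegative")
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")


@dataclass
class CapturedImage:
    """Detector frame with its exposure metadata."""

    counts: np.ndarray
    settings: ExposureSettings
    kernel_id: str = ""
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


# ---------------------------------------------------------------------------
# phantom generators
# ---------------------------------------------------------------------------

def make_fringe_phantom(size: tuple[int, int] = (256, 256),
                        pitch_um: float = 3.0, n_lines: int = 7,
                        depth: float = 0.5,
                        line_width_um: float | None = None,
                        pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
                        ) -> SourceImage:
    """Equally spaced vertical absorbing lines on a blank field.

    The default reproduces the resolution test object used throughout:
    seven lines at 3 µm pitch.  ``line_width_um`` defaults to half the
    pitch (50 % duty cycle).
    """
    if pitch_um < 2 * pixel_pitch_um:
        raise ValueError("pitch must be at least two pixels")
    if line_width_um is None:
        line_width_um = pitch_um / 2.0
    rows, cols = size
    pitch_px = pitch_um / pixel_pitch_um
    width_px = max(1.0, line_width_um / pixel_pitch_um)
    total_px = (n_lines - 1) * pitch_px + width_px
    if total_px > cols:
        raise ValueError(f"{n_lines} lines at {pitch_um} um pitch span "
                         f"{total_px:.0f} px, wider than the {cols} px image")
    img = np.ones(size, dtype=float)
    start = (cols - total_px) / 2.0
    x = np.arange(cols)
    for k in range(n_lines):
        lo = start + k * pitch_px
        mask = (x >= lo) & (x < lo + width_px)
        img[:, mask] = 1.0 - depth
    return SourceImage(img, pixel_pitch_um)


# 5x7 stroke font for glyph phantoms; enough for digits and a few letters.
_FONT_5X7 = {
    "0": ["01110", "10001", "10011", "10101", "11001", "10001", "01110"],
    "1": ["00100", "01100", "00100", "00100", "00100", "00100", "01110"],
    "2": ["01110", "10001", "00001", "00110", "01000", "10000", "11111"],
    "3": ["11110", "00001", "00001", "01110", "00001", "00001", "11110"],
    "4": ["00010", "00110", "01010", "10010", "11111", "00010", "00010"],
    "5": ["11111", "10000", "11110", "00001", "00001", "10001", "01110"],
    "6": ["01110", "10000", "10000", "11110", "10001", "10001", "01110"],
    "7": ["11111", "00001", "00010", "00100", "01000", "01000", "01000"],
    "8": ["01110", "10001", "10001", "01110", "10001", "10001", "01110"],
    "9": ["01110", "10001", "10001", "01111", "00001", "00001", "01110"],
    "X": ["10001", "10001", "01010", "00100", "01010", "10001", "10001"],
    " ": ["00000", "00000", "00000", "00000", "00000", "00000", "00000"],
}


def make_glyph_phantom(size: tuple[int, int] = (256, 256),
                       text: str = "239", depth: float = 0.5,
                       pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
                       ) -> SourceImage:
    """Rasterized glyph strokes (e.g. the etched "239" test pattern).

    The glyphs are rendered from a built-in 5×7 stroke font and scaled
    to fill roughly two thirds of the image height; strokes transmit
    ``1 − depth``.  Deterministic for identical arguments.
    """
    if not text:
        raise ValueError("text must be nonempty")
    for ch in text:
        if ch not in _FONT_5X7:
            raise ValueError(f"glyph {ch!r} is not renderable; "
                             f"available: {''.join(sorted(_FONT_5X7))}")
    rows, cols = size
    # assemble the small bitmap with 1-column gaps
    glyphs = [np.array([[int(c) for c in row] for row in _FONT_5X7[ch]])
              for ch in text]
    gap = np.zeros((7, 1), dtype=int)
    parts: list[np.ndarray] = []
    for i, g in enumerate(glyphs):
        if i:
            parts.append(gap)
        parts.append(g)
    bitmap = np.hstack(parts)
    # scale to ~2/3 of the image height (or the width, if tighter)
    scale = max(1, min(int(rows * 2 / 3 / bitmap.shape[0]),
                       int(cols * 0.9 / bitmap.shape[1])))
    big = np.kron(bitmap, np.ones((scale, scale), dtype=int))
    if big.shape[0] > rows or big.shape[1] > cols:
        raise ValueError(f"text {text!r} does not fit a {rows}x{cols} image")
    img = np.ones(size, dtype=float)
    r0 = (rows - big.shape[0]) // 2
    c0 = (cols - big.shape[1]) // 2
    img[r0:r0 + big.shape[0], c0:c0 + big.shape[1]] -= depth * big
    return SourceImage(img, pixel_pitch_um)


def make_two_region_phantom(size: tuple[int, int] = (256, 256),
                            ratio_a: float = 0.858, ratio_b: float = 0.881,
                            texture_in_b: bool = True, seed: int = 0,
                            texture_amplitude: float = 0.08,
                            pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
                            ) -> tuple[SourceImage, dict[str, np.ndarray]]:
    """Two absorbing regions on a blank field, with masks.

    Region A (left band) is smooth at transmittance ``ratio_a`` — the
    tube analog; region B (right band) has mean transmittance
    ``ratio_b`` with optional seeded fine-scale texture — the tissue/fin
    analog.  Defaults mirror the plain-system transmittance levels of a
    fin-in-Teflon-tube scene (0.858 tube, 0.881 fin).  Returns the image
    and masks ``{"a", "b", "blank"}``.
    """
    if not (0 <= ratio_a <= 1 and 0 <= ratio_b <= 1):
        raise ValueError("ratios must lie in [0, 1]")
    rows, cols = size
    img = np.ones(size, dtype=float)
    mask_a = np.zeros(size, dtype=bool)
    mask_b = np.zeros(size, dtype=bool)
    # vertical bands covering the middle, separated by blank gutters
    band_w = cols // 4
    r0, r1 = rows // 6, rows - rows // 6
    a0 = cols // 8
    b0 = cols - cols // 8 - band_w
    mask_a[r0:r1, a0:a0 + band_w] = True
    mask_b[r0:r1, b0:b0 + band_w] = True
    img[mask_a] = ratio_a
    if texture_in_b:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(size)
        fine = ndimage.gaussian_filter(noise, 1.5)
        fine = fine / (fine[mask_b].std() + 1e-30)
        tex = ratio_b + texture_amplitude * fine[mask_b]
        # re-center after clipping so the region mean hits ratio_b exactly
        for _ in range(20):
            clipped = np.clip(tex, 0.0, 1.0)
            err = clipped.mean() - ratio_b
            if abs(err) < 1e-12:
                break
            tex = tex - err
        img[mask_b] = np.clip(tex, 0.0, 1.0)
    else:
        img[mask_b] = ratio_b
    blank = ~(mask_a | mask_b)
    masks = {"a": mask_a, "b": mask_b, "blank": blank}
    return SourceImage(img, pixel_pitch_um), masks


def make_fiber_phantom(size: tuple[int, int] = (256, 256),
                       n_fibers: int = 12, width_um: float = 1.5,
                       depth: float = 0.4, seed: int = 0,
                       pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
                       ) -> SourceImage:
    """Random smooth absorbing curves emulating a fibrous sample."""
    rows, cols = size
    absorb = np.zeros(size, dtype=float)
    rng = np.random.default_rng(seed)
    width_px = max(1.0, width_um / pixel_pitch_um)
    n_steps = 4 * max(rows, cols)
    for _ in range(max(0, n_fibers)):
        r = rng.uniform(0, rows)
        c = rng.uniform(0, cols)
        ang = rng.uniform(0, 2 * math.pi)
        mask = np.zeros(size, dtype=bool)
        for _ in range(n_steps):
            ang += rng.normal(0, 0.05)
            r += math.sin(ang)
            c += math.cos(ang)
            if not (0 <= r < rows and 0 <= c < cols):
                break
            mask[int(r), int(c)] = True
        if width_px > 1:
            mask = ndimage.binary_dilation(
                mask, structure=_disk(width_px / 2.0))
        absorb[mask] = depth
    return SourceImage(np.clip(1.0 - absorb, 0.0, 1.0), pixel_pitch_um)


def _disk(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return (x * x + y * y) <= radius * radius


# ---------------------------------------------------------------------------
# capture model
# ---------------------------------------------------------------------------

def convolve_reflect(image: np.ndarray, kernel: np.ndarray,
                     center: tuple[int, int] | None = None) -> np.ndarray:
    """True 2D convolution with reflective (symmetric) boundary padding.

    FFT-accelerated; equals the direct nested-loop convolution about the
    kernel center.  The kernel center defaults to ``shape // 2``.
    """
    kr, kc = kernel.shape
    if center is None:
        center = (kr // 2, kc // 2)
    if kr > image.shape[0] or kc > image.shape[1]:
        raise ValueError("kernel is larger than the image")
    # single-pixel kernel at the center: exact scaling, no FFT roundoff
    if np.count_nonzero(kernel) == 1 and kernel[center] != 0:
        return np.clip(image * kernel[center], 0.0, None)
    # pad enough for any center position, then crop the 'same' result
    pr, pc = kr, kc
    padded = np.pad(image, ((pr, pr), (pc, pc)), mode="symmetric")
    full = fftconvolve(padded, kernel, mode="same")
    # 'same' aligns the kernel midpoint (kr//2, kc//2); shift for center
    dr = kr // 2 - center[0]
    dc = kc // 2 - center[1]
    out = full[pr + dr:pr + dr + image.shape[0],
               pc + dc:pc + dc + image.shape[1]]
    return np.clip(out, 0.0, None)


def _bin2d(a: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return a
    rows = (a.shape[0] // f) * f
    cols = (a.shape[1] // f) * f
    a = a[:rows, :cols]
    return a.reshape(rows // f, f, cols // f, f).sum(axis=(1, 3))


def capture(src: SourceImage, kernel: PSFKernel,
            exposure: ExposureSettings) -> CapturedImage:
    """Simulate one detector frame of the scene through a given kernel."""
    k = kernel.grid
    if abs(k.sum() - 1.0) > 1e-6:
        raise ValueError("kernel must be normalized to unit sum")
    blurred = convolve_reflect(src.intensity, k, kernel.center)
    rate = exposure.t_cap_ms * exposure.photons_per_pixel_per_ms * blurred
    if exposure.noiseless:
        counts = rate
    else:
        rng = np.random.default_rng(exposure.seed)
        counts = rng.poisson(rate).astype(float)
        if exposure.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, exposure.read_noise_sd,
                                         counts.shape)
        counts = np.clip(counts, 0.0, None)
    counts = _bin2d(counts, exposure.bin_factor)
    return CapturedImage(counts, exposure, kernel_id="",
                         pixel_pitch_um=src.pixel_pitch_um
                         * exposure.bin_factor)


def long_exposure_reference(src: SourceImage, kernel_none: PSFKernel,
                            exposure: ExposureSettings) -> CapturedImage:
    """Long-exposure ground-truth frame through the plain system.

    Same capture model, restricted to exposure times of at least 100 ms;
    used as the reference against which SNR curves are measured.
    """
    if exposure.t_cap_ms < 100.0:
        raise ValueError("long-exposure reference requires t_cap >= 100 ms")
    return capture(src, kernel_none, exposure)
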