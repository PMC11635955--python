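"""Diffraction-order bookkeeping and point-spread-function synthesis.

A Ce:YAG scintillator converts absorbed X-rays into isotropic visible
fluorescence.  Because the crystal's refractive index is high (n ≈ 1.82),
only rays inside the escape cone (the critical angle of total internal
reflection) leave the exit face; the rest — about 92 % of the emitted
photons — are trapped.  A periodic metasurface of period ``ξ`` etched on
the exit face diffracts trapped large-angle rays back into the system's
acceptance cone.  Summed incoherently over emission wavelength and
emission angle, the admitted rays form a convolution kernel: the optical
encoder of the fused optical–electronic autoencoder.

This module turns (index, period, spectrum, geometry) into

* a per-(θ, λ, m) table of diffraction orders with propagation and
  acceptance flags, from the scalar transmission-grating equation
  ``sin θ_out = n sin θ − m λ / ξ``, and
* a polychromatic point-spread function obtained by ray-mapping every
  admitted order to a lateral displacement ``d = L tan θ_out`` on the
  detector plane.

Per-order diffraction efficiencies are not derivable from the scalar
model; the default treats all admitted orders equally and a user table
can override that.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "OpticalSystemSpec",
    "MetasurfaceSpec",
    "EmissionSpectrum",
    "DiffractionOrder",
    "PSFKernel",
    "critical_angle",
    "escape_fraction",
    "diffraction_exit_sine",
    "order_table",
    "order_table_to_csv",
    "build_psf",
    "collection_efficiency",
    "lambertian_theta_weights",
    "kernel_preset",
    "KERNEL_PRESETS",
]

#: Handbook refractive index of cerium-doped YAG at its emission peak.
N_CE_YAG = 1.82

#: Default half-angle of the collection optics, degrees (NA ≈ 0.17 relay).
DEFAULT_ACCEPTANCE_DEG = 10.0


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@dataclass
class PSFKernel:
    """A nonnegative, unit-sum convolution kernel on a regular pixel grid.

    Parameters
    ----------
    grid
        2D nonnegative array.  ``normalize`` rescales it to sum 1.
    pixel_pitch_um
        Pixel spacing in micrometres.
    center
        (row, col) index of zero lateral displacement.
    collection_efficiency
        Fraction of the isotropically emitted fluorescence admitted by
        the system this kernel describes (before normalization).  Used
        by the scenario layer to scale photon budgets; purely metadata
        for convolution itself.
    """

    grid: np.ndarray
    pixel_pitch_um: float
    center: tuple[int, int] | None = None
    collection_efficiency: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("kernel grid must be 2D")
        if np.any(self.grid < 0):
            raise ValueError("kernel grid must be nonnegative")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.center is None:
            self.center = (self.grid.shape[0] // 2, self.grid.shape[1] // 2)
        r, c = self.center
        if not (0 <= r < self.grid.shape[0] and 0 <= c < self.grid.shape[1]):
            raise ValueError("kernel center lies outside the grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def normalize(self) -> "PSFKernel":
        """Return a copy rescaled to unit sum."""
        s = float(self.grid.sum())
        if s <= 0:
            raise ValueError("cannot normalize an all-zero kernel")
        return PSFKernel(self.grid / s, self.pixel_pitch_um, self.center,
                         self.collection_efficiency)

    @staticmethod
    def delta(shape: tuple[int, int] = (1, 1), pixel_pitch_um: float = 1.0,
              collection_efficiency: float | None = None) -> "PSFKernel":
        """Single-pixel identity kernel."""
        g = np.zeros(shape)
        g[shape[0] // 2, shape[1] // 2] = 1.0
        return PSFKernel(g, pixel_pitch_um,
                         collection_efficiency=collection_efficiency)

    # -- persistence: float32 TIFF + JSON sidecar ---------------------------

    def save(self, path: str | Path, provenance: dict | None = None) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.grid.astype(np.float32))
        sidecar = {
            "pixel_pitch_um": self.pixel_pitch_um,
            "center": list(self.center),
            "collection_efficiency": self.collection_efficiency,
            "provenance": provenance or {},
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path: str | Path) -> "PSFKernel":
        path = Path(path)
        grid = tifffile.imread(path).astype(float)
        meta_path = path.with_suffix(path.suffix + ".json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            return PSFKernel(grid, meta["pixel_pitch_um"],
                             tuple(meta["center"]),
                             meta.get("collection_efficiency"))
        return PSFKernel(grid, 1.0)


# ---------------------------------------------------------------------------
# system specifications
# ---------------------------------------------------------------------------

@dataclass
class OpticalSystemSpec:
    """Scintillator + collection-optics parameters.

    ``system_kernel`` describes every optical element other than the
    metasurface (lens blur, scintillator thickness, …); the default is a
    single-pixel delta, i.e. an ideal relay.
    """

    n_scint: float = N_CE_YAG
    acceptance_half_angle_deg: float = DEFAULT_ACCEPTANCE_DEG
    propagation_distance_um: float = 5.0
    system_kernel: PSFKernel | None = None

    def __post_init__(self) -> None:
        if self.n_scint < 1:
            raise ValueError("refractive index must be >= 1")
        if not (0 < self.acceptance_half_angle_deg <= 90):
            raise ValueError("acceptance half-angle must lie in (0, 90] deg")
        if self.propagation_distance_um <= 0:
            raise ValueError("propagation distance must be positive")
        if self.system_kernel is not None:
            g = self.system_kernel.grid
            if np.any(g < 0) or not math.isclose(float(g.sum()), 1.0,
                                                 rel_tol=1e-9):
                raise ValueError("system_kernel must be nonnegative and "
                                 "sum to 1")


@dataclass
class MetasurfaceSpec:
    """Periodic structure on the scintillator exit face.

    geometry
        ``grating_1d`` — line grating, orders displace along one axis;
        ``isotropic_2d`` — concentric/isotropic structure, orders spread
        over annuli; ``none`` — bare interface (plain system).
    efficiency_model
        ``uniform_orders`` gives every admitted order equal weight;
        ``user_table`` reads per-order weights from ``efficiency_table``
        keyed by the signed order m (fallback |m|).
    """

    period_nm: float = 300.0
    geometry: str = "grating_1d"
    efficiency_model: str = "uniform_orders"
    order_range: int = 3
    efficiency_table: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.geometry not in ("grating_1d", "isotropic_2d", "none"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry != "none" and self.period_nm <= 0:
            raise ValueError("period_nm must be positive")
        if self.order_range < 0:
            raise ValueError("order_range must be >= 0")
        if self.efficiency_model not in ("uniform_orders", "user_table"):
            raise ValueError(
                f"unknown efficiency model {self.efficiency_model!r}")
        if self.efficiency_model == "user_table" and not self.efficiency_table:
            raise ValueError("user_table efficiency model needs a table")

    def efficiency(self, m: int) -> float:
        if self.efficiency_model == "uniform_orders":
            return 1.0
        table = self.efficiency_table
        if m in table:
            return float(table[m])
        return float(table.get(abs(m), 0.0))


@dataclass
class EmissionSpectrum:
    """Discrete fluorescence spectrum: (wavelength_nm, weight) samples."""

    samples: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise ValueError("spectrum must contain at least one sample")
        lam = np.array([s[0] for s in self.samples], dtype=float)
        w = np.array([s[1] for s in self.samples], dtype=float)
        if np.any(lam <= 0):
            raise ValueError("wavelengths must be positive")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()
        self.samples = list(zip(lam.tolist(), w.tolist()))

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples])

    @property
    def weights(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples])

    @staticmethod
    def uniform_visible(step_nm: float = 10.0) -> "EmissionSpectrum":
        """Uniform weight over the 400–700 nm fluorescence band."""
        lam = np.arange(400.0, 700.0 + 0.5 * step_nm, step_nm)
        return EmissionSpectrum([(l, 1.0) for l in lam])


@dataclass(frozen=True)
class DiffractionOrder:
    """One (incidence angle, wavelength, order) record of the grating."""

    m: int
    incidence_deg: float
    wavelength_nm: float
    exit_sine: float
    propagating: bool
    in_acceptance: bool

    @property
    def exit_angle_deg(self) -> float:
        if not self.propagating:
            return math.nan
        return math.degrees(math.asin(self.exit_sine))


# ---------------------------------------------------------------------------
# escape-cone photometry
# ---------------------------------------------------------------------------

def critical_angle(n_scint: float) -> float:
    """Critical angle of total internal reflection, in degrees.

    ``arcsin(1/n)``: 90° for n=1 (no index contrast), ≈33.3° for Ce:YAG.
    """
    if n_scint < 1:
        raise ValueError("refractive index must be >= 1")
    return math.degrees(math.asin(1.0 / n_scint))


def escape_fraction(n_scint: float) -> float:
    """Solid-angle fraction of isotropic emission that exits one face.

    For an emitter inside a medium of index n, only rays within the
    escape cone (half-angle ``arcsin(1/n)``) leave through a planar
    face; the fraction of the full sphere is ``(1 − cos θ_c)/2``.  The
    complement ``1 − escape_fraction`` is the trapped ("lost") photon
    fraction — about 92 % for Ce:YAG.
    """
    theta_c = math.radians(critical_angle(n_scint))
    return (1.0 - math.cos(theta_c)) / 2.0


# ---------------------------------------------------------------------------
# grating equation
# ---------------------------------------------------------------------------

def diffraction_exit_sine(incidence_deg: float, wavelength_nm: float,
                          period_nm: float, m: int,
                          n_scint: float = N_CE_YAG) -> float:
    """Exit-angle sine of order m of a transmission grating into air.

    ``s = n sin θ − m λ / ξ``.  The order propagates iff ``|s| < 1``;
    for m=0 this is Snell refraction, with total internal reflection
    beyond the critical angle.
    """
    if period_nm <= 0:
        raise ValueError("period_nm must be positive")
    if wavelength_nm <= 0:
        raise ValueError("wavelength_nm must be positive")
    return (n_scint * math.sin(math.radians(incidence_deg))
            - m * wavelength_nm / period_nm)


def _orders(meta: MetasurfaceSpec) -> list[int]:
    if meta.geometry == "none":
        return [0]
    return list(range(-meta.order_range, meta.order_range + 1))


def order_table(meta: MetasurfaceSpec, sys: OpticalSystemSpec,
                spectrum: EmissionSpectrum,
                theta_grid: Sequence[float]) -> list[DiffractionOrder]:
    """Enumerate diffraction orders over an incidence-angle grid.

    One record per (θ, λ, m) with |m| ≤ ``order_range``.  A record is
    ``propagating`` when its exit sine lies strictly inside (−1, 1) and
    ``in_acceptance`` when, in addition, the exit angle magnitude does
    not exceed the system's acceptance half-angle.
    """
    theta_grid = list(theta_grid)
    if len(theta_grid) == 0:
        raise ValueError("theta_grid must be nonempty")
    sin_eps = math.sin(math.radians(sys.acceptance_half_angle_deg))
    records: list[DiffractionOrder] = []
    for theta in theta_grid:
        for lam in spectrum.wavelengths_nm:
            for m in _orders(meta):
                if meta.geometry == "none":
                    s = (sys.n_scint
                         * math.sin(math.radians(theta)))
                else:
                    s = diffraction_exit_sine(theta, lam, meta.period_nm, m,
                                              sys.n_scint)
                prop = abs(s) < 1.0
                acc = prop and abs(s) <= sin_eps
                records.append(DiffractionOrder(m, float(theta), float(lam),
                                                float(s), prop, acc))
    return records


def order_table_to_csv(records: Iterable[DiffractionOrder],
                       path: str | Path) -> None:
    """Write an order table as CSV."""
    lines = ["theta_deg,wavelength_nm,order,exit_sine,propagating,"
             "in_acceptance"]
    for r in records:
        lines.append(f"{r.incidence_deg},{r.wavelength_nm},{r.m},"
                     f"{r.exit_sine:.10g},{r.propagating},{r.in_acceptance}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# angular emission weighting
# ---------------------------------------------------------------------------

def lambertian_theta_weights(step_deg: float = 1.0,
                             max_deg: float = 89.0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic volume emission binned by polar angle inside the medium.

    The solid-angle element gives weight ∝ sin θ and projection onto the
    exit face gives cos θ, hence weight ∝ cos θ · sin θ on a regular
    grid — the in-medium Lambertian profile.
    """
    theta = np.arange(0.0, max_deg + 0.5 * step_deg, step_deg)
    w = np.cos(np.radians(theta)) * np.sin(np.radians(theta))
    if w.sum() > 0:
        w = w / w.sum()
    else:  # degenerate single-angle grid at 0°
        w = np.ones_like(theta) / len(theta)
    return theta, w


def _resolve_theta_weighting(theta_weighting) -> tuple[np.ndarray, np.ndarray]:
    if theta_weighting in (None, "lambertian"):
        return lambertian_theta_weights()
    if theta_weighting == "normal_incidence":
        return np.array([0.0]), np.array([1.0])
    thetas, weights = theta_weighting
    thetas = np.asarray(thetas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if thetas.shape != weights.shape or thetas.size == 0:
        raise ValueError("theta weighting must be matching nonempty arrays")
    return thetas, weights / weights.sum()


# ---------------------------------------------------------------------------
# PSF synthesis
# ---------------------------------------------------------------------------

def _bilinear_splat(grid: np.ndarray, row: float, col: float,
                    weight: float) -> None:
    r0, c0 = int(math.floor(row)), int(math.floor(col))
    fr, fc = row - r0, col - c0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < grid.shape[0] and 0 <= cc < grid.shape[1]:
                grid[rr, cc] += weight * wr * wc


def _admitted_displacements(meta: MetasurfaceSpec, sys: OpticalSystemSpec,
                            spectrum: EmissionSpectrum,
                            thetas: np.ndarray, theta_w: np.ndarray
                            ) -> list[tuple[float, float]]:
    """(displacement_um, weight) for every admitted (θ, λ, m) ray."""
    sin_eps = math.sin(math.radians(sys.acceptance_half_angle_deg))
    out: list[tuple[float, float]] = []
    lam_arr = spectrum.wavelengths_nm
    lam_w = spectrum.weights
    for theta, wt in zip(thetas, theta_w):
        for lam, wl in zip(lam_arr, lam_w):
            for m in _orders(meta):
                if meta.geometry == "none":
                    s = sys.n_scint * math.sin(math.radians(theta))
                else:
                    s = diffraction_exit_sine(theta, lam, meta.period_nm, m,
                                              sys.n_scint)
                if abs(s) >= 1.0 or abs(s) > sin_eps:
                    continue
                d = sys.propagation_distance_um * math.tan(math.asin(s))
                out.append((d, wt * wl * meta.efficiency(m)))
    return out


def build_psf(meta: MetasurfaceSpec, sys: OpticalSystemSpec,
              spectrum: EmissionSpectrum,
              theta_weighting="lambertian",
              grid_shape: tuple[int, int] = (41, 41),
              pixel_pitch_um: float = 0.5) -> PSFKernel:
    """Synthesize the optical convolution kernel by incoherent ray mapping.

    Every admitted (θ, λ, m) ray deposits its emission weight at lateral
    displacement ``d = L tan(arcsin s)`` from the kernel center, with
    sub-pixel bilinear splatting.  For ``grating_1d`` the deposit is
    mirrored to ±d along the column axis (the grating diffracts both ray
    tilts symmetrically); for ``isotropic_2d`` and ``none`` the weight
    is spread uniformly over the annulus of radius |d|.  The result is
    convolved with the system kernel and normalized to unit sum.

    Raises
    ------
    ValueError
        If the maximum admitted displacement falls outside the grid; the
        message names the required grid size.
    """
    thetas, theta_w = _resolve_theta_weighting(theta_weighting)
    rays = _admitted_displacements(meta, sys, spectrum, thetas, theta_w)

    rows, cols = grid_shape
    grid = np.zeros((rows, cols), dtype=float)
    cr, cc = rows // 2, cols // 2

    if rays:
        max_d = max(abs(d) for d, _ in rays)
        max_px = max_d / pixel_pitch_um
        half = min(cr, cc, rows - 1 - cr, cols - 1 - cc)
        if max_px > half:
            need = 2 * int(math.ceil(max_px)) + 1
            raise ValueError(
                f"admitted displacement {max_d:.2f} um ({max_px:.1f} px) "
                f"exceeds the kernel grid; need at least {need}x{need} "
                f"at pitch {pixel_pitch_um} um")

    for d, w in rays:
        r_px = d / pixel_pitch_um
        if meta.geometry == "grating_1d":
            _bilinear_splat(grid, cr, cc + r_px, 0.5 * w)
            _bilinear_splat(grid, cr, cc - r_px, 0.5 * w)
        else:  # isotropic_2d and the bare interface: annular average
            radius = abs(r_px)
            n_pts = max(8, int(math.ceil(2.0 * math.pi * radius)))
            if radius < 0.5:
                _bilinear_splat(grid, cr, cc, w)
                continue
            for k in range(n_pts):
                phi = 2.0 * math.pi * k / n_pts
                _bilinear_splat(grid, cr + radius * math.sin(phi),
                                cc + radius * math.cos(phi), w / n_pts)

    if grid.sum() == 0:
        # nothing admitted: the kernel degenerates to the system kernel
        grid[cr, cc] = 1.0

    if sys.system_kernel is not None:
        from scipy.signal import fftconvolve
        grid = fftconvolve(grid, sys.system_kernel.grid, mode="same")
        grid = np.clip(grid, 0.0, None)

    total_weight = sum(w for _, w in rays)
    kern = PSFKernel(grid, pixel_pitch_um, (cr, cc),
                     collection_efficiency=0.5 * total_weight)
    return kern.normalize()


def collection_efficiency(meta: MetasurfaceSpec, sys: OpticalSystemSpec,
                          spectrum: EmissionSpectrum) -> float:
    """Fraction of isotropic emission admitted into the acceptance cone.

    Lambertian in-medium angular weighting over 0–89°; the leading 0.5
    accounts for the half of the emission sphere headed toward the exit
    face.  Drives the photon-budget scaling between the plain and the
    metasurface-equipped systems.
    """
    thetas, theta_w = lambertian_theta_weights()
    rays = _admitted_displacements(meta, sys, spectrum, thetas, theta_w)
    return 0.5 * sum(w for _, w in rays)


# ---------------------------------------------------------------------------
# named presets
# ---------------------------------------------------------------------------

#: Metasurface presets: period in nm and geometry, keyed by the system
#: names used throughout — plain system and the ξ = 200/300/400/500 nm
#: structures (texture-enhancing K_ξ3 is the 1D grating at 300 nm,
#: region-enhancing K_ξ5 the isotropic structure at 500 nm).
KERNEL_PRESETS: dict[str, MetasurfaceSpec] = {
    "nsys": MetasurfaceSpec(period_nm=1.0, geometry="none"),
    "k_xi2": MetasurfaceSpec(period_nm=200.0, geometry="grating_1d"),
    "k_xi3": MetasurfaceSpec(period_nm=300.0, geometry="grating_1d"),
    "k_xi4": MetasurfaceSpec(period_nm=400.0, geometry="grating_1d"),
    "k_xi5": MetasurfaceSpec(period_nm=500.0, geometry="isotropic_2d"),
}


def kernel_preset(name: str, sys: OpticalSystemSpec | None = None,
                  spectrum: EmissionSpectrum | None = None,
                  grid_shape: tuple[int, int] = (21, 21),
                  pixel_pitch_um: float = 0.5) -> PSFKernel:
    """Build one of the named system kernels.

    The plain system ("nsys") stands for the focused conventional relay:
    its PSF is the system kernel itself (normal-incidence weighting),
    while its collection efficiency is the escape-cone fraction actually
    admitted by the aperture under Lambertian emission.
    """
    if name not in KERNEL_PRESETS:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(KERNEL_PRESETS)}")
    meta = KERNEL_PRESETS[name]
    sys = sys or OpticalSystemSpec()
    spectrum = spectrum or EmissionSpectrum.uniform_visible()
    weighting = "normal_incidence" if meta.geometry == "none" else "lambertian"
    kern = build_psf(meta, sys, spectrum, weighting, grid_shape,
                     pixel_pitch_um)
    kern.collection_efficiency = collection_efficiency(meta, sys, spectrum)
    return kern
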