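"""Single-exposure calibration of the electronic decoder.

The decoder must learn the optical encoder — the effective convolution
kernel of metasurface plus relay — before it can invert it.  Because the
encoder is a fixed physical convolution, one exposure of a *known*
calibration sample suffices: find the nonnegative, unit-sum kernel K
that minimizes the least-squares inference target

    Ω = argmin_K || S_obs − g · (I_known ⊗ K) ||²_F

where g is a free photometric gain (budget × exposure time) refit in
closed form every epoch.  Three recurrent solvers are provided:

* ``cg`` (default) — conjugate gradients on the normal equations of the
  least-squares target; for a k×k kernel the iterates reach the exact
  minimizer within k² epochs, and nonnegativity plus unit sum are
  imposed on the reported kernel each epoch.  Chosen as default because
  calibration scenes are DC-dominated, which makes first-order schemes
  crawl;
* ``multiplicative`` — the Richardson–Lucy-mirrored update
  ``K ← K ⊙ corr(I, S/(I ⊗ K)) / corr(I, 1)``, a one-cell recurrent
  scheme that preserves nonnegativity by construction, handles the
  large dynamic range between the DC and texture content of natural
  calibration scenes, and reads the kernel off in a single epoch when
  the calibration scene is a point source;
* ``pgd`` — projected gradient descent with backtracking line search,
  nonnegativity clipping and renormalization each epoch; guarantees a
  non-increasing loss trace.

All three record the per-epoch Frobenius loss and a stability trace,
``1 − ||K_e − K_{e−1}||_F / ||K_{e−1}||_F``, whose approach to 1 signals
convergence of the kernel iterates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .optics import PSFKernel
from .phantoms import CapturedImage, SourceImage

__all__ = [
    "CalibrationPair",
    "TrainingTrace",
    "EstimatedKernel",
    "loss",
    "estimate_kernel",
    "stability",
]


@dataclass
class CalibrationPair:
    """Known calibration scene together with its captured frame."""

    known_scene: SourceImage
    observed: CapturedImage

    def __post_init__(self) -> None:
        f = self.observed.settings.bin_factor
        sr, sc = self.known_scene.shape
        orr, oc = self.observed.shape
        if (orr * f != sr and orr != sr) or (oc * f != sc and oc != sc):
            raise ValueError("observed shape is inconsistent with the scene "
                             f"({self.observed.shape} vs {self.known_scene.shape} "
                             f"at bin factor {f})")


@dataclass
class TrainingTrace:
    """Per-epoch Frobenius loss and kernel-stability values."""

    loss: list[float]
    stability: list[float]

    def __post_init__(self) -> None:
        if len(self.loss) != len(self.stability):
            raise ValueError("loss and stability traces must have equal "
                             "length")
        if any(l < 0 for l in self.loss):
            raise ValueError("loss values must be nonnegative")

    @property
    def epochs(self) -> int:
        return len(self.loss)

    def to_csv(self, path: str | Path) -> None:
        lines = ["epoch,loss,stability"]
        for e, (l, s) in enumerate(zip(self.loss, self.stability), start=1):
            lines.append(f"{e},{l:.10g},{s:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EstimatedKernel:
    """Result of decoder calibration."""

    kernel: PSFKernel
    trace: TrainingTrace
    final_loss: float
    gain: float = 1.0
    warnings: list[str] = field(default_factory=list)


def loss(observed: np.ndarray | CapturedImage,
         predicted: np.ndarray) -> float:
    """Frobenius (Euclidean) norm of the error matrix observed − predicted."""
    obs = observed.counts if isinstance(observed, CapturedImage) else observed
    obs = np.asarray(obs, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if obs.shape != predicted.shape:
        raise ValueError(f"shape mismatch: {obs.shape} vs {predicted.shape}")
    return float(np.linalg.norm(obs - predicted))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _upsample_observed(calib: CalibrationPair) -> np.ndarray:
    """Bilinearly upsample the binned frame back to scene resolution."""
    obs = calib.observed.counts
    sr, sc = calib.known_scene.shape
    if obs.shape == (sr, sc):
        return obs.astype(float)
    zr, zc = sr / obs.shape[0], sc / obs.shape[1]
    up = ndimage.zoom(obs, (zr, zc), order=1, grid_mode=True,
                      mode="nearest")
    return up[:sr, :sc].astype(float)


def _conv_linear(image_padded: np.ndarray, k: np.ndarray,
                 out_shape: tuple[int, int],
                 pad: tuple[int, int]) -> np.ndarray:
    """Linear (unclipped) reflect-padded convolution, kernel may be signed."""
    full = fftconvolve(image_padded, k, mode="same")
    pr, pc = pad
    return full[pr:pr + out_shape[0], pc:pc + out_shape[1]]


class _SceneOperator:
    """FFT-cached forward/adjoint convolution by a fixed scene.

    ``conv`` maps a (kr, kc) kernel to the reflect-padded convolution
    of the scene, cropped to the scene frame; ``adj`` is its exact
    adjoint, mapping a scene-shaped residual to the kernel window.
    The scene transform is computed once, which matters because every
    training epoch needs one forward and one adjoint application.
    """

    def __init__(self, scene: np.ndarray, kshape: tuple[int, int]) -> None:
        from scipy.fft import next_fast_len, irfft2, rfft2
        self._rfft2, self._irfft2 = rfft2, irfft2
        kr, kc = kshape
        self.kshape = kshape
        self.out_shape = scene.shape
        self.pad = (kr, kc)
        sp = np.pad(scene, ((kr, kr), (kc, kc)), mode="symmetric")
        self.sp_shape = sp.shape
        # separate transform sizes: the forward convolves the padded
        # scene with a small kernel, the adjoint with a full residual
        self._convshape = (next_fast_len(sp.shape[0] + kr - 1),
                           next_fast_len(sp.shape[1] + kc - 1))
        self._fullshape = (next_fast_len(sp.shape[0] + scene.shape[0] - 1),
                           next_fast_len(sp.shape[1] + scene.shape[1] - 1))
        self._fs_conv = rfft2(sp, s=self._convshape)
        self._fs_full = rfft2(sp, s=self._fullshape)

    def conv(self, k: np.ndarray) -> np.ndarray:
        kr, kc = self.kshape
        full = self._irfft2(
            self._fs_conv * self._rfft2(k, s=self._convshape),
            s=self._convshape)
        r0, c0 = kr // 2, kc // 2
        pr, pc = self.pad
        orr, oc = self.out_shape
        return full[pr + r0:pr + r0 + orr, pc + c0:pc + c0 + oc]

    def adj(self, resid: np.ndarray) -> np.ndarray:
        kr, kc = self.kshape
        rr, rc = resid.shape
        fullc = self._irfft2(
            self._fs_full * self._rfft2(resid[::-1, ::-1],
                                        s=self._fullshape),
            s=self._fullshape)
        pr, pc = self.pad
        r0, c0 = kr // 2, kc // 2
        block = fullc[pr + r0 - kr + 1 + rr - 1:pr + r0 + rr,
                      pc + c0 - kc + 1 + rc - 1:pc + c0 + rc]
        return block[::-1, ::-1].copy()


def _kernel_gradient_window(image_padded: np.ndarray, resid: np.ndarray,
                            kshape: tuple[int, int],
                            pad: tuple[int, int]) -> np.ndarray:
    """corr(I, resid) restricted to the kernel support.

    Exact adjoint of the padded-FFT forward convolution used throughout.
    """
    kr, kc = kshape
    pr, pc = pad
    r0, c0 = kr // 2, kc // 2
    cv = fftconvolve(image_padded, resid[::-1, ::-1], mode="valid")
    grad = np.empty(kshape)
    for u in range(kr):
        for v in range(kc):
            grad[u, v] = cv[pr + r0 - u, pc + c0 - v]
    return grad


def _fit_gain(pred: np.ndarray, obs: np.ndarray) -> float:
    denom = float(np.vdot(pred, pred))
    if denom <= 0:
        return 1.0
    return float(np.vdot(pred, obs)) / denom


def _project_report(k_free: np.ndarray) -> np.ndarray:
    k_rep = np.clip(k_free, 0.0, None)
    s = k_rep.sum()
    return k_rep / s if s > 0 else np.full_like(k_free, 1.0 / k_free.size)


def _cg_on_support(k0, b, conv, adj, support, iters=40, tol=1e-18):
    """CG for the normal equations restricted to a support mask."""
    k = np.where(support, k0, 0.0)
    r = np.where(support, b - adj(conv(k)), 0.0)
    d = r.copy()
    rs = float(np.vdot(r, r))
    rs0 = max(rs, 1e-300)
    for _ in range(iters):
        if rs <= tol * rs0:
            break
        nd = np.where(support, adj(conv(d)), 0.0)
        denom = float(np.vdot(d, nd))
        if denom <= 0:
            break
        alpha = rs / denom
        k = k + alpha * d
        r = r - alpha * nd
        rs_new = float(np.vdot(r, r))
        d = r + (rs_new / rs) * d
        rs = rs_new
    return k


def _active_set_polish(k_free, b, conv, adj, max_outer=6):
    """Active-set refinement toward the nonnegative LS kernel.

    Starting from the unconstrained CG iterate's positive support,
    re-solves the restricted least squares and drops variables that the
    fit pushes negative, until the support is self-consistent.  This
    shrink-only variant keeps the cost bounded; it removes the spread
    of photon noise onto spurious kernel pixels without the full
    Lawson–Hanson re-entry sweep.
    """
    scale = float(np.abs(k_free).max()) or 1.0
    support = k_free > 1e-12 * scale
    if not support.any():
        return k_free
    k = k_free
    for _ in range(max_outer):
        k = _cg_on_support(k, b, conv, adj, support)
        neg = support & (k < 0)
        if not neg.any():
            break
        support = support & ~neg
        k = np.where(support, k, 0.0)
    return np.where(support, np.clip(k, 0.0, None), 0.0)


def stability(trace: TrainingTrace) -> list[float]:
    """Per-epoch kernel-stability values recorded during training."""
    if trace.epochs < 2:
        raise ValueError("stability needs at least two epochs")
    return list(trace.stability)


def _stability_value(k_new: np.ndarray, k_old: np.ndarray) -> float:
    denom = np.linalg.norm(np.abs(k_old))
    if denom == 0:
        return 1.0
    return 1.0 - float(np.linalg.norm(np.abs(k_new) - np.abs(k_old)) / denom)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def estimate_kernel(calib: CalibrationPair,
                    kernel_shape: tuple[int, int] = (33, 33),
                    epochs: int = 60,
                    step: float | None = None,
                    seed: int = 0,
                    optimizer: str = "cg",
                    patience: int = 10) -> EstimatedKernel:
    """Estimate the effective system kernel from one calibration exposure.

    Parameters
    ----------
    calib
        Known scene and its captured frame; a binned frame is bilinearly
        upsampled to scene resolution first.
    kernel_shape
        Odd support of the kernel estimate, in scene pixels.
    epochs
        Number of recurrent updates (default 60).
    step
        Initial gradient step for the ``pgd`` optimizer; default
        ``1 / max|FFT(I)|²``.  Ignored by ``multiplicative``.
    seed
        Retained for interface symmetry; both solvers are deterministic
        from a fixed initial kernel, so the seed only tags provenance.
    optimizer
        ``cg`` (default), ``multiplicative`` or ``pgd``.

    Returns an :class:`EstimatedKernel` whose ``warnings`` list flags a
    loss that failed to decrease over a full patience window.
    """
    kr, kc = kernel_shape
    if kr % 2 == 0 or kc % 2 == 0:
        raise ValueError("kernel_shape must be odd in both dimensions")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if optimizer not in ("cg", "multiplicative", "pgd"):
        raise ValueError("optimizer must be 'cg', 'multiplicative' or "
                         "'pgd'")

    scene = calib.known_scene.intensity.astype(float)
    obs = _upsample_observed(calib)
    pitch = calib.known_scene.pixel_pitch_um
    pad = (kr, kc)
    scene_padded = np.pad(scene, ((kr, kr), (kc, kc)), mode="symmetric")
    op = _SceneOperator(scene, (kr, kc))

    def forward(k: np.ndarray) -> np.ndarray:
        return np.clip(op.conv(k), 0.0, None)

    # flat nonnegative start
    k = np.full((kr, kc), 1.0 / (kr * kc))
    pred = forward(k)
    g = _fit_gain(pred, obs)
    cur_loss = float(np.linalg.norm(obs - g * pred))

    losses: list[float] = []
    stabilities: list[float] = []
    warnings: list[str] = []

    if optimizer == "cg":
        # conjugate gradients on the normal equations A^T A k = A^T obs,
        # A being the linear reflect-padded convolution by the scene;
        # the reported per-epoch kernel is the iterate clipped to >= 0
        # and renormalized.  After the last epoch an active-set polish
        # (Lawson–Hanson outer loop with CG inner solves) lands on the
        # nonnegative least-squares kernel, which keeps photon noise
        # from spreading off the true kernel support.
        conv, adj = op.conv, op.adj
        k_free = k.copy()
        b = adj(obs)
        r = b - adj(conv(k_free))
        d = r.copy()
        rs = float(np.vdot(r, r))
        k_rep_prev = k
        for _ in range(epochs):
            if rs > 1e-40:
                nd = adj(conv(d))
                denom = float(np.vdot(d, nd))
                if denom > 0:
                    alpha = rs / denom
                    k_free = k_free + alpha * d
                    r = r - alpha * nd
                    rs_new = float(np.vdot(r, r))
                    d = r + (rs_new / rs) * d
                    rs = rs_new
            k_rep = _project_report(k_free)
            pred = forward(k_rep)
            g = _fit_gain(pred, obs)
            cur_loss = float(np.linalg.norm(obs - g * pred))
            stabilities.append(_stability_value(k_rep, k_rep_prev))
            k_rep_prev = k_rep
            losses.append(cur_loss)
        k_free = _active_set_polish(k_free, b, conv, adj)
        k = _project_report(k_free)
        pred = forward(k)
        g = _fit_gain(pred, obs)
        cur_loss = float(np.linalg.norm(obs - g * pred))
        losses[-1] = cur_loss
        stabilities[-1] = _stability_value(k, k_rep_prev)
    elif optimizer == "pgd":
        if step is None:
            fpow = np.abs(np.fft.fft2(scene_padded)) ** 2
            step = 1.0 / float(fpow.max())
        cur_step = step
        for _ in range(epochs):
            resid = g * pred - obs
            grad = 2.0 * g * op.adj(resid)
            accepted = False
            for _ in range(40):
                k_try = np.clip(k - cur_step * grad, 0.0, None)
                s = k_try.sum()
                if s <= 0:
                    cur_step *= 0.5
                    continue
                k_try = k_try / s
                pred_try = forward(k_try)
                g_try = _fit_gain(pred_try, obs)
                loss_try = float(np.linalg.norm(obs - g_try * pred_try))
                if loss_try <= cur_loss:
                    accepted = True
                    break
                cur_step *= 0.5
            if accepted:
                stabilities.append(_stability_value(k_try, k))
                k, pred, g, cur_loss = k_try, pred_try, g_try, loss_try
                cur_step *= 1.2
            else:
                stabilities.append(1.0)
            losses.append(cur_loss)
    else:  # multiplicative
        eps = 1e-12
        ones = np.ones_like(obs)
        denom_win = np.clip(op.adj(ones), eps, None)
        for _ in range(epochs):
            ratio = obs / np.clip(g * pred, eps, None)
            num_win = op.adj(ratio)
            k_new = k * np.clip(num_win, 0.0, None) / denom_win
            s = k_new.sum()
            if s <= 0:
                warnings.append("kernel collapsed to zero; stopping early")
                stabilities.append(1.0)
                losses.append(cur_loss)
                break
            k_new = k_new / s
            stabilities.append(_stability_value(k_new, k))
            k = k_new
            pred = forward(k)
            g = _fit_gain(pred, obs)
            cur_loss = float(np.linalg.norm(obs - g * pred))
            losses.append(cur_loss)

    # pad traces if a solver stopped early
    while len(losses) < epochs:
        losses.append(losses[-1] if losses else cur_loss)
        stabilities.append(1.0)

    if len(losses) > patience:
        window = losses[-patience - 1:]
        if min(window[1:]) >= window[0]:
            warnings.append(
                f"loss did not decrease over the last {patience} epochs")

    kern = PSFKernel(k, pitch)
    trace = TrainingTrace(losses, stabilities)
    return EstimatedKernel(kern.normalize(), trace, losses[-1], gain=g,
                           warnings=warnings)
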