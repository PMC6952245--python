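"""Global motion stabilization by affine registration to a reference frame.

Camera or scene motion of more than a fraction of a pixel swamps the
colour pulsation signal, so every frame is registered to a reference frame
(by default the frame the segmentation was drawn on) with a 6-parameter
affine model estimated by coarse-to-fine differential (gradient-based,
Gauss-Newton) optimisation.  A second, optional stage removes slow
residual whole-frame drift -- e.g. breathing-induced translation well
below the pulse band -- by low-pass filtering the estimated translation
trajectory and warping it out, leaving in-band colour oscillations
untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import rescale

from .video_io import VideoClip

#: parameter vector layout: source_row = (1+p0)*r + p1*c + p4,
#: source_col = p2*r + (1+p3)*c + p5  (identity = all zeros)
N_PARAMS = 6
#: transforms displacing no pixel by more than this are snapped to the
#: identity, so a motion-free clip is passed through without resampling.
_IDENTITY_SNAP_PX = 0.02


@dataclass
class StabilizationReport:
    """Per-frame affine parameters and registration residuals."""

    params: np.ndarray  # (T, 6)
    residual_before: np.ndarray  # (T,)
    residual_after: np.ndarray  # (T,)
    reference_index: int
    warnings: list = field(default_factory=list)


def params_to_matrix(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return the (2x2 linear part, 2-vector offset) of a parameter vector."""
    p = np.asarray(p, dtype=float)
    A = np.array([[1.0 + p[0], p[1]], [p[2], 1.0 + p[3]]])
    t = np.array([p[4], p[5]])
    return A, t


def warp_affine(img: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Warp a 2-D image: output(x) = img(A x + t), bilinear, edge-replicated."""
    A, t = params_to_matrix(p)
    return ndi.affine_transform(img, A, offset=t, order=1, mode="nearest")


def _max_displacement(p: np.ndarray, shape: tuple[int, int]) -> float:
    """Largest pixel displacement the transform induces anywhere in frame."""
    A, t = params_to_matrix(p)
    H, W = shape
    corners = np.array([[0, 0], [0, W - 1], [H - 1, 0], [H - 1, W - 1]], float)
    moved = corners @ (A - np.eye(2)).T + t
    return float(np.max(np.hypot(moved[:, 0], moved[:, 1])))


def _interior(img: np.ndarray, margin_frac: float = 0.05) -> np.ndarray:
    mr = max(2, int(round(img.shape[0] * margin_frac)))
    mc = max(2, int(round(img.shape[1] * margin_frac)))
    return img[mr:-mr, mc:-mc]


def _residual(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.abs(_interior(a) - _interior(b))))


def _huber_weights(e: np.ndarray) -> np.ndarray:
    """Robust IRLS weights: pixels whose residual exceeds a scaled-MAD
    threshold are downweighted, so *local photometric* change (the pulse
    itself brightening or darkening the vessel) is treated as an outlier
    and does not get absorbed into spurious motion estimates."""
    med = np.median(e)
    sigma = max(1.4826 * np.median(np.abs(e - med)), 1e-3)
    c = 1.345 * sigma
    ae = np.abs(e)
    with np.errstate(divide="ignore"):
        return np.minimum(1.0, c / np.maximum(ae, 1e-12))


def estimate_affine(
    ref: np.ndarray,
    mov: np.ndarray,
    levels: int = 3,
    max_iters: int = 50,
    tol: float = 1e-4,
) -> np.ndarray:
    """Estimate p such that mov(A x + t) approximates ref.

    Coarse-to-fine Gauss-Newton on a Huber-robustified sum of squared
    intensity differences; translation parameters are doubled when
    moving to a finer pyramid level.
    """
    pyr_ref, pyr_mov = [np.asarray(ref, float)], [np.asarray(mov, float)]
    for _ in range(levels - 1):
        if min(pyr_ref[-1].shape) < 16:
            break
        pyr_ref.append(rescale(pyr_ref[-1], 0.5, anti_aliasing=True))
        pyr_mov.append(rescale(pyr_mov[-1], 0.5, anti_aliasing=True))

    p = np.zeros(N_PARAMS)
    for level in range(len(pyr_ref) - 1, -1, -1):
        r, m = pyr_ref[level], pyr_mov[level]
        rows, cols = np.mgrid[0 : r.shape[0], 0 : r.shape[1]]
        rr, cc = rows.ravel().astype(float), cols.ravel().astype(float)
        for _ in range(max_iters):
            w = warp_affine(m, p)
            gy, gx = np.gradient(w)
            e = (w - r).ravel()
            gy, gx = gy.ravel(), gx.ravel()
            J = np.column_stack((gy * rr, gy * cc, gx * rr, gx * cc, gy, gx))
            wt = _huber_weights(e)
            Jw = J * wt[:, None]
            H = Jw.T @ J
            g = Jw.T @ e
            try:
                dp = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                break
            p = p + dp
            if np.max(np.abs(dp)) < tol:
                break
        if level > 0:  # carry to the next (finer) level
            p[4:] *= 2.0
    return p


def _suppress_pulse_band(gray: np.ndarray, fps: float,
                         band: tuple[float, float]) -> np.ndarray:
    """Remove the in-band temporal component from the estimation stack.

    The plethysmographic pulse is a photometric change, not motion; left
    in, it biases the registrar (it darkens one image region rhythmically,
    which a least-squares fit partially explains as warping).  Since its
    band is known, it is subtracted from the frames used for *estimation*
    only -- the warps are applied to the original frames.
    """
    from .enhance import temporal_bandpass

    T = gray.shape[0]
    freqs = np.fft.rfftfreq(T, d=1.0 / fps)
    if not np.any((freqs >= band[0]) & (freqs <= band[1])):
        return gray  # clip too short to resolve the band
    return gray - temporal_bandpass(gray, fps, band, axis=0)


def stabilize_affine(
    clip: VideoClip,
    reference_index: int = 0,
    levels: int = 3,
    max_iters: int = 50,
    tol: float = 1e-4,
    pulse_band: tuple[float, float] | None = (0.8, 3.0),
) -> tuple[VideoClip, StabilizationReport]:
    """Register every frame of ``clip`` to ``clip.frames[reference_index]``.

    Estimation runs on a pulse-band-suppressed grey stack (see
    :func:`_suppress_pulse_band`); residuals are reported on that same
    stack, since the pulse residual is not something motion can remove.
    Frames whose registration residual would grow are passed through
    unwarped (with a warning recorded), so per-frame residual never
    increases.  Near-identity estimates are snapped to the identity to
    avoid needless resampling blur.
    """
    if not 0 <= reference_index < clip.n_frames:
        raise ValueError("reference_index out of range")
    T = clip.n_frames
    gray = clip.frames.mean(axis=-1)
    if pulse_band is not None and T >= 4 and pulse_band[1] < clip.fps / 2:
        gray = _suppress_pulse_band(gray, clip.fps, pulse_band)
    ref = gray[reference_index]

    params = np.zeros((T, N_PARAMS))
    res_before = np.zeros(T)
    res_after = np.zeros(T)
    out = clip.frames.copy()
    notes: list[str] = []

    for t in range(T):
        res_before[t] = _residual(gray[t], ref)
        if t == reference_index:
            res_after[t] = res_before[t]
            continue
        p = estimate_affine(ref, gray[t], levels=levels, max_iters=max_iters, tol=tol)
        if _max_displacement(p, gray[t].shape) < _IDENTITY_SNAP_PX:
            p = np.zeros(N_PARAMS)
        if np.all(p == 0):
            res_after[t] = res_before[t]
            params[t] = p
            continue
        warped_gray = warp_affine(gray[t], p)
        r_after = _residual(warped_gray, ref)
        if r_after > res_before[t]:
            msg = f"frame {t}: stabilization diverged, passing through unwarped"
            warnings.warn(msg)
            notes.append(msg)
            res_after[t] = res_before[t]
            continue
        params[t] = p
        res_after[t] = r_after
        for c in range(3):
            out[t, :, :, c] = warp_affine(clip.frames[t, :, :, c], p)

    out = np.clip(out, 0.0, 1.0)
    report = StabilizationReport(
        params=params,
        residual_before=res_before,
        residual_after=res_after,
        reference_index=reference_index,
        warnings=notes,
    )
    return VideoClip(out, clip.fps), report


def estimate_translation(
    ref: np.ndarray,
    mov: np.ndarray,
    levels: int = 3,
    max_iters: int = 50,
    tol: float = 1e-4,
) -> np.ndarray:
    """Translation-only variant of :func:`estimate_affine` (2 parameters)."""
    pyr_ref, pyr_mov = [np.asarray(ref, float)], [np.asarray(mov, float)]
    for _ in range(levels - 1):
        if min(pyr_ref[-1].shape) < 16:
            break
        pyr_ref.append(rescale(pyr_ref[-1], 0.5, anti_aliasing=True))
        pyr_mov.append(rescale(pyr_mov[-1], 0.5, anti_aliasing=True))
    t = np.zeros(2)
    for level in range(len(pyr_ref) - 1, -1, -1):
        r, m = pyr_ref[level], pyr_mov[level]
        for _ in range(max_iters):
            # w(x) = m(x + t): same coordinate convention as warp_affine
            w = ndi.shift(m, -t, order=1, mode="nearest")
            gy, gx = np.gradient(w)
            e = (w - r).ravel()
            J = np.column_stack((gy.ravel(), gx.ravel()))
            wt = _huber_weights(e)
            Jw = J * wt[:, None]
            try:
                dt = np.linalg.solve(Jw.T @ J, -(Jw.T @ e))
            except np.linalg.LinAlgError:
                break
            t = t + dt
            if np.max(np.abs(dt)) < tol:
                break
        if level > 0:
            t *= 2.0
    return t


def attenuate_residual_motion(clip: VideoClip, cutoff: float) -> VideoClip:
    """Suppress slow (< ``cutoff`` Hz) whole-frame translational drift.

    The per-frame translation relative to frame 0 is estimated with the
    gradient-based registrar, low-pass filtered at ``cutoff`` to isolate
    the slow drift component, and warped out.  Colour oscillations in
    the analysis band are untouched: no motion estimate means no
    resampling (sub-0.05 px trajectories are treated as zero).  This is
    a simple temporal residual-motion suppressor, not a phase-based
    motion attenuation pipeline.
    """
    if cutoff >= clip.fps / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    T = clip.n_frames
    gray = clip.frames.mean(axis=-1)
    traj = np.zeros((T, 2))
    for t in range(1, T):
        # displacement of frame t's content relative to frame 0
        traj[t] = estimate_translation(gray[0], gray[t])

    # keep only the slow part of the trajectory (drift), DC included
    spec = np.fft.rfft(traj, axis=0)
    freqs = np.fft.rfftfreq(T, d=1.0 / clip.fps)
    spec[freqs > cutoff] = 0.0
    slow = np.fft.irfft(spec, n=T, axis=0)

    if np.max(np.abs(slow)) < 0.05:
        return VideoClip(clip.frames.copy(), clip.fps)

    out = np.empty_like(clip.frames)
    for t in range(T):
        if np.max(np.abs(slow[t])) < 1e-3:
            out[t] = clip.frames[t]
            continue
        for c in range(3):
            out[t, :, :, c] = ndi.shift(
                clip.frames[t, :, :, c], -slow[t], order=1, mode="nearest"
            )
    return VideoClip(np.clip(out, 0.0, 1.0), clip.fps)
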