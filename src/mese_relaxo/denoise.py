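"""Non-local-means denoising of multi-echo magnitude stacks.

Two variants are provided:

* ``nlmeans2d`` — classical per-layer NL-means: each voxel is replaced by a
  weighted average of the voxels in its spatial search window, the weights
  decaying with the Gaussian-weighted squared distance between the spatial
  patches around the two voxels.
* ``nlmeans3d`` — the echo-aware extension: patches extend along the echo
  axis (where voxel series are strongly correlated through their common
  exponential decay), the patch kernel is a separable Gaussian with
  standard deviation ``a1`` on the echo axis and ``a2`` spatially, and the
  smoothing bandwidth ``h(te)`` is a per-echo schedule that grows with the
  per-layer noise power — late echoes, where the signal has decayed and the
  relative noise is worst, are smoothed harder.

Patch distances are kernel-normalised mean squared differences; at image
borders the kernel is clipped and renormalised.  The self-weight of each
voxel is set to the maximum weight found in its search window (standard
NL-means practice; a raw exp(0) = 1 self-weight would dominate the average
and suppress denoising).  All weights are positive and, after
normalisation, sum to one per voxel and echo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d
from skimage.metrics import peak_signal_noise_ratio, structural_similarity
from skimage.restoration import estimate_sigma

from .acquisition import MultiEchoStack

__all__ = [
    "NLMeansConfig",
    "patch_distance",
    "weight_field",
    "nlmeans2d",
    "nlmeans2d_stack",
    "nlmeans3d",
    "h_schedule_from_noise",
    "evaluate_denoising",
]

_H_FLOOR = 1e-8


@dataclass(frozen=True)
class NLMeansConfig:
    """Patch/search geometry, kernel widths and bandwidth schedule.

    ``a1`` is the Gaussian standard deviation weighting echo-axis offsets
    inside a patch, ``a2`` the one weighting spatial offsets.
    ``h_schedule`` holds one bandwidth per echo (positive, non-decreasing);
    if None it is derived from per-layer noise estimates at run time.
    """

    patch_radius_space: int = 2
    patch_radius_echo: int = 1
    search_radius_space: int = 5
    a1: float = 1.0
    a2: float = 2.0
    h_schedule: np.ndarray | None = None
    h_scale: float = 1.0  # multiplier linking sigma-hat to h when auto-deriving
    noise_compensation: bool = True  # subtract the expected 2 sigma^2 distance offset
    sigma2_schedule: np.ndarray | None = None  # per-echo noise power for compensation

    def __post_init__(self) -> None:
        if self.patch_radius_space < 0 or self.patch_radius_echo < 0 or self.search_radius_space < 0:
            raise ValueError("radii must be nonnegative")
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("kernel standard deviations must be positive")
        if self.h_schedule is not None:
            h = np.asarray(self.h_schedule, dtype=float)
            if np.any(h <= 0):
                raise ValueError("h_schedule must be positive")
            if np.any(np.diff(h) < 0):
                raise ValueError("h_schedule must be non-decreasing across echoes")
            object.__setattr__(self, "h_schedule", h)
        if self.sigma2_schedule is not None:
            s2 = np.asarray(self.sigma2_schedule, dtype=float)
            if np.any(s2 < 0):
                raise ValueError("sigma2_schedule must be nonnegative")
            object.__setattr__(self, "sigma2_schedule", s2)


def _gauss_kernel(radius: int, std: float) -> np.ndarray:
    off = np.arange(-radius, radius + 1, dtype=float)
    return np.exp(-(off**2) / (2.0 * std**2))


def h_schedule_from_noise(
    layer_noise_powers: np.ndarray, scale: float = 1.0, floor: float = _H_FLOOR
) -> np.ndarray:
    """Bandwidth per echo: h(te) = scale * sigma_hat(te), made non-decreasing.

    ``layer_noise_powers`` are per-echo noise power (variance) estimates;
    the running maximum enforces the layer-by-layer growth that matches the
    decreasing SNR of later echoes. Zero noise maps to a small positive
    floor so weights stay defined.
    """
    p = np.asarray(layer_noise_powers, dtype=float)
    if np.any(p < 0):
        raise ValueError("noise powers must be nonnegative")
    h = scale * np.sqrt(p)
    h = np.maximum.accumulate(h)
    return np.maximum(h, floor)


def _resolve_h(stack_data: np.ndarray, config: NLMeansConfig) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-echo bandwidth and (optionally) noise power for compensation."""
    n_echo = stack_data.shape[2]
    sig2: np.ndarray | None = None
    if config.sigma2_schedule is not None:
        if config.sigma2_schedule.size != n_echo:
            raise ValueError("sigma2_schedule length must match the number of echoes")
        sig2 = config.sigma2_schedule
    if config.h_schedule is not None:
        if config.h_schedule.size != n_echo:
            raise ValueError("h_schedule length must match the number of echoes")
        h = config.h_schedule
    else:
        if sig2 is None:
            sig2 = np.array(
                [estimate_sigma(stack_data[:, :, k]) for k in range(n_echo)]
            ) ** 2
        h = h_schedule_from_noise(sig2, scale=config.h_scale)
    if config.noise_compensation and sig2 is None:
        sig2 = np.array(
            [estimate_sigma(stack_data[:, :, k]) for k in range(n_echo)]
        ) ** 2
    if not config.noise_compensation:
        sig2 = None
    return h, sig2


# ---------------------------------------------------------------------------
# Patch distance (reference implementation; the fast path reproduces it)


def patch_distance(
    stack: MultiEchoStack | np.ndarray,
    i: tuple[int, int],
    j: tuple[int, int],
    te: int,
    config: NLMeansConfig,
) -> float:
    """Kernel-weighted mean squared difference of the 3D patches at i and j.

    Offsets are kept only where both patches stay inside the image (border
    clipping is symmetric) and within the echo range; the separable
    Gaussian kernel (std ``a1`` along echoes, ``a2`` spatially) is
    renormalised over the retained offsets.
    """
    data = stack.data if isinstance(stack, MultiEchoStack) else np.asarray(stack, dtype=float)
    rows, cols, n_echo = data.shape
    (iy, ix), (jy, jx) = i, j
    if not (0 <= iy < rows and 0 <= ix < cols and 0 <= jy < rows and 0 <= jx < cols):
        raise IndexError("patch centres out of range")
    if not 0 <= te < n_echo:
        raise IndexError("echo index out of range")
    ps, pe = config.patch_radius_space, config.patch_radius_echo
    num = 0.0
    norm = 0.0
    for dy in range(-ps, ps + 1):
        for dx in range(-ps, ps + 1):
            for dt in range(-pe, pe + 1):
                ay, ax, at = iy + dy, ix + dx, te + dt
                by, bx, bt = jy + dy, jx + dx, te + dt
                if not (0 <= ay < rows and 0 <= ax < cols and 0 <= at < n_echo):
                    continue
                if not (0 <= by < rows and 0 <= bx < cols):
                    continue
                k = math.exp(-(dy * dy + dx * dx) / (2.0 * config.a2**2)) * math.exp(
                    -(dt * dt) / (2.0 * config.a1**2)
                )
                diff = data[ay, ax, at] - data[by, bx, bt]
                num += k * diff * diff
                norm += k
    if norm == 0:
        return 0.0
    return num / norm


def weight_field(
    stack: MultiEchoStack | np.ndarray,
    i: tuple[int, int],
    te: int,
    config: NLMeansConfig,
    h: float | None = None,
) -> dict[tuple[int, int], float]:
    """Normalised NL-means weights over the search window of voxel ``i``.

    Reference (loop) implementation used for introspection and testing;
    returns ``{(row, col): weight}`` with weights summing to one, the
    self-weight set to the maximum off-centre weight before normalisation.
    """
    data = stack.data if isinstance(stack, MultiEchoStack) else np.asarray(stack, dtype=float)
    rows, cols, _ = data.shape
    h_all, sig2_all = _resolve_h(data, config)
    if h is None:
        h = float(h_all[te])
    offset = 2.0 * float(sig2_all[te]) if sig2_all is not None else 0.0
    iy, ix = i
    ws = config.search_radius_space
    raw: dict[tuple[int, int], float] = {}
    for dy in range(-ws, ws + 1):
        for dx in range(-ws, ws + 1):
            jy, jx = iy + dy, ix + dx
            if not (0 <= jy < rows and 0 <= jx < cols) or (dy == 0 and dx == 0):
                continue
            d = patch_distance(data, (iy, ix), (jy, jx), te, config)
            raw[(jy, jx)] = math.exp(-max(d - offset, 0.0) / (h * h))
    self_w = max(raw.values()) if raw else 1.0
    raw[(iy, ix)] = self_w
    z = sum(raw.values())
    return {k: v / z for k, v in raw.items()}


# ---------------------------------------------------------------------------
# Fast vectorised core


def _nlmeans_core(
    data: np.ndarray,
    config: NLMeansConfig,
    h: np.ndarray,
    sig2: np.ndarray | None = None,
) -> np.ndarray:
    """Offset-vectorised NL-means over a rows x cols x n_echo array.

    For every spatial shift in the search window the squared-difference
    field is convolved with the (border-renormalised) separable patch
    kernel, giving the patch distance of every voxel to its shifted
    neighbour in one pass.  With ``sig2`` given, the expected pure-noise
    distance 2 sigma^2 is subtracted (floored at zero) before the
    exponential, so equally noisy but structurally identical patches get
    full weight.
    """
    rows, cols, n_echo = data.shape
    ps, pe = config.patch_radius_space, config.patch_radius_echo
    ws = config.search_radius_space
    ky = _gauss_kernel(ps, config.a2)
    ke = _gauss_kernel(pe, config.a1)
    h2 = (h * h)[None, None, :]
    offset = None if sig2 is None else (2.0 * sig2)[None, None, :]

    def smooth(field: np.ndarray) -> np.ndarray:
        out = convolve1d(field, ky, axis=0, mode="constant", cval=0.0)
        out = convolve1d(out, ky, axis=1, mode="constant", cval=0.0)
        if pe > 0:
            out = convolve1d(out, ke, axis=2, mode="constant", cval=0.0)
        return out

    norm_cache: dict[tuple[int, ...], np.ndarray] = {}

    def kernel_avg(field: np.ndarray) -> np.ndarray:
        # Border-renormalised separable kernel average.
        norm = norm_cache.get(field.shape)
        if norm is None:
            norm = smooth(np.ones_like(field))
            norm_cache[field.shape] = norm
        return smooth(field) / norm

    num = np.zeros_like(data)
    den = np.zeros((rows, cols, n_echo))
    wmax = np.zeros((rows, cols, n_echo))

    for dy in range(-ws, ws + 1):
        for dx in range(-ws, ws + 1):
            if dy == 0 and dx == 0:
                continue
            # Overlap region: positions p with both p and p+shift in-image.
            ty0, ty1 = max(0, -dy), min(rows, rows - dy)
            tx0, tx1 = max(0, -dx), min(cols, cols - dx)
            if ty0 >= ty1 or tx0 >= tx1:
                continue
            dst = (slice(ty0, ty1), slice(tx0, tx1))
            src = (slice(ty0 + dy, ty1 + dy), slice(tx0 + dx, tx1 + dx))
            diff = data[dst] - data[src]
            dist = kernel_avg(diff * diff)
            if offset is not None:
                dist = np.maximum(dist - offset, 0.0)
            w = np.exp(-dist / h2)
            num[dst] += w * data[src]
            den[dst] += w
            np.maximum(wmax[dst], w, out=wmax[dst])

    wmax[wmax == 0] = 1.0  # isolated voxels (search radius 0 handled upstream)
    num += wmax * data
    den += wmax
    return num / den


def nlmeans3d(stack: MultiEchoStack, config: NLMeansConfig | None = None) -> MultiEchoStack:
    """Echo-aware 3D NL-means with a per-echo bandwidth schedule."""
    config = config if config is not None else NLMeansConfig()
    data = stack.data
    if stack.n_echo < 2 * config.patch_radius_echo + 1:
        raise ValueError("stack needs at least 2*patch_radius_echo + 1 echoes")
    if config.search_radius_space == 0:
        return replace(stack, data=data.copy())
    h, sig2 = _resolve_h(data, config)
    out = _nlmeans_core(data, config, h, sig2)
    return MultiEchoStack(data=np.maximum(out, 0.0), te_grid=stack.te_grid, sigma=stack.sigma)


def nlmeans2d(
    layer: np.ndarray,
    config: NLMeansConfig | None = None,
    h: float = 1.0,
    sigma2: float | None = None,
) -> np.ndarray:
    """Classical per-layer NL-means on a single echo image."""
    config = config if config is not None else NLMeansConfig()
    layer = np.asarray(layer, dtype=float)
    if layer.ndim != 2:
        raise ValueError("nlmeans2d expects a single 2-D echo layer")
    if config.search_radius_space == 0:
        return layer.copy()
    flat_cfg = replace(config, patch_radius_echo=0, h_schedule=None, sigma2_schedule=None)
    sig2 = None if sigma2 is None else np.array([float(sigma2)])
    out = _nlmeans_core(layer[:, :, None], flat_cfg, np.array([float(h)]), sig2)
    return out[:, :, 0]


def nlmeans2d_stack(stack: MultiEchoStack, config: NLMeansConfig | None = None) -> MultiEchoStack:
    """Layer-by-layer NL-means over a whole stack (the baseline method)."""
    config = config if config is not None else NLMeansConfig()
    h, sig2 = _resolve_h(stack.data, config)
    out = np.stack(
        [
            nlmeans2d(
                stack.data[:, :, k],
                config,
                h=float(h[k]),
                sigma2=None if sig2 is None else float(sig2[k]),
            )
            for k in range(stack.n_echo)
        ],
        axis=2,
    )
    return MultiEchoStack(data=np.maximum(out, 0.0), te_grid=stack.te_grid, sigma=stack.sigma)


# ---------------------------------------------------------------------------
# Quality metrics


def evaluate_denoising(
    noisy: MultiEchoStack | np.ndarray,
    denoised: MultiEchoStack | np.ndarray,
    truth: MultiEchoStack | np.ndarray,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-echo and aggregate PSNR / RMSE / SSIM of a denoising result.

    PSNR and SSIM use the ground-truth dynamic range; a perfect
    reconstruction reports RMSE 0 and PSNR +inf.
    """
    arrs = []
    for obj in (noisy, denoised, truth):
        a = obj.data if isinstance(obj, MultiEchoStack) else np.asarray(obj, dtype=float)
        arrs.append(a)
    noisy_a, den_a, truth_a = arrs
    if not (noisy_a.shape == den_a.shape == truth_a.shape):
        raise ValueError("stack shapes must match")
    rng_ = float(truth_a.max() - truth_a.min()) or 1.0

    def metrics(est: np.ndarray, ref: np.ndarray) -> tuple[float, float, float]:
        mse = float(np.mean((est - ref) ** 2))
        rmse = math.sqrt(mse)
        psnr = math.inf if mse == 0 else peak_signal_noise_ratio(ref, est, data_range=rng_)
        win = min(7, min(ref.shape))
        if win % 2 == 0:
            win -= 1
        ssim = (
            structural_similarity(ref, est, data_range=rng_, win_size=win)
            if win >= 3
            else math.nan
        )
        return psnr, rmse, ssim

    rows = []
    for k in range(truth_a.shape[2]):
        p, r, s = metrics(den_a[:, :, k], truth_a[:, :, k])
        pn, rn, sn = metrics(noisy_a[:, :, k], truth_a[:, :, k])
        rows.append(
            {"echo": k, "psnr": p, "rmse": r, "ssim": s,
             "psnr_noisy": pn, "rmse_noisy": rn, "ssim_noisy": sn}
        )
    per_echo = pd.DataFrame(rows)
    p_all, r_all, s_all = metrics(den_a, truth_a)
    pn_all, rn_all, sn_all = metrics(noisy_a, truth_a)
    aggregate = {
        "psnr": p_all, "rmse": r_all, "ssim": s_all,
        "psnr_noisy": pn_all, "rmse_noisy": rn_all, "ssim_noisy": sn_all,
    }
    return per_echo, aggregate
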