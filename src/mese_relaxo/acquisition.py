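"""Forward simulation of multi-echo spin-echo (MESE) acquisitions.

This module is the synthetic-data generator standing in for the scanner.
It produces multi-echo magnitude stacks from a geometric phantom whose
regions decay multi-exponentially,

    S(t) = sum_e A_e * exp(-t / T2_e),

sampled on a uniform echo-time grid, and corrupts them with the noise a
magnitude-reconstructed MRI image actually carries: independent zero-mean
Gaussian noise on the real and imaginary channels, turned Rician by the
modulus operation.  The long repetition time of the emulated protocol
(TR = 4000 ms >> T1) makes the signal proportional to proton density times
the T2 decay, which is what justifies fitting the pure-decay model above.

The default three-ring phantom (A = 250 everywhere, T2 = 80/200/600 ms from
inner to outer ring) mimics bound, semi-bound and free water pools of fruit
tissue at amplitudes typical of low-field fruit imaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionParams",
    "Annulus",
    "Region",
    "PhantomSpec",
    "MultiEchoStack",
    "LabelMap",
    "tomato_protocol",
    "phantom_protocol",
    "fig_phantom_spec",
    "three_ring_phantom_spec",
    "simulate_decay",
    "generate_phantom",
    "add_rician_noise",
    "estimate_layer_snr",
]

#: Echo spacing of the emulated MESE protocol, ms.
ECHO_SPACING_MS = 30.0


def _validate_te_grid(te_grid: np.ndarray) -> np.ndarray:
    te = np.asarray(te_grid, dtype=float)
    if te.ndim != 1 or te.size == 0:
        raise ValueError("te_grid must be a non-empty 1-D sequence")
    if np.any(te <= 0):
        raise ValueError("all echo times must be positive")
    if np.any(np.diff(te) <= 0):
        raise ValueError("te_grid must be strictly increasing")
    return te


@dataclass(frozen=True)
class AcquisitionParams:
    """MESE sequence parameters.

    Parameters
    ----------
    tr : repetition time, ms. Must exceed the last echo time.
    te_grid : strictly increasing echo times, ms.
    t1 : optional longitudinal relaxation time, ms; only used to verify
        the long-TR approximation via :meth:`long_tr_factor`.
    """

    tr: float
    te_grid: np.ndarray
    t1: float | None = None

    def __post_init__(self) -> None:
        te = _validate_te_grid(self.te_grid)
        object.__setattr__(self, "te_grid", te)
        if self.tr <= te[-1]:
            raise ValueError("tr must exceed the largest echo time")
        if self.t1 is not None and self.t1 <= 0:
            raise ValueError("t1 must be positive")

    @property
    def etl(self) -> int:
        """Echo-train length (number of echoes)."""
        return int(self.te_grid.size)

    def long_tr_factor(self, t1: float | None = None) -> float:
        """Saturation factor 1 - exp(-TR/T1).

        Close to 1 under the long-TR condition, in which case signal
        intensity is proportional to proton density times exp(-TE/T2)
        with no T1 weighting.
        """
        t1 = self.t1 if t1 is None else t1
        if t1 is None:
            raise ValueError("no T1 provided")
        if t1 <= 0:
            raise ValueError("t1 must be positive")
        return 1.0 - math.exp(-self.tr / t1)


def tomato_protocol() -> AcquisitionParams:
    """The emulated fruit protocol: TR 4000 ms, 61 echoes, TE 30..1830 ms."""
    return AcquisitionParams(tr=4000.0, te_grid=np.arange(1, 62) * ECHO_SPACING_MS)


def phantom_protocol(n_echo: int = 45, tr: float = 4000.0) -> AcquisitionParams:
    """Echo grid for the simulation phantom (default 45 echoes, 30 ms apart)."""
    if n_echo < 1:
        raise ValueError("n_echo must be >= 1")
    return AcquisitionParams(tr=tr, te_grid=np.arange(1, n_echo + 1) * ECHO_SPACING_MS)


# ---------------------------------------------------------------------------
# Geometry


@dataclass(frozen=True)
class Annulus:
    """Concentric annulus r_inner <= r < r_outer around ``center``.

    ``center=None`` centres the annulus in the grid. ``r_inner=0`` gives a
    filled disk.
    """

    r_inner: float
    r_outer: float
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.r_inner < self.r_outer):
            raise ValueError("need 0 <= r_inner < r_outer")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        cy, cx = self.center if self.center is not None else ((rows - 1) / 2.0, (cols - 1) / 2.0)
        yy, xx = np.ogrid[:rows, :cols]
        r = np.hypot(yy - cy, xx - cx)
        return (r >= self.r_inner) & (r < self.r_outer)


@dataclass(frozen=True)
class Region:
    """One phantom region: a label, a geometry, and its decay components."""

    label: int
    geometry: Annulus
    components: tuple[tuple[float, float], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("region labels must be positive (0 is background)")
        comps = tuple((float(a), float(t2)) for a, t2 in self.components)
        for a, t2 in comps:
            if a < 0:
                raise ValueError("amplitudes must be nonnegative")
            if t2 <= 0:
                raise ValueError("relaxation times must be positive")
        object.__setattr__(self, "components", comps)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric phantom specification: disjoint labelled regions on a grid."""

    shape: tuple[int, int]
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 1 or cols < 1:
            raise ValueError("shape must be positive")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        object.__setattr__(self, "regions", tuple(self.regions))


def three_ring_phantom_spec(
    shape: tuple[int, int] = (256, 256),
    amplitude: float = 250.0,
    t2s: Sequence[float] = (80.0, 200.0, 600.0),
    equal_area: bool = False,
    fill_fraction: float = 0.8,
) -> PhantomSpec:
    """Three concentric rings with mono-exponential decay per ring.

    The rings are centred in the grid and span ``fill_fraction`` of the
    half-width. By default the three annuli have equal radial thickness;
    with ``equal_area=True`` the radii are chosen so the three regions have
    equal areas, making the foreground-mean curve an equal-amplitude
    three-component mixture.
    """
    r_max = fill_fraction * min(shape) / 2.0
    if equal_area:
        edges = [0.0] + [r_max * math.sqrt(k / 3.0) for k in (1, 2, 3)]
    else:
        edges = [k * r_max / 3.0 for k in range(4)]
    names = ("inner", "middle", "outer")
    regions = tuple(
        Region(
            label=k + 1,
            geometry=Annulus(edges[k], edges[k + 1]),
            components=((float(amplitude), float(t2s[k])),),
            name=names[k],
        )
        for k in range(3)
    )
    return PhantomSpec(shape=shape, regions=regions)


# Alias: the printed simulation phantom of the source protocol.
fig_phantom_spec = three_ring_phantom_spec


# ---------------------------------------------------------------------------
# Data containers


@dataclass(frozen=True)
class MultiEchoStack:
    """rows x cols x n_echo grid of magnitude images with its TE vector.

    ``sigma`` records the (true or estimated) per-channel Gaussian noise
    standard deviation, in signal units, when known.
    """

    data: np.ndarray
    te_grid: np.ndarray
    sigma: float | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        te = _validate_te_grid(self.te_grid)
        if data.ndim != 3:
            raise ValueError("stack data must be rows x cols x n_echo")
        if data.shape[2] != te.size:
            raise ValueError("third dimension must match the number of echoes")
        if np.any(data < 0):
            raise ValueError("magnitude data must be nonnegative")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "te_grid", te)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_echo(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class LabelMap:
    """Integer structure assignment per voxel with a label name table."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        if lab.ndim != 2:
            raise ValueError("label map must be 2-D")
        if lab.min() < 0:
            raise ValueError("labels must be nonnegative")
        object.__setattr__(self, "labels", lab)
        for k in self.names:
            if int(k) < 0:
                raise ValueError("named labels must be nonnegative")

    def region_labels(self) -> list[int]:
        """Sorted non-background labels present in the map."""
        present = np.unique(self.labels)
        return [int(v) for v in present if v != 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def name(self, label: int) -> str:
        return self.names.get(int(label), f"structure_{int(label)}")


# ---------------------------------------------------------------------------
# Operations


def simulate_decay(
    components: Sequence[tuple[float, float]], te_grid: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Multi-exponential decay S(t) = sum_e A_e exp(-t/T2_e) on a TE grid.

    ``te_grid`` may contain t = 0 (returns the total amplitude there); when
    used as an acquisition grid it is strictly positive.
    """
    te = np.asarray(te_grid, dtype=float)
    if te.ndim != 1 or te.size == 0:
        raise ValueError("te_grid must be a non-empty 1-D sequence")
    if len(components) == 0:
        return np.zeros_like(te)
    amps = np.array([a for a, _ in components], dtype=float)
    t2s = np.array([t2 for _, t2 in components], dtype=float)
    if np.any(t2s <= 0):
        raise ValueError("relaxation times must be positive")
    if np.any(amps < 0):
        raise ValueError("amplitudes must be nonnegative")
    return np.exp(-te[:, None] / t2s[None, :]) @ amps


def generate_phantom(
    spec: PhantomSpec,
    params: AcquisitionParams | None = None,
    n_echo: int = 45,
) -> tuple[MultiEchoStack, LabelMap]:
    """Render a noiseless multi-echo stack and its label map from a spec.

    Every voxel of a region carries that region's decay curve exactly;
    background voxels are zero at all echoes.  Deterministic.
    """
    if params is None:
        params = phantom_protocol(n_echo=n_echo)
    te = params.te_grid
    rows, cols = spec.shape
    data = np.zeros((rows, cols, te.size), dtype=float)
    labels = np.zeros((rows, cols), dtype=np.int32)
    occupied = np.zeros((rows, cols), dtype=bool)
    names: dict[int, str] = {0: "background"}
    for region in spec.regions:
        m = region.geometry.mask(spec.shape)
        if np.any(m & occupied):
            raise ValueError(f"region {region.label} overlaps a previous region")
        occupied |= m
        labels[m] = region.label
        data[m, :] = simulate_decay(region.components, te)
        if region.name:
            names[region.label] = region.name
    return MultiEchoStack(data=data, te_grid=te, sigma=0.0), LabelMap(labels, names)


def add_rician_noise(stack: MultiEchoStack, sigma: float, seed: int) -> MultiEchoStack:
    """Corrupt a magnitude stack with Rician noise of channel std ``sigma``.

    The input magnitude is treated as the real-channel signal; independent
    zero-mean Gaussian noise of standard deviation sigma is added to the
    real and imaginary channels of every voxel at every echo (white across
    space and echoes) before taking the modulus:

        M = sqrt((S + n1)^2 + n2^2).

    Signal-free voxels therefore come out Rayleigh-distributed.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return replace(stack, sigma=0.0)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=stack.data.shape)
    n2 = rng.normal(0.0, sigma, size=stack.data.shape)
    noisy = np.hypot(stack.data + n1, n2)
    return MultiEchoStack(data=noisy, te_grid=stack.te_grid, sigma=float(sigma))


def estimate_layer_snr(
    stack: MultiEchoStack,
    signal_mask: np.ndarray,
    background_mask: np.ndarray,
) -> pd.DataFrame:
    """Per-echo signal power, noise power and SNR from two masks.

    Signal power is the mean squared intensity over ``signal_mask``.  Noise
    power is the Rayleigh-corrected channel variance estimated from the
    signal-free background: for a Rayleigh magnitude M, E[M^2] = 2 sigma^2,
    so sigma_hat^2 = mean(background^2) / 2.  SNR is their ratio (power
    ratio; +inf where the noise estimate is zero).
    """
    signal_mask = np.asarray(signal_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if signal_mask.shape != stack.shape[:2] or background_mask.shape != stack.shape[:2]:
        raise ValueError("masks must match the stack's spatial shape")
    if not signal_mask.any() or not background_mask.any():
        raise ValueError("both masks must be non-empty")
    if np.any(signal_mask & background_mask):
        raise ValueError("signal and background masks must be disjoint")

    sig = stack.data[signal_mask, :]          # (n_sig, E)
    bg = stack.data[background_mask, :]       # (n_bg, E)
    signal_power = np.mean(sig**2, axis=0)
    noise_power = np.mean(bg**2, axis=0) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise_power > 0, signal_power / noise_power, np.inf)
    return pd.DataFrame(
        {
            "echo": np.arange(stack.n_echo),
            "te_ms": stack.te_grid,
            "signal_power": signal_power,
            "noise_power": noise_power,
            "snr": snr,
        }
    )
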