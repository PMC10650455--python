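"""Training-time augmentations for force sequences.

All operators are pure functions of (input, parameters, rng) and act on the
preprocessed (clipped, scaled, fixed-length) 1-D sequence.  Operators with a
stochastic gate (`apply_prob`) draw one uniform variate per call and return
the input unchanged when the gate does not fire.  `rfft_stack` is the one
deterministic operator and the only one that changes the channel count
(1xT -> 3xT): models trained with it take 3-channel input at train *and*
test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .force_data import ForceTrace

AUGMENTATION_NAMES = ("fft", "quantize", "drift", "timewarp",
                      "gaussian_noise", "temporal_jitter")


@dataclass(frozen=True)
class AugmentationConfig:
    name: str
    apply_prob: float | None = None  # None -> operator default
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in AUGMENTATION_NAMES:
            raise ValueError(
                f"unknown augmentation {self.name!r}; expected one of {AUGMENTATION_NAMES}")
        if self.apply_prob is not None and not (0.0 <= self.apply_prob <= 1.0):
            raise ValueError("apply_prob must be in [0, 1]")


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, ForceTrace) else np.asarray(x, dtype=np.float64)


def rfft_stack(x) -> np.ndarray:
    """Stack the sequence with its real-input DFT coefficients.

    Row 0 is the sequence itself; rows 1-2 hold the real and imaginary parts
    of its one-sided DFT (floor(T/2)+1 coefficients), zero-padded on the
    right to length T.  Output shape (3, T).
    """
    v = _values(x)
    T = v.size
    if T < 2:
        raise ValueError("rfft_stack requires a sequence of length >= 2")
    spec = np.fft.rfft(v)
    out = np.zeros((3, T), dtype=np.float64)
    out[0] = v
    out[1, :spec.size] = spec.real
    out[2, :spec.size] = spec.imag
    return out


def quantize(x, n_levels: int = 10, apply_prob: float = 0.5,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Round each sample to the nearest of `n_levels` equally spaced levels
    spanning the trace's own [min, max]; ties break to the lower level."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    v = _values(x)
    if rng is None:
        rng = np.random.default_rng()
    if rng.random() >= apply_prob:
        return v.copy()
    lo, hi = v.min(), v.max()
    if hi == lo:
        return v.copy()  # single degenerate level
    levels = np.linspace(lo, hi, n_levels)
    # argmin returns the first (lower) level on distance ties
    idx = np.abs(v[:, None] - levels[None, :]).argmin(axis=1)
    return levels[idx]


def drift(x, n_points: int = 5, max_drift: tuple[float, float] = (0.1, 0.5),
          apply_prob: float = 0.5, rng: np.random.Generator | None = None) -> np.ndarray:
    """Multiply by a smooth random drift curve.

    `n_points` interior anchors get multipliers Uniform(1 + max_drift[0],
    1 + max_drift[1]); the endpoints are pinned at 1; a cubic spline through
    the anchors gives the per-step multiplier.
    """
    v = _values(x)
    T = v.size
    if T < n_points + 2:
        raise ValueError(f"drift needs T >= n_points + 2 (= {n_points + 2}), got T={T}")
    if rng is None:
        rng = np.random.default_rng()
    if rng.random() >= apply_prob:
        return v.copy()
    anchors = np.sort(rng.choice(np.arange(1, T - 1), size=n_points, replace=False))
    mults = rng.uniform(1.0 + max_drift[0], 1.0 + max_drift[1], size=n_points)
    knots_x = np.concatenate([[0], anchors, [T - 1]])
    knots_y = np.concatenate([[1.0], mults, [1.0]])
    curve = CubicSpline(knots_x, knots_y)(np.arange(T))
    return v * curve


def time_warp(x, n_ranges: int = 5, apply_prob: float = 0.5,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Double the local speed inside `n_ranges` disjoint segments.

    Each segment is floor(T/20) steps; within it every second sample is
    kept, then the shortened sequence is linearly resampled back to T so
    that fixed-shape batching is preserved.
    """
    v = _values(x)
    T = v.size
    if T < 20 * n_ranges:
        raise ValueError(f"time_warp needs T >= 20 * n_ranges (= {20 * n_ranges}), got T={T}")
    if rng is None:
        rng = np.random.default_rng()
    if rng.random() >= apply_prob:
        return v.copy()
    L = T // 20
    # disjoint placement: sort k draws in the compressed space, then re-expand
    offsets = np.sort(rng.integers(0, T - n_ranges * L + 1, size=n_ranges))
    starts = offsets + np.arange(n_ranges) * L
    keep = np.ones(T, dtype=bool)
    for s in starts:
        keep[s:s + L] = False
        keep[s:s + L:2] = True
    short = v[keep]
    return np.interp(np.linspace(0.0, short.size - 1, T), np.arange(short.size), short)


def gaussian_noise(x, sd: float = 0.1,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Additive i.i.d. Normal(0, sd) noise."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    v = _values(x)
    if rng is None:
        rng = np.random.default_rng()
    return v + rng.normal(0.0, sd, size=v.size)


def temporal_jitter(x, n_segments: int = 30, segment_len: int = 10,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Shuffle the order of consecutive fixed-length segments."""
    v = _values(x)
    if v.size != n_segments * segment_len:
        raise ValueError(
            f"temporal_jitter needs T == n_segments * segment_len "
            f"(= {n_segments * segment_len}), got T={v.size}")
    if rng is None:
        rng = np.random.default_rng()
    perm = rng.permutation(n_segments)
    return v.reshape(n_segments, segment_len)[perm].reshape(-1)


def apply_augmentation(name: str, x, rng: np.random.Generator,
                       apply_prob: float | None = None, **params) -> np.ndarray:
    """Apply one named augmentation to a 1-D sequence.

    Returns a (C, T) array: (3, T) for "fft", (1, T) otherwise, so the
    result can be fed straight into a model batch.
    """
    v = _values(x)
    if name == "fft":
        return rfft_stack(v)
    if name == "quantize":
        out = quantize(v, apply_prob=0.5 if apply_prob is None else apply_prob,
                       rng=rng, **params)
    elif name == "drift":
        out = drift(v, apply_prob=0.5 if apply_prob is None else apply_prob,
                    rng=rng, **params)
    elif name == "timewarp":
        out = time_warp(v, apply_prob=0.5 if apply_prob is None else apply_prob,
                        rng=rng, **params)
    elif name == "gaussian_noise":
        out = gaussian_noise(v, rng=rng, **params)
    elif name == "temporal_jitter":
        out = temporal_jitter(v, rng=rng, **params)
    else:
        raise ValueError(f"unknown augmentation {name!r}")
    return out[None, :]
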