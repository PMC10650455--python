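"""Temporal saliency: where on the force trace a model focuses.

The final pre-head feature map (TCN: the fourth block's output, 16 x T;
CLDNN: the last recurrent layer's sequence output, 64 x T/4) is averaged
over the feature axis, min-max normalized to [0, 1], and linearly
upsampled to the trial's original length.  The overlay renders the force
trace colored by that intensity: warm colors mark high-attention regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection

from .augmentation import rfft_stack
from .evaluation import _preprocess
from .force_data import TrialRecord
from .models import FittedModel

SALIENCY_ARCHS = ("tcn", "cldnn")


@dataclass(frozen=True)
class SaliencyTrack:
    intensities: np.ndarray  # length T, values in [0, 1]
    source_feature: str      # "F4" (tcn) or "recurrent_seq" (cldnn)
    T_prime: int             # temporal length of the source feature
    f: int                   # feature (channel) dimension of the source


def compute_saliency(model: FittedModel, trial: TrialRecord) -> SaliencyTrack:
    """Per-time-step attention intensity for a TCN or CLDNN model."""
    arch = model.spec.arch
    if arch not in SALIENCY_ARCHS:
        raise ValueError(
            f"saliency is defined for {SALIENCY_ARCHS}, not {arch!r}")
    seq = _preprocess([trial], model.scaler,
                      "pooled" if model.scaler is not None else "per_trial")[0]
    x = rfft_stack(seq) if model.input_transform == "fft" else seq[None, :]
    model.forward([x], capture=True)
    if arch == "tcn":
        feat = model.features["F4"][0]          # (16, T') with T' == T
        per_step = feat.mean(axis=0)
    else:
        feat = model.features["recurrent_seq"][0]  # (T', 64)
        per_step = feat.mean(axis=1)
        feat = feat.T
    lo, hi = per_step.min(), per_step.max()
    if hi > lo:
        norm = (per_step - lo) / (hi - lo)
    else:
        norm = np.zeros_like(per_step)  # constant activation: no attention anywhere
    T = trial.trace.T
    t_prime = norm.size
    if t_prime == T:
        up = norm
    else:
        src_pos = np.linspace(0.0, T - 1, t_prime)
        up = np.interp(np.arange(T), src_pos, norm)
    return SaliencyTrack(intensities=up, source_feature="F4" if arch == "tcn"
                         else "recurrent_seq", T_prime=t_prime, f=feat.shape[0])


def render_overlay(trial: TrialRecord, track: SaliencyTrack,
                   path: str | Path, cmap: str = "coolwarm", dpi: int = 100,
                   colorbar: bool = True) -> Path:
    """Write a raster image of the force trace colored by saliency."""
    force = trial.trace.values
    T = force.size
    if track.intensities.size != T:
        raise ValueError("saliency track length does not match the trial")
    t = np.arange(T)
    points = np.stack([t, force], axis=1).reshape(-1, 1, 2)
    segments = np.concatenate([points[:-1], points[1:]], axis=1)
    seg_intensity = 0.5 * (track.intensities[:-1] + track.intensities[1:])
    fig, ax = plt.subplots(figsize=(8, 3))
    lc = LineCollection(segments, cmap=cmap, norm=plt.Normalize(0.0, 1.0))
    lc.set_array(seg_intensity)
    lc.set_linewidth(1.5)
    ax.add_collection(lc)
    ax.set_xlim(0, max(T - 1, 1))
    pad = 0.05 * (force.max() - force.min() + 1e-9)
    ax.set_ylim(force.min() - pad, force.max() + pad)
    ax.set_xlabel("time step")
    ax.set_ylabel("force (N)")
    if colorbar:
        fig.colorbar(lc, ax=ax, label="attention")
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, dpi=dpi)
    plt.close(fig)
    return out
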