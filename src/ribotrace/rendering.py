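"""Rendering of synthetic TIRF movies from positioned trace sets.

Each spot is drawn as a 2-D Gaussian PSF whose amplitude is
proportional to the channel intensity, on a uniform photon background
with Poisson shot noise.  The pixel coordinate origin is the center of
pixel (0, 0); sub-pixel positions are continuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracesim import TraceSet

__all__ = ["Optics", "render_movie", "render_frame"]


@dataclass(frozen=True)
class Optics:
    psf_sigma: float = 1.3        # px
    gain: float = 1.0             # counts per intensity unit
    photon_background: float = 100.0  # mean counts per px
    fov: tuple[int, int] = (128, 128)  # (height, width) px

    def __post_init__(self):
        if not (0.2 <= self.psf_sigma <= 10):
            raise ValueError("psf_sigma out of sensible range")
        if self.gain <= 0 or self.photon_background < 0:
            raise ValueError("invalid camera parameters")


def render_frame(h, w, xs, ys, amps, sigma, background, rng) -> np.ndarray:
    """One noisy frame: Gaussians (peak amplitude ``amps``) + Poisson background."""
    img = np.full((h, w), float(background))
    half = int(np.ceil(4 * sigma))
    for x, y, a in zip(xs, ys, amps):
        if a <= 0:
            continue
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += a * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
        )
    noisy = rng.poisson(np.maximum(img, 0.0)).astype(np.float64)
    return noisy


def render_movie(traceset: TraceSet, optics: Optics, seed: int):
    """Render a positioned trace set into image stacks plus a truth table.

    Returns ``(stacks, truth)`` where ``stacks`` maps channel name
    ('rna', 'ch1', optionally 'ch2') to a uint16 array of shape
    (n_frames, H, W) and ``truth`` lists the true position and peak
    amplitude of every spot per frame and channel.
    """
    df = traceset.traces
    if "x_px" not in df.columns or "y_px" not in df.columns:
        raise ValueError("traceset has no positions; simulate with positions=True")
    h, w = optics.fov
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(31,)))
    channels = ["rna", "ch1"] + (["ch2"] if "ch2_signal" in df.columns else [])
    sig_col = {"rna": "rna_signal", "ch1": "ch1_signal", "ch2": "ch2_signal"}

    frames = np.sort(df["frame"].unique())
    stacks = {c: np.zeros((len(frames), h, w), dtype=np.uint16) for c in channels}
    truth_rows = []
    clipped = 0
    for fi, fr in enumerate(frames):
        g = df[df["frame"] == fr]
        xs = g["x_px"].to_numpy(float)
        ys = g["y_px"].to_numpy(float)
        inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        clipped += int((~inside).sum())
        for c in channels:
            amps = np.maximum(g[sig_col[c]].to_numpy(float), 0.0) * optics.gain
            img = render_frame(
                h, w, xs[inside], ys[inside], amps[inside], optics.psf_sigma,
                optics.photon_background, rng,
            )
            stacks[c][fi] = np.clip(img, 0, 65535).astype(np.uint16)
            for rid, cid, x, y, a in zip(
                g["rna_id"][inside], g["cell_id"][inside], xs[inside], ys[inside], amps[inside]
            ):
                truth_rows.append((int(fr), c, int(cid), int(rid), x, y, a))
    if clipped:
        warnings.warn(f"{clipped} spot-frames fell outside the field and were clipped")
    truth = pd.DataFrame(
        truth_rows, columns=["frame", "channel", "cell_id", "rna_id", "x_px", "y_px", "amplitude"]
    )
    return stacks, truth
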