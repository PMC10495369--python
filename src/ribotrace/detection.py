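"""Spot detection, track building and RNA-protein track linking.

Detection: band-pass (difference of Gaussians) + local maxima above an
SNR threshold on the robust noise level, each candidate refined by a
least-squares 2-D Gaussian fit giving sub-pixel center, amplitude,
sigma and local background.

Linking: greedy nearest-neighbour frame-to-frame assignment with gap
closing; tracks shorter than six frames (the "longer than five frames"
rule) and tracks with merge/split events are discarded before an RNA
track and a protein track are paired by minimal time-averaged distance
with at least five frames of temporal overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .tracesim import IntensityTrace

__all__ = [
    "Spot",
    "Track",
    "LinkedTrace",
    "detect_spots",
    "link_spots",
    "filter_tracks",
    "link_rna_protein",
]

log = logging.getLogger(__name__)


@dataclass
class Spot:
    frame: int
    x: float
    y: float
    amplitude: float
    sigma: float
    background: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0 or self.frame < 0:
            raise ValueError("invalid spot")


@dataclass
class Track:
    track_id: int
    channel: str
    spots: list[Spot] = field(default_factory=list)
    merged: bool = False
    split: bool = False

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def length(self) -> int:
        """Frames spanned, including closed gaps."""
        if not self.spots:
            return 0
        return self.spots[-1].frame - self.spots[0].frame + 1

    def position_at(self, frame: int):
        for s in self.spots:
            if s.frame == frame:
                return np.array([s.x, s.y])
        return None

    def amplitude_at(self, frame: int) -> float:
        for s in self.spots:
            if s.frame == frame:
                return s.amplitude
        return 0.0


@dataclass
class LinkedTrace:
    rna_track: Track
    ch1_track: Track | None = None
    ch2_track: Track | None = None
    overlap_ch1: int = 0
    overlap_ch2: int = 0

    def to_intensity_trace(self, dt: float, cell_id: int = 0) -> IntensityTrace:
        """Intensity trace on the RNA track's frames; protein 0 where absent."""
        frames = self.rna_track.frames
        rna = np.array([s.amplitude for s in self.rna_track.spots])
        ch1 = np.array(
            [self.ch1_track.amplitude_at(f) if self.ch1_track else 0.0 for f in frames]
        )
        ch2 = None
        if self.ch2_track is not None:
            ch2 = np.array([self.ch2_track.amplitude_at(f) for f in frames])
        return IntensityTrace(
            cell_id=cell_id,
            rna_id=self.rna_track.track_id,
            time=frames * dt,
            rna=rna,
            ch1=ch1,
            ch2=ch2,
            dt=dt,
            merged=self.rna_track.merged,
            split=self.rna_track.split,
        )


def _gauss2d(params, xx, yy):
    a, x0, y0, s, b = params
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s**2)) + b


def detect_spots(
    image: np.ndarray,
    expected_sigma: float = 1.3,
    snr_threshold: float = 5.0,
    frame: int = 0,
    box: int = 11,
) -> list[Spot]:
    """Detect diffraction-limited spots in one 2-D frame.

    Candidates come from a difference-of-Gaussians band-pass thresholded
    at ``snr_threshold`` times the robust (MAD) noise; each is refined
    in a ``box`` x ``box`` window (default 11 x 11 px) by least-squares
    Gaussian fitting.  Fits that diverge, leave the window, or return a
    sigma more than 2x off the expected width are dropped.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a single 2-D frame, got ndim={image.ndim}")
    if not (0.5 <= expected_sigma <= 5.0):
        raise ValueError("expected_sigma must be within [0.5, 5] px")

    bp = gaussian_filter(image, expected_sigma) - gaussian_filter(image, 2.5 * expected_sigma)
    noise = 1.4826 * np.median(np.abs(bp - np.median(bp)))
    if noise <= 0:
        noise = max(bp.std(), 1e-12)
    peaks = peak_local_max(
        bp, min_distance=max(1, int(round(2 * expected_sigma))),
        threshold_abs=snr_threshold * noise, exclude_border=2,
    )

    half = box // 2
    h, w = image.shape
    spots = []
    for py, px in peaks:
        y0, y1 = max(py - half, 0), min(py + half + 1, h)
        x0, x1 = max(px - half, 0), min(px + half + 1, w)
        win = image[y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        bkg0 = float(np.median(win))
        amp0 = float(win.max() - bkg0)
        if amp0 <= 0:
            continue
        p0 = [amp0, float(px), float(py), expected_sigma, bkg0]
        try:
            fit = least_squares(
                lambda p: (_gauss2d(p, xx, yy) - win).ravel(), p0,
                bounds=([0, x0 - 1, y0 - 1, 0.2, -np.inf], [np.inf, x1, y1, 10.0, np.inf]),
                max_nfev=200,
            )
        except Exception:
            continue
        a, xc, yc, s, b = fit.x
        if not fit.success and fit.status <= 0:
            continue
        if not (expected_sigma / 2 <= s <= expected_sigma * 2):
            continue
        if not (x0 <= xc < x1 and y0 <= yc < y1):
            continue
        spots.append(Spot(frame=int(frame), x=float(xc), y=float(yc),
                          amplitude=float(a), sigma=float(s), background=float(b)))
    return spots


def detect_movie(stack: np.ndarray, expected_sigma: float = 1.3, snr_threshold: float = 5.0):
    """Per-frame spot lists for a (n_frames, H, W) stack."""
    return [
        detect_spots(stack[i], expected_sigma, snr_threshold, frame=i)
        for i in range(stack.shape[0])
    ]


def link_spots(
    spots_per_frame,
    max_disp: float = 5.0,
    max_gap: int = 2,
    channel: str = "",
) -> list[Track]:
    """Greedy nearest-neighbour track building with gap closing.

    Per frame transition, candidate (track, spot) pairs are assigned in
    order of increasing squared displacement, rejecting moves larger
    than ``max_disp`` px/frame (scaled by the gap length when a track
    reconnects across up to ``max_gap`` missed frames).  Two tracks
    competing for one spot mark a merge; a leftover spot appearing
    within ``max_disp`` of an existing track's head marks a split.
    """
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 0
    for spots in spots_per_frame:
        if not spots:
            continue
        fr = spots[0].frame
        open_tracks = [
            t for t in open_tracks if fr - t.spots[-1].frame <= max_gap + 1
        ]
        cands = []
        for ti, t in enumerate(open_tracks):
            last = t.spots[-1]
            gap = fr - last.frame
            lim = (max_disp * gap) ** 2
            for si, s in enumerate(spots):
                d2 = (s.x - last.x) ** 2 + (s.y - last.y) ** 2
                if d2 <= lim:
                    cands.append((d2, ti, si))
        cands.sort()
        used_t, used_s = set(), set()
        contested_t = set()
        for d2, ti, si in cands:
            if si in used_s:
                if ti not in used_t:
                    contested_t.add(ti)  # this track also wanted an already-claimed spot
                continue
            if ti in used_t:
                continue
            open_tracks[ti].spots.append(spots[si])
            used_t.add(ti)
            used_s.add(si)
        for ti in contested_t:
            if ti not in used_t:
                open_tracks[ti].merged = True
        new_tracks = []
        for si, s in enumerate(spots):
            if si in used_s:
                continue
            t = Track(track_id=next_id, channel=channel, spots=[s])
            next_id += 1
            # a brand-new spot right next to a continuing track suggests a split
            for ti in used_t:
                last = open_tracks[ti].spots[-1]
                if last.frame == fr and (s.x - last.x) ** 2 + (s.y - last.y) ** 2 <= max_disp**2:
                    open_tracks[ti].split = True
                    t.split = True
                    break
            tracks.append(t)
            new_tracks.append(t)
        open_tracks.extend(new_tracks)
    return tracks


def filter_tracks(tracks, min_len: int = 5, drop_merge_split: bool = True):
    """Keep tracks longer than ``min_len`` frames (strict) without
    merge/split flags; returns (kept, exclusion_counts)."""
    kept = []
    counts = {"short_track": 0, "merge_split": 0}
    for t in tracks:
        if t.length <= min_len:
            counts["short_track"] += 1
            continue
        if drop_merge_split and (t.merged or t.split):
            counts["merge_split"] += 1
            continue
        kept.append(t)
    return kept, counts


def _pairing_distance(rna: Track, prot: Track):
    common = sorted(set(rna.frames) & set(prot.frames))
    if not common:
        return 0, np.inf
    d = []
    for f in common:
        pr, pp = rna.position_at(f), prot.position_at(f)
        d.append(np.hypot(*(pr - pp)))
    return len(common), float(np.mean(d))


def link_rna_protein(
    rna_tracks,
    protein_tracks,
    protein_tracks_ch2=None,
    max_dist: float = 3.0,
    min_overlap: int = 5,
) -> tuple[list[LinkedTrace], list[Track]]:
    """Pair each protein track with the RNA track of minimal
    time-averaged distance, requiring co-existence of at least
    ``min_overlap`` frames and mean distance <= ``max_dist``; ties break
    deterministically toward the lower RNA track id.  Returns the
    linked traces plus the orphan protein tracks."""
    links = {t.track_id: LinkedTrace(rna_track=t) for t in rna_tracks}
    orphans = []
    for chan, prots in (("ch1", protein_tracks), ("ch2", protein_tracks_ch2 or [])):
        for p in prots:
            best = None
            for r in rna_tracks:
                ov, dist = _pairing_distance(r, p)
                if ov >= min_overlap and dist <= max_dist:
                    key = (dist, r.track_id)
                    if best is None or key < best[0]:
                        best = (key, r, ov)
            if best is None:
                orphans.append(p)
                continue
            _, r, ov = best
            lt = links[r.track_id]
            if chan == "ch1":
                if lt.ch1_track is None or ov > lt.overlap_ch1:
                    lt.ch1_track, lt.overlap_ch1 = p, ov
                else:
                    orphans.append(p)
            else:
                if lt.ch2_track is None or ov > lt.overlap_ch2:
                    lt.ch2_track, lt.overlap_ch2 = p, ov
                else:
                    orphans.append(p)
    linked = [lt for lt in links.values() if lt.ch1_track or lt.ch2_track]
    if orphans:
        log.info("%d protein tracks left unlinked (orphans)", len(orphans))
    return linked, orphans
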