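"""Kinetic and measurement parameters of the trace simulator.

All rates are per second, speeds in codons/s, times in seconds and
intensities in arbitrary units (one completed fluorescent epitope
contributes ``unit_intensity``).  ``v_flank`` is the elongation speed
through ordinary coding sequence (v0 in the runoff inversion) and
``v_insert`` the speed through the repeat/control insert (vI).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass

__all__ = ["KineticParams"]


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class KineticParams:
    # telegraph (bursty) initiation: ON<->OFF switching and initiation while ON
    k_on: float = 0.01
    k_off: float = 0.012
    k_init: float = 0.02
    # elongation
    v_flank: float = 3.5
    v_insert: float = 3.5
    footprint: int = 10
    exclusion: bool = True
    stepping: str = "exponential"  # or "deterministic" (fixed dwell 1/v)
    # frameshifting / cap-independent channel-2 initiation
    p_fs_traversal: float = 0.0
    p_ran: float = 0.0
    # measurement model
    unit_intensity: float = 1.0
    noise_sd: float = 0.2
    background: float = 0.0
    rna_intensity: float = 10.0
    # sampling / perturbation schedule; burn_in is simulated but not
    # recorded, so recordings start with the mRNA at steady state
    dt: float = 10.0
    duration: float = 1800.0
    burn_in: float = 0.0
    t_drug: float | None = None
    t_bleach: float | None = None
    # mature single-protein intensity population (for normalization)
    mature_median: float = 24.0
    mature_cv: float = 0.3

    def __post_init__(self):
        for name in ("k_on", "k_off", "k_init", "v_flank", "v_insert",
                     "p_fs_traversal", "p_ran", "unit_intensity", "noise_sd",
                     "rna_intensity", "mature_median"):
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {val}")
        for name in ("p_fs_traversal", "p_ran"):
            if getattr(self, name) > 1:
                raise ParameterError(f"{name} is a probability, got {getattr(self, name)}")
        if self.v_flank <= 0:
            raise ParameterError("v_flank must be > 0")
        if self.footprint < 1:
            raise ParameterError("footprint must be >= 1 codon")
        if self.stepping not in ("exponential", "deterministic"):
            raise ParameterError(f"unknown stepping mode {self.stepping!r}")
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise ParameterError("dt must be > 0")
        if not (math.isfinite(self.duration) and self.duration >= self.dt):
            raise ParameterError("duration must be >= dt")
        if not (math.isfinite(self.burn_in) and self.burn_in >= 0):
            raise ParameterError("burn_in must be finite and >= 0")
        for name in ("t_drug", "t_bleach"):
            val = getattr(self, name)
            if val is not None and (not math.isfinite(val) or val < 0):
                raise ParameterError(f"{name} must be finite and >= 0 or None")
        if self.mature_cv < 0:
            raise ParameterError("mature_cv must be >= 0")
        if not math.isfinite(self.background):
            raise ParameterError("background must be finite")

    # -- helpers -------------------------------------------------------
    def replace(self, **kw) -> "KineticParams":
        return dataclasses.replace(self, **kw)

    @property
    def duty_cycle(self) -> float:
        """Long-run fraction of time the initiation switch is ON."""
        if self.k_on == 0 and self.k_off == 0:
            return 1.0  # no switching: stays in its initial (ON) state
        return self.k_on / (self.k_on + self.k_off)

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration / self.dt)) + 1

    def fs_codon_hazard(self, insert_length: int) -> float:
        """Per-codon frameshift probability giving the stated per-traversal total."""
        if insert_length <= 0 or self.p_fs_traversal <= 0:
            return 0.0
        if self.p_fs_traversal >= 1:
            return 1.0
        return 1.0 - (1.0 - self.p_fs_traversal) ** (1.0 / insert_length)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
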