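"""Table and image readers/writers and run configuration.

Trace tables are plain CSV with a mandatory header: cell_id, rna_id,
frame, time_s, rna_signal, ch1_signal, optionally ch2_signal and
x_px/y_px; unknown extra columns survive a round trip.  Ground-truth
sidecars (ribosomes.csv, rna_states.csv) are written alongside traces.
Movies go to multi-page 16-bit TIFF, one page per frame, one file per
channel, with channel order recorded in a metadata JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import KineticParams
from .tracesim import GroundTruth, TraceSet

__all__ = ["read_traces", "write_traces", "write_ground_truth", "write_movie",
           "RunConfig", "load_config", "save_config", "SchemaError"]

MANDATORY = ["cell_id", "rna_id", "frame", "time_s", "rna_signal", "ch1_signal"]
_FLOAT_FMT = "%.6g"


class SchemaError(ValueError):
    pass


def write_traces(traceset: TraceSet, path) -> None:
    path = Path(path)
    df = traceset.traces
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"traceset missing mandatory columns: {missing}")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta_path.write_text(json.dumps(traceset.metadata, sort_keys=True, indent=1, default=str))


def read_traces(path) -> TraceSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    for col in ("time_s", "rna_signal", "ch1_signal"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise SchemaError(f"{path.name}: non-numeric {col!r} at data row {row}")
        df[col] = coerced
    meta = {}
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    if "dt" not in meta:
        t = np.sort(df["time_s"].unique())
        meta["dt"] = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return TraceSet(traces=df, metadata=meta)


def write_ground_truth(truth: GroundTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.ribosomes.to_csv(outdir / "ribosomes.csv", index=False, float_format=_FLOAT_FMT)
    # fold each RNA's ON intervals into one row for the states sidecar
    iv = {
        (c, r): ";".join(f"{a:.3f}-{b:.3f}" for a, b in zip(g["start_s"], g["end_s"]))
        for (c, r), g in truth.on_intervals.groupby(["cell_id", "rna_id"])
    }
    states = truth.rna_states.copy()
    states["on_intervals"] = [
        iv.get((c, r), "") for c, r in zip(states["cell_id"], states["rna_id"])
    ]
    states.to_csv(outdir / "rna_states.csv", index=False, float_format=_FLOAT_FMT)


def write_movie(stacks: dict, outdir, name: str = "movie") -> None:
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    order = list(stacks)
    for chan in order:
        tifffile.imwrite(outdir / f"{name}_{chan}.tif", stacks[chan])
    (outdir / f"{name}_channels.json").write_text(
        json.dumps({"channel_order": order, "dtype": "uint16"}, indent=1)
    )


# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    design: str = "elongation_NLuc"
    params: KineticParams = dataclasses.field(default_factory=KineticParams)
    n_rna: int = 50
    n_cells: int = 5
    seed: int = 0
    outdir: str = "out"
    # analysis thresholds (defaults follow the published rules where stated)
    threshold_frac: float = 0.10
    init_frames: int = 4
    persistence: int = 3
    min_track_len: int = 5
    min_overlap: int = 5
    min_units: float = 2.0
    burst_k_sigma: float = 4.0
    survival_mode: str = "pooled_km"  # or "per_cell_mean"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pk = d.pop("params", {})
        if isinstance(pk, KineticParams):
            params = pk
        else:
            params = KineticParams(**pk)
        cfg = cls(params=params, **d)
        _validate_config(cfg)
        return cfg


def _validate_config(cfg: RunConfig) -> None:
    if not (0 < cfg.threshold_frac < 1):
        raise ValueError("threshold_frac must be in (0, 1)")
    for name in ("init_frames", "persistence", "min_track_len", "min_overlap"):
        if getattr(cfg, name) < 1:
            raise ValueError(f"{name} must be >= 1")
    if cfg.survival_mode not in ("pooled_km", "per_cell_mean"):
        raise ValueError("survival_mode must be pooled_km or per_cell_mean")


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    return RunConfig.from_dict(d)
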