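"""End-to-end workflow tying simulation to analysis.

Stages write their interface files into the run directory; each stage
declares the upstream artifacts it needs and fails with an explicit
dependency error naming the absent file.  A manifest records the
configuration digest, seed, package version and the thresholds in
force, so every output names the conventions that produced it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .frameshift import call_bursts, classify_trace, summarize_population
from .io import RunConfig, read_traces, write_ground_truth, write_traces
from .quantify import nascent_units, percent_translating
from .runoff import extract_runoff_time, km_survival, per_cell_survival
from .tracesim import sample_mature_proteins, simulate_traces

__all__ = ["run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "runoff", "frameshift", "quantify", "report")


class DependencyError(RuntimeError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} needs missing artifact: {path}")
    return path


def _survival_to_df(curve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": curve.times,
            "survival": curve.survival,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
            "n_at_risk": curve.n_at_risk,
            "mode": curve.mode,
        }
    )


def run_pipeline(config: RunConfig, stages=STAGES) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in set(stages)]
    traces_path = out / "traces.csv"

    if "simulate" in stages:
        ts, truth = simulate_traces(
            config.design, config.params, n_rna=config.n_rna,
            seed=config.seed, n_cells=config.n_cells,
        )
        write_traces(ts, traces_path)
        write_ground_truth(truth, out)
        log.info("simulate: %d traces written", ts.n_traces())

    if "runoff" in stages:
        ts = read_traces(_require(traces_path, "runoff"))
        t_drug = config.params.t_drug or 0.0
        records = [
            extract_runoff_time(
                tr, t_drug, config.threshold_frac, config.init_frames,
                config.persistence, min_len=config.min_track_len + 1,
            )
            for tr in ts.iter_traces()
        ]
        rec_df = pd.DataFrame(
            [
                (r.cell_id, r.rna_id,
                 "" if r.runoff_time is None else r.runoff_time,
                 int(r.censored),
                 "" if r.censor_time is None else r.censor_time,
                 r.exclusion)
                for r in records
            ],
            columns=["cell_id", "rna_id", "runoff_time_s", "censored", "censor_time_s", "exclusion"],
        )
        rec_df.to_csv(out / "runoff_records.csv", index=False)
        excl = rec_df["exclusion"].value_counts().to_dict()
        log.info("runoff: exclusion tallies %s", excl)
        eligible = [r for r in records if r.exclusion == "none"]
        if eligible:
            curve = (
                per_cell_survival(eligible)
                if config.survival_mode == "per_cell_mean"
                else km_survival(eligible)
            )
            _survival_to_df(curve).to_csv(out / "survival.csv", index=False)
            (out / "runoff_summary.json").write_text(json.dumps({
                "median_runoff_s": curve.median,
                "mode": curve.mode,
                "n_eligible": len(eligible),
                "exclusions": excl,
                "threshold_frac": config.threshold_frac,
                "init_frames": config.init_frames,
                "persistence": config.persistence,
            }, indent=1))

    if "frameshift" in stages:
        ts = read_traces(_require(traces_path, "frameshift"))
        thr = config.burst_k_sigma * config.params.noise_sd + config.params.background
        rows, triples = [], []
        for tr in ts.iter_traces():
            b1 = call_bursts(tr.ch1, thr)
            b2 = call_bursts(tr.ch2 if tr.ch2 is not None else np.zeros_like(tr.ch1), thr)
            cls = classify_trace(b1, b2)
            triples.append((cls, b1, b2))
            rows.append((tr.cell_id, tr.rna_id, cls,
                         b1.total_on_frames, b2.total_on_frames))
        pd.DataFrame(
            rows, columns=["cell_id", "rna_id", "class", "ch1_burst_frames", "ch2_burst_frames"]
        ).to_csv(out / "frameshift_calls.csv", index=False)
        summ = summarize_population(triples, n_cells=config.n_cells)
        (out / "frameshift_summary.json").write_text(json.dumps({
            "percentages": summ.percentages,
            "time_fractions": summ.time_fractions,
            "counts": summ.counts,
            "threshold_au": thr,
            "denominator": summ.denominator,
        }, indent=1, default=float))

    if "quantify" in stages:
        ts = read_traces(_require(traces_path, "quantify"))
        mature = sample_mature_proteins(config.params, 10000, config.seed)
        med = float(np.median(mature))
        rows = []
        for tr in ts.iter_traces():
            tls = float(np.mean(tr.ch1[-4:]))  # end-of-trace snapshot intensity
            bg = float(np.percentile(tr.ch1, 5))
            nu = float(nascent_units(tls, med, background=bg))
            rows.append((tr.cell_id, tr.rna_id, tls, nu, nu >= config.min_units))
        qdf = pd.DataFrame(
            rows, columns=["cell_id", "rna_id", "tls_intensity", "nascent_units", "translating"]
        )
        qdf.to_csv(out / "quantify.csv", index=False)
        per_cell, per_rep, summary = percent_translating(qdf, min_units=config.min_units)
        (out / "group_summary.json").write_text(json.dumps({
            "per_cell": per_cell.to_dict("records"),
            "replicate_means": per_rep.to_dict(),
            "summary": summary,
            "median_single_protein": med,
        }, indent=1, default=float))

    if "report" in stages:
        _require(traces_path, "report")
        report = {"config_digest": config.params.digest(), "seed": config.seed,
                  "version": __version__, "design": config.design}
        for name in ("runoff_summary", "frameshift_summary", "group_summary"):
            p = out / f"{name}.json"
            if p.exists():
                report[name] = json.loads(p.read_text())
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
        surv = out / "survival.csv"
        if surv.exists():
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            df = pd.read_csv(surv)
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.step(df["time_s"] / 60, df["survival"], where="post")
            ax.fill_between(df["time_s"] / 60, df["ci_low"], df["ci_high"],
                            step="post", alpha=0.3)
            ax.set_xlabel("time after drug (min)")
            ax.set_ylabel("fraction still translating")
            ax.set_ylim(0, 1.02)
            fig.tight_layout()
            fig.savefig(out / "survival.png", dpi=120)
            plt.close(fig)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
        "config": config.to_dict(),
        "params_digest": config.params.digest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return out
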