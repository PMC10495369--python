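# ribotrace

Simulation and analysis of single-molecule translation imaging on single
mRNAs: SunTag/HA nascent-chain traces, harringtonine ribosome-runoff
survival analysis with elongation-speed inversion, two-color
frameshift classification, and translating-fraction quantification —
plus spot detection and RNA–translation-site track linking for rendered
(or user-supplied) TIRF movies.

It is written for groups doing live-cell translation imaging of repeat
expansions and other hard-to-elongate sequences who need (a) a
mechanistic trace simulator with full ground truth to calibrate and
stress their analysis rules, and (b) a tested implementation of the
standard trace analyses, without any external dataset.

## The model in brief

Initiation is a telegraph-gated Poisson process (ON/OFF rates `k_on`,
`k_off`, initiation rate `k_init`); ribosomes step codon-by-codon with
exponential dwell `1/v` (`v_flank` outside the insert, `v_insert`
inside), optionally blocked within a 10-codon footprint of the ribosome
ahead. Signal per frame is the number of completed, still-attached
epitopes times a unit brightness, plus noise.

For the runoff assay, harringtonine stops initiation at `t_drug`; the
runoff time *t* of a trace is the first time its signal falls
persistently below 10% of the trace maximum. Runoff times form
Kaplan–Meier survival curves (plain Greenwood 95% bounds), and median
runoff times invert to elongation speeds through

    t = t_I + t_0 = L_I / v_I + L_0 / v_0
    v_0 / v_I = (t − L_0/v_0) / (L_I/v_0)

where `L_I` is the insert length, `L_0` the rest of the construct, and
`v_0 = L_total / t_control` from a uniform-speed control. `v_0/v_I` is
the insert's per-amino-acid residence-time fold.

## Worked example

```python
import ribotrace as rt

# a 30-min runoff experiment on the repeat reporter, 10x slower insert
params = rt.KineticParams(k_on=0.0, k_off=0.0, k_init=0.06,
                          v_insert=0.35, exclusion=False,
                          burn_in=300.0, t_drug=0.0, duration=1800.0)
traces, truth = rt.simulate_traces("elongation_GGGGCC70", params,
                                   n_rna=100, seed=1, n_cells=10)

records = [rt.extract_runoff_time(tr, t_drug=0.0) for tr in traces.iter_traces()]
curve = rt.km_survival([r for r in records if r.exclusion == "none"])
print(f"median runoff {curve.median/60:.1f} min, "
      f"{sum(r.exclusion != 'none' for r in records)} traces excluded")

# invert to the insert speed fold against a control cohort
ctrl, _ = rt.simulate_traces("elongation_NLuc", params.replace(v_insert=3.5),
                             n_rna=100, seed=1, n_cells=10)
ctrl_curve = rt.km_survival([r for r in (rt.extract_runoff_time(tr, 0.0)
                            for tr in ctrl.iter_traces()) if r.exclusion == "none"])
v0 = rt.estimate_v0(ctrl_curve.median, 1034)
est = rt.elongation_fold(curve.median, v0, L_I=140, L_0=863)
print(f"v0 = {v0:.2f} codons/s, insert slow-down = {est.speed_fold:.1f}-fold")
```

prints

```
median runoff 10.3 min, 0 traces excluded
v0 = 3.83 codons/s, insert slow-down = 10.8-fold
```

The slow insert more than doubles the median runoff time (10.3 vs
4.5 min for the control here), and the inversion turns that modest
runoff-time change into the ~10-fold elongation difference that
produced it — the insert is short, so it must be dramatically slower to
delay total runoff that much. (A single pooled median is quantised to
the 10-s frame interval; `ribotrace.studies.runoff_fold_recovery`
averages per-cell medians over replicate experiments for calibrated
recovery.)

There is also a CLI over the same pipeline:

```bash
ribotrace init-config cfg.yaml
ribotrace run --config cfg.yaml --seed 1 --out out/
```

which writes `traces.csv` + ground-truth sidecars, `runoff_records.csv`,
`survival.csv`, summary JSONs, a survival figure and a manifest naming
every threshold used.

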