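# Methods

## The model

`ribotrace` simulates and analyses single-molecule translation imaging of
membrane-tethered reporter mRNAs. A reporter ORF is described in codon
coordinates as an ordered tiling of regions — an N-terminal epitope
cassette (24 SunTag or HA epitopes), a repeat or control *insert*, and
flanking ordinary sequence — plus the codon positions at which each
epitope is completed. Two-color frameshift reporters carry a channel-1
cassette upstream of the insert and a channel-2 cassette downstream,
with the normal reading frame terminating at a stop codon directly after
the insert; channel 2 is reached only by ribosomes that shift frame
inside the insert or by cap-independent initiation.

Per mRNA, the simulator draws:

* **Initiation.** A two-state telegraph switch (rates `k_on`, `k_off`,
  stationary initial state) gates a Poisson initiation process of rate
  `k_init`. Harringtonine at `t_drug` sets the initiation rate to zero
  and leaves elongating ribosomes untouched.
* **Elongation.** Each ribosome advances codon by codon with
  exponentially distributed dwell of mean `1/v` (Gillespie), where `v`
  is `v_flank` outside the insert and `v_insert` inside; a
  deterministic-stepping mode (dwell exactly `1/v`) exists for analytic
  tests. With steric exclusion enabled (default), a ribosome cannot step
  within `footprint` (default 10) codons of the one ahead, and
  initiation attempts that find the entry window occupied are aborted.
  With exclusion off, an exactly equivalent vectorised
  independent-ribosome sampler is used.
* **Frameshifting.** The per-traversal probability `p_fs_traversal` is
  converted to a per-codon hazard `h = 1 − (1 − p)^(1/L_I)`; a shifted
  ribosome continues through the insert at `v_insert`, then translates
  the downstream cassette at `v_flank` and terminates at the ORF end.
  Cap-independent channel-2-only initiation is a separate Poisson hazard
  `p_ran` (default 0).
* **Signal.** Epitopes fluoresce the instant their last codon is
  translated (probe binding treated as instantaneous); a nascent chain
  carries all its completed epitopes until termination, when it leaves
  the site. Channel intensity per frame is
  `unit_intensity × (completed epitopes attached) + background` plus
  additive Gaussian noise of SD `noise_sd` (not clipped at zero). A
  photobleach at `t_bleach` zeroes all accumulated fluorescence;
  epitopes completed afterwards fluoresce normally. Note the total
  signal transiently *rises* after initiation stops while loaded
  ribosomes finish the cassette — a real feature of runoff traces.
* **Reproducibility.** Every mRNA gets an RNG substream derived from
  `(seed, cell_id, rna_id)`; identical inputs give byte-identical
  outputs.

A `burn_in` interval is simulated but not recorded, so recordings start
with the mRNA at steady state; `t_drug`/`t_bleach` are on the recorded
clock. Frame intervals default to 10 s over 30 min (runoff) and 5 s over
10 min (FRAP), matching the imaging protocols the simulator emulates.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| `k_init` | 0.02 /s | one initiation per ~50 s, mid-range for single-molecule reporters |
| `k_on`, `k_off` | 0.01, 0.012 /s | duty cycle 0.455 ≈ the ~45% fraction of time regular reporters translate |
| `v_flank` | 3.5 codons/s | ordinary elongation speed; the runoff inversion estimates ~3.5 AA/s |
| `footprint` | 10 codons | ribosome steric size ~30 nt |
| `unit_intensity`, `noise_sd` | 1, 0.2 a.u. | one epitope = 1 unit; spot-integration noise well below one epitope |
| `mature_median`, `mature_cv` | 24, 0.3 | a mature protein carries all 24 epitopes; right-skewed (gamma) spot intensities |

## Runoff analysis

The runoff time of a trace is the time from drug addition until the
protein signal falls below 10% of the raw trace maximum and stays below
for ≥3 consecutive frames (the persistence guards single-frame noise
dips; the rule itself is the 10% threshold). Traces are excluded when:
the mean of the first 4 frames is below the threshold (not visibly
translating at drug addition); the RNA track vanishes within ±2 frames
of the protein signal's final fall (lost mRNA, not runoff); the track
spans ≤5 frames; or it carries merge/split flags. Signals still above
threshold at the movie end are right-censored, never discarded.

Survival is estimated two ways: a pooled product-limit (Kaplan–Meier)
curve with plain Greenwood variance
`Var[S] = S² Σ d_i/(n_i(n_i−d_i))` and normal-approximation 95% bounds
clipped to [0, 1]; and a per-cell mode (per cell, the fraction of its
translating mRNAs still above threshold, averaged unweighted across
cells, CI from the across-cell SE). A curve median is the first time
survival ≤ 0.5 and is reported as undefined when the curve never gets
there. Group comparisons use the log-rank (Mantel–Cox) test (via
lifelines); a Cox regression with covariates is out of scope.

The elongation inversion decomposes the median runoff time as
`t = L_I/v_I + L_0/v_0`: the control construct (uniform speed) gives
`v_0 = L_total/t_control`, and the insert's speed fold — identical to
its per-amino-acid residence-time fold — is
`v_0/v_I = (t − L_0/v_0)/(L_I/v_0)`. Construct lengths are explicit
inputs (the published speed estimate is not exactly reproducible from
any single printed construct length, so nothing is hard-coded): the
repeat construct is 1003 codons (140-codon insert, 863-codon flank), the
control 1034 (171-codon insert).

### The fold-recovery study

The validation experiment simulates harringtonine runoff cohorts at
known insert slow-down factors {1, 5, 10, 15} and requires the full
pipeline (rule → survival → inversion) to recover them. Its frozen
conditions: constitutive AUG initiation `k_init = 0.06`/s (~1 per 17 s,
a strong reporter), 100 mRNAs in 10 cells per cohort, 5-min burn-in,
exclusion **off**, common random numbers across cohorts within an
experiment, and the fold taken as the mean over 3 independent replicate
experiments of inversions based on mean per-cell KM medians. Two of
these choices deserve explanation:

* The inversion presumes the last ribosome's transit is unobstructed.
  With the 10-codon footprint enabled, a 10–15-fold slower insert runs
  near jamming density at this initiation rate and the assay then
  measures elongation *plus* queueing delay (recovered folds 13–24).
  That crowding regime is a real behaviour of the model, kept and
  exercised in the tests, but the calibration study is run in the
  collision-free regime the inversion formula describes.
* Runoff times are quantised to the 10-s frame grid, so a single pooled
  median resolves the factor-1 case (a 9-s difference between
  constructs) only by luck. Averaging per-cell medians within a cohort
  and folds across replicate experiments — exactly how the
  per-amino-acid folds are aggregated in the experiments this emulates —
  restores sub-frame resolution.

## Frameshift classification

Per channel of a linked two-color trace, ON bursts are called by
hysteresis: a burst starts after `min_on_frames = 3` consecutive frames
above threshold (default `4 × noise_sd` above background, chosen to hold
the false-positive rate below 1%) and ends after `min_off_frames = 2`
consecutive frames below. An mRNA with bursts in both channels is
classified *frameshift* — no temporal overlap between channels is
required, only co-occurrence within the observation window; channel-1
only is *normal*, channel-2 only is *ran_only* (zero channel-1 bursts
over the whole track), neither is *silent*. Population summaries report
class percentages over translating (non-silent) mRNAs and time-in-state
fractions (ch1-only / both / ch2-only) over frames where either channel
is ON. Ground truth classes mirror what an imaging experiment can see: a
trace counts as frameshift when a shifted ribosome completes at least
one downstream-frame epitope during the recording.

## Quantification

Translation-site intensities are normalised to the median single
mature-protein intensity (nascent units); "actively translating"
defaults to ≥2 mature-protein equivalents — a threshold that separates a
multi-ribosome site from a single mature protein diffusing at the RNA —
and is always reported alongside results since the original cutoff is
not published. Percentages are computed per cell, averaged per
replicate, and summarised as mean ± SD over replicate means (the
replicate is the statistical unit). The fraction of time translating is
the fraction of a trace's frames inside called bursts; the duty-cycle
validation uses a short 200-codon reporter with slow switching because
the nascent-signal tail after an OFF switch lasts one ribosome transit —
with a 1000-codon reporter the measured ON fraction would exceed the
initiation duty by construction. Group comparison is the two-tailed
pooled-variance t-test on replicate means.

## Imaging

Rendered movies draw each spot as a 2-D Gaussian PSF (σ = 1.3 px) with
peak amplitude proportional to intensity on a Poisson background; pixel
origin is the center of pixel (0,0). Detection band-passes with a
difference of Gaussians, thresholds local maxima at `snr × MAD` noise,
and refines each candidate by least-squares Gaussian fitting in an
11 × 11 px window, dropping fits that diverge or whose σ deviates >2×
from expected. Linking is greedy nearest-neighbour per frame transition
(reject moves > 5 px/frame, close gaps ≤ 2 frames); contested
assignments set merge/split flags. Tracks spanning ≤5 frames or flagged
merge/split are discarded; a protein track links to the RNA track with
minimal time-averaged distance ≤ 3 px (the colocalization radius is not
published; this default is recorded in all outputs) over ≥5 co-existing
frames, ties broken toward the lower RNA track id.

## What the generator does and does not emulate

It reproduces: steady-state and drug/bleach-perturbed intensity
kinetics, bursting statistics, epitope-resolution signal build-up,
frameshift and RAN event frequencies, mature-protein intensity
populations, tethered-spot movies with shot noise. It does not model:
3-D optics, chromatic registration, probe-pool photobleaching,
fluorophore maturation or probe-binding kinetics, RNA secondary
structure, codon-specific dwell tables, or cell-to-cell kinetic
heterogeneity (cells differ only by sampling). Passing tests therefore
validate the analysis rules and estimators under the stated stochastic
model, not instrument- or biology-specific artefacts of real data.

## Numerical choices and degenerate inputs

Exponential dwells make the elongation engine a continuous-time Markov
chain, so event ties have probability zero; simultaneous
initiation/step timestamps resolve initiation first. A survival curve
over zero eligible records, a log-rank group without events, an
inversion with non-positive insert time (`t ≤ L_0/v_0`), and a
non-positive normaliser all raise explicit errors rather than returning
clipped values. Probabilities in CIs are clipped to [0, 1]. The
zero-variance equal-means t-test returns p = 1 by convention, logged.
Problem sizes in the validation suite (100-trace cohorts, 500-trace
frameshift sweeps, 200-trace duty recovery, 500 coverage replicates,
20-spot movies) were chosen so each study estimates its quantity well
inside the asserted tolerance.
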