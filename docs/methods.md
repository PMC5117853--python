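# Methods

## What the package computes

The analysis quantifies stimulus-evoked somatic calcium signals in
population imaging of dorsal root ganglion (DRG) neurons expressing a
genetically encoded calcium indicator (GCaMP), and classifies how each
neuron's mechanosensitivity changes after an inflammatory exposure.

For one region of interest (ROI) and one stimulus the core measure is

    ΔF/F₀ [%] = 100 · (F − F₀) / F₀

where F₀ is the mean background-subtracted fluorescence over a baseline
window immediately before stimulus onset and F is the
background-subtracted peak inside the response window.  The decay
half-time T₅₀ is the time from the peak to the first crossing of
baseline + ½·(peak − baseline), linearly interpolated between frames;
it is deliberately *undefined* for traces that never return toward
baseline inside the window — such cells are flagged, not assigned a
number.

Because the imaging is wide-field (not confocal), an ROI can collect
emission from nearby out-of-focus cells.  Each analyzed cell therefore
carries an adjacent-control ROI of similar size; the cell's peak ΔF/F₀
is corrected by subtracting the control's peak ΔF/F₀ (an additive
scattered-light model).  A ratio dialect is available via
`QuantConfig(normalization="ratio")` for users who prefer a
multiplicative reading.  A contamination flag is raised whenever the
control itself crosses the detection threshold.  Caveat: adjacent
controls should be drawn over *non-responding cells*, whose baseline
fluorescence is comparable to the analyzed cell's.  A control over
blank background has a much dimmer F₀, which inflates its ΔF/F₀ and
makes the subtraction overcorrect.

## Detection rule

A response is called when the (corrected) peak ΔF/F₀ exceeds
`k_sd` × the baseline ΔF/F₀ SD (default k_sd = 3) *and* an absolute
floor of 5% ΔF/F₀.  The floor exists because the peak is a maximum over
a multi-frame window: over W frames of pure noise the expected maximum
is ≈ √(2 ln W) baseline SDs, so a bare k·SD rule false-alarms far more
often than the one-frame normal tail suggests.  Negative corrected
peaks are retained in result tables but never counted as responses.

## Plasticity classification

Percent change of the per-force peak ΔF/F₀ between a pre-exposure and a
post-exposure session is referenced to the distribution of changes in
uninjected/vehicle controls: the significance band is the control mean
± 2 SD of pooled per-cell-per-force changes (band width and a per-force
banding mode are configurable).  Cell categories:

- **SA** ('silent' afferent): no detected response at any force before
  exposure, at least one after.  A cell with any pre-exposure detection
  can never be SA (asserted at cohort aggregation).
- **lost**: detected before, nothing after (reported inside the
  decreased group for three-way summaries, kept separate in detail).
- **I / D / NC**: any per-force change above the band with none below →
  increased; the mirror case → decreased; all inside → no change.  If
  changes cross both bands the excursion at the highest out-of-band
  force decides (the force series concentrates significance at the
  highest force), and the tie-break is logged.
- Cells insensitive in both sessions are excluded from all proportion
  denominators (never counted as NC); the denominator is mechanically
  sensitive cells plus converted silent afferents.

Acute chemical sensitivity is a detection over the window from infusion
onset to 20 s past its end.  Heat sensitivity is a binary call for
cells innervating the heated top skin layer only; bottom-layer cells
are untested by construction (the shielded layer stays below the
nociceptor activation threshold).

## Cohort statistics

Between-cohort category differences use the Pearson chi-square on 2×2
tables, computed from Σ(O−E)²/E with p from the χ²₁ tail.  No Yates
correction by default: on the silent-afferent table (2/47 vs 8/39) the
uncorrected statistic gives p ≈ 0.019; the corrected variant
(`correction=True`) is noticeably more conservative on such sparse
tables.  Repeated-measures designs (e.g. triple K⁺ applications) use a
one-way RM-ANOVA assembled from its sums of squares, with Tukey HSD
referenced to the studentized range; two-group comparisons use the
classical pooled-variance t.  All three are formula-level
implementations cross-checked in the test suite against independent
library implementations.  Percentages are reported rounded to integers
(one decimal where a finer figure is conventional).  No
multiple-testing adjustment is applied.

## The synthetic cohort generator

The generator exists so that every stage — trace extraction, ΔF/F₀,
detection, classification, cohort statistics — can be validated against
known ground truth without any recordings.  It is deliberately the
*simplest* forward model that reproduces the phenomena the analysis
must cope with.

**Spikes → calcium → fluorescence.**  Each spike increments a
single-compartment calcium pool by `ca_per_spike_nM`; the pool decays
mono-exponentially with `tau_decay_s` toward `ca_rest_nM`;
fluorescence reads the pool through a Hill saturation with
dissociation constant `kd_nM` and coefficient `hill_n`, between
`f_min` and `f_max`.  Frozen defaults: 50 nM rest, 150 nM per spike,
τ = 0.25 s, Kd = 350 nM (GCaMP3-like affinity; 144 nM approximates
GCaMP6s), Hill n = 2, F ∈ [50, 1000] a.u.  These are calibration
choices of this package — the indicator's true in-neuron kinetics are
not published for this preparation — chosen so that:

- electrical trains produce phase-locked transients that summate;
- transient counting (peak prominence ≥ 10% of the trace's amplitude,
  phase-locked within half an inter-pulse interval) recovers the exact
  pulse count at 0.5–10 Hz and fails at ≥20 Hz, where summation erases
  the per-spike maxima;
- fluorescence saturates rather than growing without bound.

**Stimuli.**  Electrical trains fire one spike per pulse (a fidelity
parameter thins pulses at ≥100 Hz).  Mechanical holds (2 s) evoke a
nondecreasing force→spike-count map, default {50→3, 100→4, 200→5,
500→6} spikes, spread uniformly over the hold, so peak ΔF/F₀ encodes
force.  Sustained K⁺ depolarization drives a plateau whose amplitude
(300 nM above rest — the locally linear point of the Hill readout, so
relative ΔF/F₀ declines track amplitude factors) falls by factors
1.00/0.93/0.88 over repeated applications; these echo the in vitro
decline qualitatively and are not treated as reproducible truth.
Narrow-spike (Aβ-like) cells carry a near-zero calcium gain and stay
below detection at every frequency.

**Variability.**  Trial-to-trial amplitude variability is lognormal on
the calcium gain with a session-level component (σ = 0.08, shared by
all stimuli of one imaging session — slow drift of focus, expression,
health) plus a small per-stimulus component (σ = 0.003).  The
session-dominant structure makes a cell's four per-force percent
changes strongly correlated, which is what keeps the 2-SD
classification's per-cell false-call rate near the single-draw tail
(≈5–6%) instead of the ~17% that four independent draws would give.
Additive Gaussian frame noise (0.5 a.u.) plays the role of camera
noise on the trace-level fast path.

**Plasticity effects.**  Post-exposure, increased/decreased cells
scale their calcium gain by exp(±effect·σ_pc), where σ_pc is the
model's log-amplitude-ratio SD — a symmetric multiplicative change of
`effect` control-SDs (default 5).  Silent afferents fire no mechanical
spikes before exposure and acquire a responder map afterwards, 88% of
them from the lowest force.  Lost cells stop firing to mechanical
stimuli.  Control arms (uninjected, vehicle, heat-only) cannot carry
effect categories by construction.  Ground-truth heat-sensitivity and
direct-IS-response flags are assigned at the per-category rates the
cohorts report (e.g. 50% of converted silent afferents heat-sensitive,
20% directly IS-responsive).

**Movie rendering.**  Cells are Gaussian discs on a grid; a wide
Gaussian halo diverts a configurable fraction of emission to emulate
out-of-focus contamination; rigid per-frame jitter and Poisson shot
noise complete the corruption model.  With all corruption at zero, the
ROI mean of a rendered cell is an affine function of its input trace.
The pipeline runs on generated traces directly by default; rendering
is exercised by the I/O tests and the `--render-stacks` CLI path.

**What the generator does not emulate** — and hence what passing tests
do not certify about real data: non-rigid tissue motion, focal drift
with structure over minutes, bleaching, overlapping somata,
indicator-expression heterogeneity coupled to cell size, and real
spike-train statistics (bursting, adaptation).  Results on real movies
depend on ROI quality and motion control in ways the synthetic tests
cannot measure.

## Numerical and statistical choices

- Pixel membership: a pixel belongs to an ROI disc when its center is
  within `radius_px` of the center (0-based, x = column).  Extraction
  is checked exactly against a per-pixel loop.
- Windows: baseline = 2 s before onset, response = onset → offset +
  2 s (both configurable).  Peaks are single maximum frames; an
  optional boxcar smoother exists for noisy real data and is off by
  default.
- Degenerate baselines (F₀ ≤ 0) raise and exclude the cell with a log
  entry; T₅₀ of non-returning transients is undefined, not imputed.
- The specificity check compares the observed per-cell false-call rate
  with a Monte-Carlo oracle of the control-variability model
  (`null_call_rate_model`), which re-estimates the 2-SD band from a
  finite control sample in every replication.  The comparison interval
  therefore combines binomial noise with band-estimation dispersion;
  a pure binomial interval around a fixed tail probability would be
  overdispersed and reject a correct classifier too often.
- Study problem sizes: the recovery study runs 20 seeded replicates of
  four arms (83-cell vehicle, 47-cell IS, 39-cell heat+IS, 30-cell
  heat-only) on the trace-level fast path; specificity uses 500 null
  cells against a 100-cell control reference.

## Known limitations

- The classification aggregates multi-force changes with an any-force
  rule; with 2-SD bands this has an irreducible per-cell false-call
  floor of ~4–6% under realistic correlated noise, so ~1 of 23
  no-change cells per cohort is mislabeled in expectation.  This is a
  property of the 2-SD criterion itself, not of the implementation.
- Percent change is undefined for zero baselines by design; cells in
  that situation are routed to the silent-afferent/lost logic.
- The uncorrected chi-square is anti-conservative on very sparse
  tables; use `correction=True` or exact methods when expected counts
  fall below ~5.
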