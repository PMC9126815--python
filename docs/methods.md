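# Methods

This note documents the models, defaults and numerical conventions behind
`socialphys`, and what the synthetic generators do and do not emulate.

## Arena geometry and behavioural scoring

The three-chamber arena is a 60 × 40 cm rectangle split into three equal
20 cm-wide chambers along x; the two 16 × 9 cm enclosures sit at the
centres of the outer chambers. The proximity zone around each enclosure is
a circle of diameter "enclosure ø + 5 cm". A rectangular enclosure has no
single diameter; we use the circumscribing dimension max(16, 9) = 16 cm,
giving a 21 cm zone, and expose both the margin and an explicit
`zone_diameter` override. Zone membership is evaluated on the tracked
centre point and the zone disc is closed (a point exactly on the boundary
counts as inside). Dwell time weights each frame by its forward inter-frame
interval, so chamber times partition the session span exactly. The dwell
circle is the full disc, not the annulus outside the enclosure footprint.

Entry detection is a debounced state machine: an entry is an
outside→inside transition, and an exit shorter than the debounce (default
0.5 s, suppressing boundary jitter at typical 25 Hz tracking) is merged
into the ongoing visit. Events can be flagged (never dropped) by
configurable exclusion windows; the default windows are empty because the
natural reading of excluding the "first and last" stretch of a 10-min test
is ambiguous at desk scale — callers pass explicit windows.

The inclusion rule keeps an animal when total enclosure exploration is at
least 10 s (the exclusion criterion is "less than 10 s", so the boundary is
kept).

## Tracking simulator

Between scheduled visits the point performs a Gaussian random walk (step
SD 1 cm/frame at 25 Hz by default) reflected at the walls and held at
least 1 cm outside both proximity zones, so scheduled visits are the only
entries and the schedule is exact ground truth. During a visit the point
sits jittered around the enclosure centre; the trajectory therefore jumps
at visit onset. This is deliberately minimal: it validates geometry and
event logic, not locomotor statistics (no velocity autocorrelation, no
thigmotaxis), so passing tests say nothing about tracking-noise robustness
beyond the debounce.

## Photometry model and analysis

The generator produces the raw interleaved stream: one photodetector at
`raw_rate` while the 465/405 nm LEDs alternate in square half-pulses at
40 Hz. The continuous 465 signal is
`B·exp(−t/τ_bleach)·(1 + Σ a·K(t − t_event − latency)) + motion + noise`,
where K is a double-exponential kernel (rise 0.2 s, decay 1.6 s — typical
for slow GCaMP indicators; the exact kinetics are irrelevant to pipeline
correctness) normalized to unit peak, and `a` is the response amplitude in
ΔF/F units (the event term scales with the baseline so ΔF/F recovers `a`
exactly). The 405 channel carries the same bleaching, noise and the
verbatim motion artifact, but no calcium term. Motion is a half-sine bump
added identically to both channels — the minimal model that exercises
isosbestic correction.

Demultiplexing averages each LED pulse after discarding its leading 20%
(LED/detector settling), timestamps at the pulse centre, and ignores
off-state samples; each channel ends up at ~40 Hz. ΔF/F uses the mean
(median available) over the F0 window, by convention the last portion of
habituation before stimuli appear. The PETH window defaults to [−5, +10] s
with the grid anchored at 0 and linear interpolation onto it; events whose
window leaves the recording are dropped and logged. z-scores use the mean
and SD of the ΔF/F restricted to the test phase (habituation excluded) —
this is configurable via `session_interval` since the normalization epoch
is a genuine free choice. Isosbestic correction (linear 405→465 fit,
ΔF/F against the fitted baseline) is provided but off by default: the
primary ΔF/F path uses the raw 465 channel only. Because the two channels
sample a fast artifact half a pulse apart, correction suppresses rather
than cancels shared artifacts.

Desk-scale runs (tests, acceptance) simulate at 1200 Hz raw rate — still
30 samples per 40 Hz alternation period — rather than the instrument's
12 kHz; the default of the session type remains 12 kHz.

## Integrate-and-fire electrophysiology

The synthetic MSN is a leaky integrate-and-fire cell (τ_m 10 ms, R_in
100 MΩ, rest −80 mV, threshold −45 mV, reset −80 mV, refractory 2 ms —
an MSN-flavoured hyperpolarized, low-excitability profile with rheobase
between 350 and 400 pA on the 50 pA step grid). A Trpv4-like conductance
enters as a static ohmic term g_t·(V − E_t) with E_t = 0 mV, which
depolarizes the cell and left-shifts the F–I curve. Noiseless sweeps are
integrated event-exactly: the membrane follows the exponential bridge
between samples and threshold crossings are solved analytically, so spike
counts equal the closed-form interspike-interval formula
`τ·ln((V∞ − V_reset)/(V∞ − V_th))` to machine precision — the closed form
used in tests is derived independently of the integrator. Spikes are
marked as a single +30 mV sample so the threshold-crossing detector
(0 mV, 2 ms minimum ISI — standard conventions) counts them.

Ramp sessions sample I(V) directly on the −100..+100 mV grid every 5 s:
leak plus the blocker-sensitive term during the 5-min baseline, leak only
during the 20-min drug phase (the blocker acts instantaneously — no wash-in
kinetics, hence the recommended drug window is late anyway). The analysis
windows are half-open in time; the default recommendation is all of
baseline vs the last 5 min of the drug phase. EPSCs are biexponential
(rise 1 ms, decay 6 ms; optional slow component with 80 ms decay standing
in for the NMDA-receptor current). Amplitudes are baseline-subtracted
signed peaks in a 1–20 ms post-stimulus window with a 10 ms pre-stimulus
baseline. The AMPA/NMDA convention — peak at −70 mV divided by the
45–55 ms late-window mean at +35 mV — is one reading of an ambiguous
verbal definition; both windows and the orientation are parameters.
Chord conductances use a 0 mV glutamatergic reversal by default. At the
50 ms paired-pulse interval the second EPSC rides on ~0.2% of the first's
tail; ratios are reported as measured, without overlap correction.

QC boundaries follow the stated rules exactly: resting potential must be
strictly below −60 mV; an access-resistance change of exactly 20% passes;
the Ih criterion flags a sag ratio above 0.1 at the −140 mV step (the
underlying rule is qualitative — "absence of Ih" — so the 0.1 is an
explicit, configurable operationalization).

## Count simulation and worst-case selection

The count generator covers the full 2 populations × 2 infections × 2
conditions × n replicates design. Gene baselines (RPM units) are
log-uniform on [20, 2000]; library sizes uniform on [0.8, 1.2] × 10⁶ so
RPM roughly tracks counts; counts are negative binomial with
var = µ + α·µ² (α = 0.05 default; α = 0 degenerates to rounded means).
Planted genes multiply their mean by 2^(±log2fc) in the `sh` condition of
designated population/infection cells. The generator ignores real-data
features such as gene-length bias, GC effects and count–dispersion trends,
so calibration results transfer to real tables only to the extent those
effects cancel in within-gene ratios.

Worst-case selection enumerates all cross-group replicate pairs.
Direction is concordant only when every pairwise ratio falls on the same
side of 1; the worst-case fold change is the minimum pairwise magnitude
`max(r, 1/r)`, and discordant genes are never selected (a sign-flipping
gene has worst-case magnitude ≤ 1 under any consistent reading). The
pseudocount defaults to 0 because the strict >10 RPM filter precedes
selection; the filter default is per-sample ("all"), the strictest rule,
with "any" and "mean" exposed. Fold changes are computed on RPM — the
scale the filter is stated on; PCA instead uses log2(x+1) on RPM as a
light-weight variance stabilization in place of a fitted regularized-log
transform, which belongs to an external package. This is recorded in the
PCA output metadata and is the main caveat when comparing gene counts with
the deposited-data benchmark.

Fisher enrichment is the exact hypergeometric test on the 2×2
selected × annotated table, one-sided (enrichment) by default; tests
validate it against explicit tail enumeration. ΔΔCt follows the standard
two-reference normalization: ΔCt per sample, ΔΔCt against the control-group
mean, expression 2^(−ΔΔCt).

## Statistical battery

Normality is screened per tested variable with Shapiro–Wilk at α = 0.05;
on rejection the paired t becomes a Wilcoxon signed-rank and the one-sample
t against chance 0.5 a signed-rank on deviations, with the fallback
recorded in the result. The F–I comparison is a mixed repeated-measures
ANOVA (between: group; within: current step; subject: cell) via pingouin,
with the Greenhouse–Geisser-corrected p adopted when Mauchly's test
rejects sphericity; the table's `p` column carries that headline value.
Cells missing steps are excluded listwise with a warning. The outlier
screen flags values beyond 3.5 scaled MADs from the median and never
removes anything — exclusion is an analyst's decision.

Calibration (acceptance suite): under a null cohort of 10 animals the
battery's type-I error over 2000 replicates is checked against the
[0.04, 0.06] band, and its power under a paired effect of d = 1.5 is
compared with the analytic noncentral-t power within the Monte-Carlo 95%
CI. These sizes (2000 × 10) keep the whole calibration under a minute.

## Determinism and degenerate inputs

All generators take explicit integer seeds and are bit-reproducible; the
cohort runner derives per-animal seeds from one master seed and regenerates
byte-identical output files. Degenerate inputs fail loudly rather than
silently: zero total exploration (undefined index), non-positive F0, zero
session variance, constant matrices in PCA, zero-variance isosbestic fits,
singleton replicate groups and zero-total samples all raise with specific
messages.

## Known limitations

- The tracking walk is geometrically faithful but kinematically naive.
- The photometry noise is white; real recordings have 1/f drift beyond the
  single exponential bleach term.
- The LIF cell has no adaptation, so F–I curves rise faster than real MSN
  curves at high currents; only the oracle-checked counting logic matters.
- The regularized-log PCA transform is approximated by log2(x+1).
- The benchmark against the deposited study tables requires downloading
  them separately; it is not exercised by the desk-scale suite.
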