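# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the limitations a user should know before trusting the numbers
on real data.

## Calcium-trace analysis

**Normalization.** Activity is expressed as ΔF/F_min with F_min the minimum
raw reading of the whole recording: dff(t) = (F(t) − F_min)/F_min. The
transform requires min(F) > 0 and is invariant to rescaling the raw trace
by any positive constant (F_min scales along), but *not* to additive
offsets: adding c to the raw trace changes dff to (F(t) − F_min)/(F_min +
c). Both properties are asserted in the test suite; the offset sensitivity
is a real caveat when comparing recordings acquired at different detector
offsets.

**Baseline level and transient detection.** A transient is a maximal run of
consecutive frames with dff above `threshold_multiple` (default 3) times a
baseline level. "Baseline level" is an interpretation point: this package's
default estimator is the robust noise scale 1.4826 × median absolute
deviation of the dff trace, floored at 1e−6 so constant traces have a
positive threshold and yield zero transients rather than an error. An
alternative reading — the mean of the frames at or below the trace median,
i.e. a resting-ΔF/F level — is available as
`baseline_method="submedian_mean"`. Both are flagged as interpretations;
neither is claimed to be *the* definition used by any particular lab.

`min_duration_frames` defaults to 1 (at the 2 Hz default sampling rate, one
frame = 0.5 s). With a 1-frame criterion, noise near the threshold crossing
of an event's decay tail can split one event into several counted
transients; at realistic noise this inflates counts severalfold. Counting
applications should set a duration criterion of ~2 s (4 frames at 2 Hz),
which in simulation brings detected counts to within a few percent of
ground truth; amplitude and integral metrics are much less sensitive. The
detector itself is deterministic and matches an independent brute-force
run-length scan exactly, which is the property the tests enforce.

**Integrated calcium** is the plain sum of dff over *all* frames, not only
frames within transients, and is not normalized by recording length; a
comparison across recordings of different lengths is the caller's
responsibility (the pipeline logs a warning when lengths differ).

**Synchrony.** Pairwise Pearson correlation of the dff traces within one
FOV, summarized by the arithmetic mean of the C(n,2) upper-triangle
entries (Fisher-z averaging is available as an option but is not the
default, since the plain average is what "averaged correlation" computes).
Pairs involving a constant trace have no defined correlation; they are
excluded from the mean and counted in `n_excluded_pairs` instead of being
silently imputed.

## Spine turnover

Spines are 1-D arc-length positions along a shaft; lateral offsets and
morphological subtypes are out of scope. Shafts are filtered to those
carrying 8–15 spines *in session 1*, and that shaft set is then fixed for
both sessions.

**Matching** is greedy nearest-neighbour: all cross-session pairs within
`tolerance_um` (default 1.0 μm) are processed in ascending distance order,
ties broken by lower session-1 then session-2 index, each spine used at
most once. Greedy was chosen over optimal assignment because it is
deterministic, order-independent given the tie-breaks, and provably
equivalent to the optimal matching when spines are separated by more than
twice the tolerance — the regime the 8–15-spines-per-shaft filter puts real
dendrites in. An exhaustive assignment oracle in the tests confirms the
equivalence on small shafts. The practical failure mode is different:
when new spines appear within the tolerance of an eliminated spine's old
position, they are matched as survivors and elimination is underestimated.
The tolerance should therefore be comfortably above the session-to-session
positional jitter but small against typical inter-spine spacing; with
jitter ≈ 0.1 μm a tolerance of 0.5 μm recovers simulated elimination rates
without measurable bias.

**Rates.** The denominators are a convention, not a law of nature:
formation = 100·|new|/N₁, elimination = 100·|eliminated|/N₁, turnover =
their arithmetic mean, with N₁ the session-1 count — the dominant
convention in transcranial spine-imaging work. A pooled alternative
(formation over N₂, turnover = 100·(gained+lost)/(N₁+N₂)) is selectable
via `denominator="pooled"`. Whether spines should be pooled across animals
or averaged per animal before group testing is likewise left to the
caller; the pipeline computes per-animal summaries.

## Astrocyte morphometry

SWC files are parsed in two passes (forward parent references are legal),
must contain exactly one root, and round-trip through the writer to 1e−4
μm. Soma area is the shoelace area of the contour polygon
(orientation-independent, self-intersecting contours rejected).

**Sholl analysis** is computed in the tree's native 3-D space. The centre
is the arithmetic mean of the soma-contour vertices (at the root's z) — a
sparse-contour-robust choice; the area centroid differs negligibly for
near-convex somas. The boundary convention is "inside means distance ≤ r":
a segment with an endpoint exactly on a circle does not cross it, and
annuli are half-open [r_{i−1}, r_i) starting at r₀ = 0. Segments longer
than r_step/2 are recursively bisected before crossing counts so one long
segment cannot skip circles; annulus lengths are exact segment–sphere
clippings (quadratic roots per sphere, sub-intervals binned by midpoint
distance), so the annulus lengths plus the length beyond the largest
circle partition the total length to float precision. Default radii start
at 5 μm with a 5 μm step and extend to the smallest multiple enclosing the
tree; profiles are only comparable across cells at matched radii, which
the CLI enforces per run.

Branch count is the number of maximal unbranched segments (paths between
the root, bifurcations, and terminals), counted as Σ outdegree over the
root and all bifurcation nodes.

## Group statistics

The decision tree is: Shapiro–Wilk per group at α = 0.05; if every group
passes, one-way ANOVA with Tukey HSD (post-hoc only for k > 2), otherwise
Kruskal–Wallis (tie-corrected) with Dunn's z-based pairwise comparisons.
Constant groups make Shapiro–Wilk undefined and are routed to the
nonparametric branch with a logged warning. Dunn p values are reported
unadjusted by default — matching the per-pair reporting style common in
this literature — with Holm/Bonferroni options. Two-way designs use a
fixed-effects OLS decomposition with type-II sums of squares (identical to
the classical balanced decomposition on balanced designs; a note is
recorded when the design is unbalanced). Treating the within factor (e.g.
training day) as a crossed fixed effect rather than a repeated measure is
an explicit interpretation and is labelled as such in result notes; no
mixed-effects machinery is included. Per-gene expression contrasts default
to Student's equal-variance t (Welch optional), and ΔΔCt assumes
amplification efficiency exactly 2 — efficiency correction is out of
scope.

Degenerate inputs fail loudly: zero within-group variance with equal means
raises an undefined-F error, all-identical values raise an undefined-H
error, and zero-variance t-test inputs are resolved explicitly (t = 0,
p = 1 when means agree; p = 0 when they differ).

## Synthetic data

The generator exists to give every stage a ground truth, not to claim
realism for any particular dataset.

**Traces.** Each ROI receives a Poisson event train; an event adds
amplitude × k(t − t₀) to the true dff, with k a difference-of-exponentials
kernel normalized to unit peak so the drawn amplitude *is* the true peak
ΔF/F (this is what makes amplitude-recovery tests exact). Default kinetics
are tau_rise = 0.1 s with tau_decay = 1.8 s as a slow-indicator stand-in
(neuronal GCaMP6s) and 0.4 s as the fast stand-in (astrocytic GCaMP6f);
only the fact that the kinetics differ is anchored in the source designs,
the values are configurable defaults. Sampling is 2 Hz, matching the
acquisition rate of layer-V somatic imaging. Amplitudes are lognormal
parameterized by arithmetic mean and SD; synchrony comes from one shared
population train per FOV, each cell event drawn from it with probability
`sync_prob`, which maps monotonically onto mean pairwise correlation (0 →
independent, 1 → identical traces). Noise is additive Gaussian on *raw*
fluorescence (baseline_f0 × (1 + dff) + ε); the whole noise matrix is
redrawn (up to 200 times, then clipped) if any frame falls to ≤ 0, keeping
ΔF/F_min defined. An optional `min_event_interval_s` deterministically
thins each ROI's train to a minimum gap, making "well-separated events" a
reproducible condition for exact-recovery tests rather than a seed hunt;
ground truth reflects only the kept events. Not emulated: photobleaching,
drift, neuropil contamination, motion artifacts — so passing recovery
tests says the *arithmetic* is right, not that real SNR regimes are easy.

**Spines.** Session-1 counts per shaft are Poisson (resampled to ≥ 1,
default mean 11 so most shafts pass the 8–15 filter), positions uniform;
each spine survives with `survival_prob`, survivors are jittered by
Gaussian `position_jitter_um` and clipped to the shaft; births arrive at
`birth_rate_per_um`. Coincident session-2 positions are nudged apart by
1e−5 μm to keep positions unique. Fate labels (stable / eliminated / new)
are exact by construction, which is what the binomial-recovery tests use.

**Trees.** Primary processes grow outward from the soma in random 3-D
directions, extending a few exponential-length segments per chain and
bifurcating with `branch_prob` up to `max_depth`; the soma contour is a
gently wobbled circle so soma areas vary across cells. Ground-truth total
length is the running sum of generated segment lengths and ground-truth
branch count the number of chains; both are checked exactly against the
morphometry stage.

**Study.** The three-group design derives per-animal seeds
deterministically from the master seed via `SeedSequence(master,
spawn_key=(group, animal, stream))`, so bundles are bit-reproducible. The
default group effects follow the qualitative directions reported for this
experimental system — alcohol lowers neuronal event amplitude/rate,
raises synchrony, lowers both spine formation and elimination, enlarges
astrocyte somas and arbors; exercise moves each parameter back toward the
saline setting — with magnitudes chosen as plausible mid-sized effects,
since the source reports no distributional parameters for its raw traces.

## Problem sizes and determinism

The default simulated study is 3 groups × 4 animals × 2 FOVs of 30 ROIs ×
600 frames (5 min at 2 Hz), ~500-spine recovery runs, and 500-replicate
null calibrations — sizes chosen so the whole suite and the acceptance
script each run in well under a minute of compute while keeping binomial
and calibration standard errors small enough for 3-SE assertions. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; two pipeline runs with the same config and
seed produce byte-identical output files, and that is asserted at file
level in the tests.

## Known limitations

- No spike inference, neuropil correction or bleaching detrending; the
  trace metrics are exactly the simple definitions above.
- Spine matching is positional only; a new spine arising at an eliminated
  spine's location is indistinguishable from survival.
- Sholl profiles depend on the centroid choice for strongly asymmetric
  contours; the mean-of-vertices centre is an option, not a truth.
- The statistics stage tests each endpoint marginally; no multiplicity
  control across endpoints and no repeated-measures modelling.
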