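# Methods

This note documents the models and procedures implemented in `wardsense`,
the parameters that matter, what the synthetic ward does and does not
emulate, and the numerical and design choices that were genuinely open.

## 1. Sensing model and cleaning

A badge advertises its id every `beacon_period` = 4 s; the receiving badge
logs *(sender, RSSI, Unix timestamp)*. RSSI is treated as a proximity proxy
through a log-distance path-loss model,

    RSSI(d) = P₁ − 10·n·log₁₀(d) + ε,   ε ~ N(0, σ²),

with defaults P₁ = −69 dBm at 1 m, n = 2.0, σ = 4 dBm, so the expected RSSI
at 2 m is −75 dBm. −75 dBm is therefore the cleaning threshold separating
conversational proximity from bystanders; records **strictly below** it are
removed (the threshold value itself survives — the inclusive/exclusive
choice at exactly −75 is underdetermined, we chose strict-below removal and
test it). Cleaning order is duplicate → weekend → out-of-hours → RSSI, each
removal attributed to the first rule that fires, so per-rule counts
partition the input; the day window is half-open [08:00, 20:00) in a single
configured time zone (all timestamps UTC internally — this makes
weekday/day-window logic unambiguous).

Badge **active time** on a day is the sum of consecutive same-badge battery
ping intervals. The raw sum is unbounded, which would count long off-body
gaps as wear time, so intervals are capped at `max_gap` = 450 s
(1.5 × battery period): one missed ping is tolerated, two are not.

## 2. Event reconstruction

Each detection contributes the interval [t, t + 4]; per-direction intervals
with gaps ≤ 75 s (inclusive) are merged — interpolation is a
sensing-dropout correction, so it acts on each badge's stream *before* the
two directions are combined, and once more after combining (whether the
bridge should act per direction or on the merged stream is underdetermined;
both are implemented, per-direction is the default). An interaction event
is the intersection of the two directional streams (mutual detection); a
union mode is provided because packet loss is asymmetric and one dead badge
otherwise erases a dyad.

Consequences to keep in mind: the minimum event duration is one beacon
period (4 s); endpoint resolution is one beacon period; ground-truth
contacts closer than the bridge gap fuse into one event.

Interaction durations enter all statistics as log₁₀ **minutes**. The unit
inside the logarithm is a free choice (it shifts every log-duration by a
constant, log₁₀ 60 ≈ 1.78, and shifts edge weights likewise); minutes make
the 10-min network cutoff map to weights > 1, keeping all edge weights
positive. The unit is configurable.

Per participant-day, *relative interaction time* = (length of the union of
the person's event intervals) / active time — simultaneous partners count
once toward clock time, while each event still counts separately for event
counts and mean log duration; role-split totals (with staff / with
patients) may therefore sum to more than the overall total. Relative time
is undefined (missing) when active time is 0; events without any battery
activity are kept but flagged inconsistent.

## 3. Daily networks and node metrics

Nodes are the badge-active participants of the day (isolates included). A
dyad receives an edge when its summed event duration strictly exceeds
10 min (`min_edge_minutes`, exposed as a parameter; results should be
checked for robustness to it), weighted w = log₁₀(minutes).

*Eigenvector centrality* is the unit-Euclidean-norm, nonnegative principal
eigenvector of the weighted adjacency; isolated nodes get 0; on
disconnected graphs the vector is supported on the component(s) attaining
the leading eigenvalue. Ward-sized graphs (≤ 64 nodes) use a dense
symmetric eigendecomposition — exact, and immune to the slow mixing of
power iteration when the spectral gap is small; larger graphs use power
iteration (tol 1e−10, ≤ 1000 iterations) with the dense route as fallback.

*Weighted clustering* follows the geometric-mean triangle intensity: with
weights normalised by the day's maximum (per-day, not per-study),
cᵢ = Σⱼₖ (ŵᵢⱼ ŵᵢₖ ŵⱼₖ)^⅓ / (degᵢ(degᵢ−1)) over ordered neighbour pairs,
cᵢ = 0 for degree < 2. This makes cᵢ ∈ [0, 1] and invariant to rescaling
all raw weights. An edgeless day yields all-zero metrics, not an error.
Both metrics are cross-checked in the test suite against independent
routes (dense eigendecomposition, exhaustive triple enumeration, and the
networkx implementations).

Staff are retained as nodes when computing patient metrics (the network a
patient integrates into includes staff); an `omit_staff` switch rebuilds
patient-only networks as a robustness variant.

## 4. Windows and mixed models

Daily metrics are averaged (unweighted, per-metric pairwise deletion) over
the 6 days preceding plus the day of each assessment. Each day with data is
used at most once: among assessments whose window contains the day, the
nearest date wins (a tie, impossible for two distinct future dates, would
go to the earlier one). Windows with no days contribute no row.

The ten models share the form yᵢⱼ = β₀ + β₁xⱼ + α₀ᵢ + εᵢⱼ with a random
intercept per participant, fitted by REML. Models 1–2 regress relative
interaction on self-report and time; 3–5 regress duration, centrality and
clustering on time; 6–10 regress PANSS total on relative interaction,
duration, centrality, clustering and self-report. "Time" is days since the
participant's first observation (origin and unit were open; a calendar
alternative is a flag). Time-varying predictors are group-mean centered, so
β₁ is the within-person slope. Person-constant covariates (the
olanzapine-equivalent doses at study start and end) would be annihilated by
group-mean centering and therefore enter grand-mean centered.

The REML fit exploits the compound-symmetry structure: with
λ = σ²_b/σ²_e, each group's covariance inverts by Sherman–Morrison,
collapsing the criterion to a 1-D profiled search over log λ. A boundary
solution (σ²_b → 0) is reported with a `singular` flag, never as an error,
and collapses to OLS.

The F-test of β₁ uses **Satterthwaite** denominator degrees of freedom via
the delta method: df = 2C²/(gᵀAg), where C is the contrast variance, g its
finite-difference gradient in the variance components, and A twice the
inverse finite-difference Hessian of the REML deviance — the same
construction as the reference R implementation, against which the test
suite checks F, df and p on a fixture. df is clamped to [1, n − p]; for
singular fits the classical OLS residual df is used.

**Cook's distances** are computed on the GLS-whitened fixed-effects
regression (one distance per observation); the threshold is 4/n by default
(the conventional cutoff — the screening method is prescribed but no cutoff
value is, so it is configurable), and both the original and the screened
fit of the focal model are always reported. Subscale models (positive /
negative / general) rerun the PANSS-model structure per subscale as a
directionality check, without multiplicity adjustment.

## 5. The synthetic ward

The generator emulates the study conditions of a 25-person open ward:
7 patients and 18 staff over 50 weekdays (ten working weeks), wear windows
08:00–20:00 on weekdays only, beacons every 4 s, battery pings every 5 min.
Contacts arise from two layers:

- **Scheduled events** (breakfast 08:30, lunch 12:30, team meeting 14:00,
  dinner 18:00, with attendance probabilities 0.7/0.8/0.5/0.6): attendees
  are seated at tables of ≤ 6 and each table renders as a clique contact
  for roughly the event duration. Seating is role-assortative (patients
  tend to share tables), which reproduces the observation that patients
  interact more with other patients than with the more numerous staff.
- **Background dyadic contacts** (≈ 14 per person-day, role-homophilous
  partner choice) with truncated-power-law durations, p(x) ∝ x^−α on
  [20 s, 10⁴ s], α = 1.7 by default. The empirical duration exponent of
  such data is not established; 1.7 sits in the range reported for
  face-to-face contact networks and is configurable. Durations are clipped
  at wear boundaries (clipped contacts are labelled, so the duration-law
  recovery check fits the unclipped ones).

Wear compliance is Bernoulli per person-day (0.8 patients, 0.5 staff,
matching the wear rates of the motivating study) with jittered pick-up and
return times (mean ≈ 10 h worn). Rendering adds per-badge beacon phase,
packet loss (10 %), Gaussian RSSI noise at the contact's distance
(uniform 0.5–2 m), and far-field sightings (2.5–8 m, ≈ 40/day) for the
RSSI filter to remove. Everything is deterministic given the seed.

**Assessments.** Weekly scores follow the mixed-model form
PANSS = γ₀ + Σ_f γ_f (x_f − ref_f) + b_i + ε, γ₀ = 45, σ_b = 8, σ_e = 4
(PANSS ≈ 45 ± 16, as in early-psychosis samples with moderate severity).
The reference values ref_f anchor γ₀ at the score of a typical resident.
Default slopes are γ = (−60, −20, 0, −40, 0) on relative time, log
duration, centrality, clustering and self-report: chosen once, before any
acceptance run, from a power argument — at the default design (7 patients
× ~10 assessments, within-person feature SDs ≈ 0.04/0.12/0.04/0.07) each
nonzero slope gives a noncentrality ≈ 4–5, i.e. power ≈ 0.99 at α = .05,
so the configured sign pattern is detectable while the nulls stay null.
The self-report items are neutral-heavy 7-point Likert draws whose link to
true interaction is a fidelity parameter, 0 by default (self-report as
pure noise, the empirical finding).

Because pipeline features are correlated within person (window-mean
centrality and relative time correlate ≈ 0.7 — attending lunch raises
both), a *structural* zero coefficient on centrality would not make the
*univariate* centrality model null: the relative-time effect leaks in. The
analysis models are univariate, so the meaningful "configured truth" is the
marginal slope, and `structural_from_marginal` converts marginal targets
into structural coefficients through the realised within-person feature
covariance (solve C a = diag(C) γ). The sign-pattern experiments configure
the generator this way; with uncorrelated features (the directly drawn
feature tables used in the calibration experiments) the two coincide.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: clock drift and time synchronisation, RSSI
multipath beyond Gaussian noise, non-stationary behaviour (no trends,
holidays, discharges or ward events), measurement reactivity, symptom
dynamics beyond the linear feature link (no autocorrelation in ε), and any
link between symptoms and subsequent behaviour (the causal arrow only runs
features → scores). Recovery and calibration results therefore demonstrate
the correctness of the measurement and inference machinery, not the
clinical validity of the metrics.

## 6. Problem sizes and determinism

The test suite and the acceptance script run the simulated study at the
default scale (≈ 5 × 10⁶ raw detections; ≈ 1 min on one CPU for the full
pipeline), 500 random graphs for the metric oracles, one controlled day of
16 contacts for reconstruction recovery, 200 replicates for slope recovery
and 500 for type-I calibration (20 participants × 10 assessments each),
and 50 replicates for the sign-pattern experiment. All randomness flows
from explicit seeds; identical config + seed reproduces byte-identical
logs and model tables.
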