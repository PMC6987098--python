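# Methods

This note documents the model implemented by `rhiexposure`, the default
parameter values and why they were chosen, what the synthetic generator
does and does not emulate, the numerical choices, and the known
limitations. It makes no empirical claim that is not computed by the test
suite or by `scripts/acceptance.py`.

## 1. Data model

An **impact log** is a per-game table of impact events with columns
`game_id, position, player, event_type, event_sublabel, head_location,
elevation_level, status, quarter, clock_remaining, velocity_mps,
pile_count` (CSV or JSON). Events carry one of three statuses:

- `confirmed` — the impact was directly observed on film; requires an event
  type and a head location.
- `suspected` — an impact probably occurred (for example the player
  disappears under bodies) but could not be confirmed; counted separately,
  never scored.
- `multiple` — a pile-up in which 2–6 impacts may have occurred; the
  possible count is recorded in `pile_count`, never scored.

Event types are `helmet`, `shoulder`, `hip_thigh`, `ground` (the four
*primary* striking surfaces) and `other` (requires a free-text sublabel
such as `knee` or `back`). Only confirmed primary impacts enter the
analysis set (`select_analysis_set`); everything else is retained for
bookkeeping. Game-clock stamps are `quarter` (1–4, 5 = overtime) plus
`MM:SS` time remaining; logs are kept chronologically sorted with a stable
sort, so same-stamp rows keep file order.

## 2. Kinematics

**Collision velocity.** Ground-plane markings with known field coordinates
calibrate each camera view through a planar homography fitted by the
normalized direct linear transform (≥ 4 non-collinear correspondences;
overdetermined sets are solved by SVD and the per-point geometric residual
is reported). Closing speed is the first-to-last field-plane displacement
of the tracked helmet divided by elapsed time; at least 3 frame samples
are required.

**Fall velocity.** When the head moves toward the ground the field plane
no longer contains the motion, so the horizontal component is estimated in
the image: per-frame helmet displacement minus the displacement of a
static reference marker (removing camera pan), scaled by a helmet-diameter
pixel scale. The vertical component is the finite-difference rate of
change of the head-to-ground distance. The resultant is their Euclidean
norm. An opt-in ballistic mode returns `sqrt(2 g h)` from drop height
alone for cases where tracking is impossible.

**Velocity levels.** Speeds are binned into five ordinal levels with
half-open bounds (closed on the left):

| level | collisions (m/s) | falls (m/s) |
|---|---|---|
| very low | [0, 2) | [0, 2) |
| low | [2, 4.5) | [2, 4) |
| moderate | [4.5, 7) | [4, 6) |
| high | [7, 9.5) | [6, 8) |
| very high | [9.5, ∞) | [8, ∞) |

The midrange of a bounded level (for example 3.25 m/s for a low-speed
collision) stands in for the level when a single representative speed is
needed and four or more measured speeds exist; with three or fewer the
mean of the measured speeds is used, and the open-ended top level always
uses the mean.

**Head location.** The head surface is coded as eight 45° azimuthal
sectors (eyes-forward = 0°) plus the crown. Left and right are collapsed
by mirroring azimuths above 180°, giving `front`, `front_boss`, `side`,
`rear_boss`, `rear`; sector boundaries assign rearward (a 22.5° impact is
`front_boss`). Crown impacts override the azimuth and carry no elevation;
all other locations carry an ordinal elevation level 1–5.

## 3. Strain mapping

Impact conditions are mapped to brain-tissue **maximum principal strain**
(MPS, %) through an exemplar table of reconstructed impacts. Lookup tries
the exact condition `(event, position, velocity level, head location)`
first, then falls back to the `(position, event)` mean, then to the
event-collapsed mean across positions; the fallback level and provenance
are recorded on the event so downstream users can audit coarse
assignments. The bundled default table carries the position-by-event mean
MPS values of the reconstruction study conditions; one cell (DB helmet) is
flagged `suspect` in its provenance because its source value is
typographically ambiguous, and the QB hip/thigh cell is absent (no
exemplar exists) and resolves through the event-collapsed fallback.

MPS values are binned into five ordinal **magnitude categories** with
half-open bounds and severity weights equal to the category ordinal:

| category | MPS (%) | severity weight |
|---|---|---|
| very low | [0, 8) | 1 |
| low | [8, 17) | 2 |
| moderate | [17, 26) | 3 |
| high | [26, 35) | 4 |
| very high | [35, 100] | 5 |

**Tissue model.** The strain interpretation rests on a linear viscoelastic
shear relaxation model `G(t) = G∞ + (G0 − G∞) e^(−βt)` with β = 80 s⁻¹,
bulk modulus 2.19 GPa and (G0, G∞) in kPa of (10, 2) for cerebellum and
grey matter, (22.5, 4.5) for brain stem and (12.5, 2.5) for white matter.
`shear_modulus` exposes this curve; the tests pin its anchors G(0) = G0
and G(∞) = G∞ and its monotone decay.

## 4. Real inter-impact intervals

Game clocks stop constantly, so clock time understates recovery time
between impacts. Each game's **stop-time factor** is its broadcast
duration divided by its clock duration (60 min regulation). A clock
interval is multiplied by the factor and then fixed paddings are added for
every period boundary crossed: +2 min between quarters within a half, +12
min at halftime, +5 min between regulation and overtime. The first impact
of a game is measured from kickoff (Q1, 15:00) by default; the `exclude`
alternative leaves it unscored. Real intervals are binned with half-open
bounds and *inverted* weights — shorter recovery is worse:

| category | interval (min) | weight |
|---|---|---|
| very low | [0, 15) | 4 |
| low | [15, 31) | 3 |
| moderate | [31, 91) | 2 |
| high | [91, ∞) | 1 |

## 5. The BSE/T index

For a position-game, each scored impact contributes
`severity_weight(magnitude) × weight(interval category)` and the index is
the sum divided by the number of scored impacts, so it is bounded in
[1, 20] by construction: 1 for exclusively very-low-strain impacts at long
intervals, 20 for exclusively very-high-strain impacts in rapid
succession. Two modes are provided:

- `per_impact` (default) — weights each impact's own interval category.
- `category_mean` — groups impacts by magnitude category and weights each
  group's *mean* interval; equivalent whenever a group's intervals share a
  category, coarser otherwise.

An empty analysis set leaves the index **undefined** (`None`), never zero:
zero would falsely read as "less than the mildest possible exposure".

Season aggregation multiplies per-game means by 16 games per season;
career projections multiply per-season estimates by average career length
in years, and per-game means by record career length in games.

## 6. Positional comparison statistics

- **Kruskal–Wallis** (tie-corrected, via `scipy.stats.kruskal`) as the
  omnibus test across positions, with per-group mean ranks reported.
- **Dunn's post-hoc test** on the pooled mean ranks with the tie-corrected
  standard error and Bonferroni adjustment over all k(k−1)/2 pairs.
  Implemented in-package (no maintained dependency provides it here) and
  validated against an exhaustive label-permutation oracle in the tests.
- **Contingency analysis**: Pearson chi-square without continuity
  correction plus per-cell *adjusted standardized residuals*
  `(O − E) / sqrt(E (1 − row/N)(1 − col/N))`, Bonferroni-corrected
  conservatively over all r×c cells. Zero-marginal rows/columns are
  dropped with a warning; 1×c tables are degenerate and return zero
  residuals.

p-values are displayed to three decimals with a `<0.001` floor.

## 7. Synthetic generator

The generator exists so the full pipeline can be exercised, benchmarked
and power-analyzed without film data. Its defaults are the study
conditions and are treated as fixed. Per position and game it emulates:

- **Counts**: negative-binomial per-game confirmed-impact counts matched
  to the published 32-game position means and SDs (Poisson when not
  overdispersed); suspected impacts and pile-ups as independent Poisson
  processes at the published per-game rates.
- **Timing**: impact clock times uniform over the 60 clock minutes (a
  homogeneous arrival process); stop-time factor drawn as
  `max(1, Normal(3.1, 0.15))` per game.
- **Composition**: event-type shares from the pooled documented
  distribution (helmet 0.49, shoulder 0.23, ground 0.13, hip/thigh 0.02,
  other 0.13); strain magnitude categories from position-specific mixes
  derived from the published per-game frequency-by-magnitude table, with
  MPS sampled uniformly within the drawn category (capped at the observed
  exemplar ceiling of 50.6%). An `exemplar` fidelity mode instead draws
  velocity levels and head locations and routes strain assignment through
  the exemplar table, exactly as observed data would flow.

It does **not** emulate: within-game clustering of impacts by play or
drive, between-player heterogeneity within a position, correlation between
impact magnitude and timing, opponent or score effects, weather, or season
phase. Frequencies and magnitude mixes are position-exchangeable and
game-independent.

All randomness flows from a single integer seed through numpy's
`SeedSequence.spawn` hierarchy (one child stream per game, then per
game-position), so a fixed seed yields byte-identical CSV exports.

## 8. Numerical choices

- All ordinal bins are half-open, closed on the left, so every boundary
  value has exactly one category; binning uses `bisect_right` over the
  shared edge tuples, which also makes monotonicity automatic.
- Homographies are fitted with Hartley normalization before the SVD; a
  calibration is rejected as degenerate when the second-smallest singular
  value falls below 1e-8 of the largest.
- Sample SDs use `ddof=1`; a single observation reports SD 0.
- Published-style display rounding (1 decimal for per-game/per-season
  rates, integer career estimates) happens only at the reporting layer;
  internal arithmetic is unrounded.
- Monte-Carlo tests compare the generator's output against *its own
  parameters* (for example DL 706/32 = 22.0625 per game), not against
  rounded display values, with fixed a-priori seeds and 2-standard-error
  tolerances derived from the samples themselves.

## 9. Parameter defaults

| parameter | default | rationale |
|---|---|---|
| games per season | 16 | regulation season length at the study conditions |
| reference sample | 32 games | size of the frequency reference underlying the bundled profiles |
| quarter length | 15 min | regulation |
| quarter-break padding | 2 min | typical between-quarter stoppage |
| halftime padding | 12 min | regulation halftime |
| overtime padding | 5 min | intermission before overtime |
| stop-factor draw | max(1, N(3.1, 0.15)) | broadcast-to-clock ratio of a typical broadcast; floored at 1 because real time cannot run faster than clock time |
| first impact | measured from kickoff | the pre-first-impact span is genuine recovery time; `exclude` provided for sensitivity analysis |
| BSE/T mode | `per_impact` | uses all interval information; `category_mean` provided for coarser reporting |
| alpha | 0.05 | conventional, Bonferroni-adjusted per family |
| MPS sampling ceiling | 50.6 % | top of the observed exemplar strain range |

## 10. Limitations

- Strain assignment is a table lookup of reconstructed exemplar means; it
  carries no per-impact uncertainty, and fallback assignments (position ×
  event, or event-collapsed) can be far coarser than the exact condition.
- Velocity estimation assumes the tracked motion lies in the calibrated
  ground plane (collisions) or that a static reference marker is visible
  (falls); projective distortion of out-of-plane motion is not corrected.
- The BSE/T index is ordinal-weighted and normalized per impact: it ranks
  exposure quality, and is deliberately insensitive to raw frequency,
  which must be reported alongside it (as `season_aggregate` does).
- Stop-time correction uses one global factor per game; actual stoppage is
  unevenly distributed across quarters.
- The generator's independence assumptions (Section 7) make it suitable
  for pipeline validation and power analysis, not for simulating
  individual player careers.
- Positions are treated as homogeneous groups; the data model has a player
  field but no per-player modeling is performed.
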