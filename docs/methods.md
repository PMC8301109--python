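# Methods

## The analysis chain

The pipeline turns a telemetry fix table (animal, sex, timestamp, planar
x/y in meters) into habitat-association statements in five stages.

**Step metrics.** Consecutive fixes of one animal give displacement,
linear speed (m/h), compass bearing (north 0°, clockwise) and turning
angle wrapped into (−180°, 180°], with an exact reversal mapping to +180°.
Steps spanning more than `max_gap` hours (default 3 h — twice the nominal
fix interval) cross unobserved periods and are excluded from speed
statistics. Angular speed is the turning angle divided by the later step's
duration; both the angle and the rate are carried so either convention can
be plotted.

**Snapshots and neighbor distances.** Fix times are rounded to a nominal
1 h grid; each animal contributes its temporally nearest fix within ±30 min
(half the minimum fix interval; the synchrony convention is configurable
because field protocols rarely state one). For each animal in a snapshot,
DAS/DSS/DDS are planar Euclidean nearest-neighbor distances (self excluded,
ties to the lowest id). Per animal and variable, missing fractions below
5% are imputed with the animal's mean; heavier missingness is left missing
and flagged, and such rows are dropped from training. Animals enter the
analysis only with enough records (defaults n ≥ 54 for females, n ≥ 80 for
males, mirroring the uneven retention typical of VHF campaigns).

**Co-occurrence.** Every unordered within-radius pair in a snapshot is one
event (dyads, not cliques; repeated co-occurrence across snapshots counts
each time, so frequencies are observation-weighted). The radius sweep runs
50–2000 m in 50 m steps; the working radius for incidence variables
defaults to 250 m. The stable-radius rule formalizes "the pattern persists
until r": it returns the largest radius whose set of nonzero
(month × pair-class) cells equals the smallest radius's set. This is a
deliberate surrogate for choosing the radius by inspecting sweep plots.

**Geo-SOM.** The map is a 9×6 rectangular lattice (Chebyshev lattice
distance; hexagonal available). The BMU search is two-phase: the
geo-winner minimizes the summed squared distance restricted to the
geographic variables (X, Y), then the BMU minimizes the full distance
among nodes within lattice distance k (default 3) of the geo-winner; k=0
pins the geo-winner and k at the grid diameter recovers the ordinary SOM.
Updates use the binary bubble neighborhood, `w ← w + η(x−w)` for nodes
within the current radius. Training runs a rough phase (200 iterations,
initial radius 4, η 0.2) then a fine phase (20 iterations, initial radius
10, η 0.1); within a phase the radius decays linearly to 1 and the rate to
a tenth of its initial value, and each iteration presents all samples in a
seeded-shuffled order. The fine phase's initial radius exceeding the rough
phase's is kept as the configured default; a monotone variant (fine radius
2) is provided as `MONOTONE_PHASES` and exercised in the tests. Inputs are
min-max normalized per variable; the normalizer is stored with the model.
Quantization error — the mean root distance of samples to their BMU — is
recorded per iteration as the convergence diagnostic.

Each training row is one (eligible animal × snapshot) with 19 variables:
position X, Y (geographic), water temperature WT, the 8 habitat indicators
(point-in-polygon; a boundary point counts as inside, and within a
vocabulary class the earliest patch in map order wins so indicators sum to
at most 1), the sex code SR, movement covariates LiS and AnS (nearest
retained step within the snapshot tolerance; missing values filled with
the animal's mean), the neighbor distances DAS/DSS/DDS, and the per-class
co-occurrence partner counts FM/FF/MM at the working radius,
log1p-compressed because counts are heavy-tailed and a single busy
snapshot would otherwise pin the min-max scaling. Three maps are trained:
females as targets, males as targets, and all animals pooled.

**Post-training analysis.** The codebook is clustered by best-of-20
k-means for k = 2..10, selecting k by the Davies–Bouldin index. Cluster
distance summaries report mean ± SD and n per (cluster × variable) with
samples assigned through their BMU, and the minimum- and maximum-distance
clusters are named by mean DDS. Group comparisons use pairwise Welch
t-tests with Holm correction — the literature this design follows names no
specific multiple-comparison method, and Welch+Holm is assumption-light
and conservative. Plane association replaces visual matching: the score is
the Spearman rank correlation of two component planes over nodes, the
polarity is "inverse" for negative scores, and a top-decile Jaccard
overlap localizes the match. The association table tallies, per pair class
and habitat, whether the score exceeds a threshold. Association rows come
from the per-target-sex maps (F-M and F-F from the females-as-targets map,
M-F and M-M from the males-as-targets map): on the pooled map the
geographic BMU search assigns different nodes to the two sexes at the same
location (the SR variable separates them), which structurally dilutes a
same-sex incidence plane against any habitat plane.

## The synthetic telemetry generator

No raw tracking data are deposited for this kind of campaign, so the
generator defines the study conditions: 24 animals (12 F, 12 M), 12 monthly
rounds of 3 consecutive days, fix intervals uniform in 1–2 h with ±10 min
per-animal timing jitter, per-animal fix retention uniform in [0.15, 0.50]
(dealt round-robin across the design roles so no subgroup is starved by the
luck of the draw), on a 6.9 km × 0.4 km site whose long axis points NE–SW.

Movement is a discrete-time two-state walk: resting (speed 0) or active
with lognormal speeds (log-mean 5.45, log-sd 0.85 m/h), persistence 0.8,
activity probability 0.45, von Mises forward-biased turning (κ=4), and
mirror reflection at the site boundary. Undirected animals drift back
toward a den center (home-range fidelity, blend weight 0.5/1.5); the den
spacing alternates sexes strictly along the axis and staggers them across
the width, so the only persistent neighbor contacts are different-sex
ones. The NE–SW anisotropy of observed bearings comes from the elongated
reflecting site, not from biased headings. The resulting marginal speed
distribution has mean ≈ 46 m/h and SD ≈ 80–95 m/h — within a quarter of
the field-reported 48.3 ± 96.2 m/h, the calibration target for these
defaults — with the heavy tail supplied by free-ranging movement and the
gathered animals' sorties.

The habitat map tiles the axis with near-equal vegetation strips in a
periodic mosaic — floating-leaved beds (FL) every fourth strip, tall
grassland (TG) between them, the drier covers (XHV, HHV, HWV) cycling
through the gaps, so every dry strip borders exactly one FL and one TG
strip and spill from a patch never loads onto a single competing label.
Land-cover patches (a crossing road, open areas, one structure) are
full-width slices anchored on the grassland side of dry host strips.

Planted associations are the recoverable ground truth. A rule sends
designated pairs of a class (F-M, F-F, M-M) to patches of a designated
habitat in designated months: the walk heading is blended with the bearing
to the target (weight s/(1+s), default s=5), travel is fast and capped at
the remaining distance, and arrival switches to short capped steps that
keep the animal inside the patch, with an occasional full-speed sortie
(probability 0.12 per active step) that the goal bias immediately pulls
back — the sorties carry the heavy upper tail of observed speeds. The
reference plan runs year-round: three solitary F-M pairs on the three TG
patches, and communal same-sex groups (eight females, eight males) on the
FL patches. Solitary different-sex pairs avoid planting wrong-class dyads;
communal same-sex groups multiply the intended-class dyad count
quadratically. Groups of one habitat claim distinct patches (so two
classes never co-locate) and rotate patches monthly so each class's
association covers the habitat map-wide. Dens are excluded within 250 m of
planted patches: a den wedged against a gathering patch would bridge its
owner's incidental contacts onto that patch's surroundings. Two animals
remain free-ranging background.

**What the generator does not emulate.** Real VHF campaigns have
positional error, diel activity cycles, seasonal home-range shifts,
demographic turnover, and habitat selection by all animals rather than a
scripted subset. Passing recovery tests on this generator shows the
analysis chain is faithful and sensitive — it does not show that real
nutria data would yield equally clean associations, and field-scale
cluster distance values (hundreds of meters to ~1.5 km) are not
reproduced because they depend on unavailable raw tracking data.

## Numerical conventions and degenerate inputs

- Ties (BMU, geo-winner, nearest neighbor) break to the lowest index/id.
- A constant component plane normalizes to 0.5 everywhere and is flagged
  undefined in association scoring.
- Training rejects inputs outside [0,1] beyond 1e-9; empty categories in a
  snapshot yield missing distances rather than errors; a fix outside the
  habitat map warns and gets all-zero indicators.
- All randomness flows from explicit integer seeds; identical
  (seed, config) reproduce byte-identical outputs, which the test suite
  asserts at the file level.

## Problem sizes

The shipped reference campaign yields ≈ 4,000 retained fixes, ≈ 700
snapshots and ≈ 4,400 training rows; one Geo-SOM training (220 epochs) and
the full pipeline complete in about half a minute and two minutes
respectively on one CPU. The end-to-end reproducibility check runs a
reduced campaign (8 animals, 6 rounds) twice; this choice only trades
sample size, not code paths.
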