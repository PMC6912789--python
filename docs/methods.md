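# Methods

## Data model and clock

An event log is a list of agonistic interactions, each with a pen, an
initiator, a receiver and — when the fight ended with clear submissive
behavior — a winner and loser drawn from the two participants. Indecisive
interactions are kept in the files with an explicit flag so exclusion rates
can be reported, but every analysis first drops them: indices and networks
are built from decisive events only.

Time is stored as *cumulative observed hours* since mixing. Pens are only
videotaped in daytime blocks (piglets: day 1 12:00–18:00, days 2–3
07:00–18:00, 28 h total; fatteners/gilts: the first two blocks, 17 h), and
every analysis is indexed by observed hours, so the unobserved gaps are
removed from the clock and wall-clock positions are derived on demand
(`obs_hour_to_wall_clock`). Events landing exactly on a block boundary
belong to the earlier block; windows advance in whole observed hours with
boundary events in the earlier window (`t_obs ≤ k`). Tied timestamps are
allowed and no analysis assumes strict ordering.

## Dominance indices

`DI1 = (wins − defeats)/(wins + defeats)` and
`DI2 = (wins·Pwon − defeats·Plost)/((wins + defeats)·(n − 1))`, where
`Pwon`/`Plost` count *distinct* pen mates beaten / lost to. A pen mate both
beaten and lost to contributes to both counts; the formula does not exclude
the overlap and the symmetric reading keeps the role-swap antisymmetry
(swapping every win with a defeat negates both indices) exactly testable.
Animals with no decisive fight have no index: missingness propagates as NaN
and is never coerced to 0 — an isolated animal has *zero* centrality but
*undefined* dominance, and downstream code (pairwise deletion in
correlations, per-parameter exclusion in rankings, complete-case PLS) keeps
the two semantics apart.

## Networks and centralities

Both network flavors are unweighted directed simple graphs on the full
roster: repeated fights of a dyad in the same direction collapse to one
edge, and never-fighting animals remain as isolated nodes. Conventions,
chosen to match the defaults of the standard network-analysis libraries of
the era and documented here as assumptions:

- standardized degree = raw degree / (n − 1);
- closeness uses the Wasserman–Faust correction for disconnected digraphs:
  for the ingoing direction of node v, with R the set of nodes that reach v
  and s the sum of their geodesic distances to v,
  `closeness = (|R|/s)·(|R|/(n−1))`, and 0 when R is empty; the outgoing
  variant runs on reversed edges;
- betweenness is directed shortest-path betweenness with fractional
  counting over all geodesics, endpoints excluded, normalized by
  `(n−1)(n−2)`, computed by Brandes' dependency accumulation.

All three are implemented directly on adjacency sets (BFS geodesics). The
test suite proves them equal to an independently coded brute-force oracle
(Floyd–Warshall distances plus explicit enumeration of all shortest paths)
on every labeled 3- and 4-node digraph and 1000 random digraphs with up to
7 nodes, to 1e−12, and cross-checks against networkx.

## Rising windows and correlation series

Every parameter is recomputed from scratch on each cumulative window
(1, …, T observed hours); window statistics are pure functions of the
window's event subset, so there is no incremental-update drift to control.
Spearman's rs (average ranks for ties, p from the t approximation with
n − 2 df, via `scipy.stats.spearmanr`) is computed per parameter pair per
window with pairwise deletion of missing values and flagged undefined below
3 complete pairs or for constant inputs. The default series pools animals
across pens within a window — group sizes inside an age group are similar
and all parameters are group-size-standardized — while a per-pen variant is
emitted alongside, since either pooling could be meant by a single
per-window correlation for an age group. Significance flags use unadjusted
two-sided p < 0.05; the multiplicity correction belongs to the
rank-difference contrasts only.

## Rank differences and contrasts

Parameters are mapped to a common [0, 1] scale — dominance indices by
(x+1)/2, the centralities are already normalized — because spacing
comparisons across parameters require a shared bounded range. Per pen and
parameter the standardized values are sorted descending and differences
between subsequent rank positions recorded up to a profile cutoff (8:9 for
piglet pens, 20:21 fattener, 18:19 gilt), ties yielding zero differences.
The telescoping identity (differences sum to max − min) holds exactly and
is asserted in the tests.

Whether a parameter spaces ranks differently from DI2 is tested with a
fixed-effects two-way least-squares model
`abs_diff ~ parameter + comparison + parameter:comparison` with pens as
replicates. The saturated fit's cell means and pooled residual variance
give each parameter-vs-DI2 contrast within each comparison level
(t statistic on the residual df); the whole contrast family is
Holm-adjusted. A mixed model with a pen random effect would be the
field-standard alternative; the fixed-effects version uses the same fixed
effects, is exactly reproducible without iterative variance estimation, and
the deviation is recorded in every output bundle's metadata.

## PLS structural equation model

Latent dominance D (indicators DI1, DI2) is regressed on latent centrality
constructs C_IR (IR out-degree, IR outgoing closeness, plus IR betweenness
for the larger-pen fattener/gilt specifications) and C_WL (WL out-degree,
WL outgoing closeness). Estimation is the classical PLS path algorithm,
written from scratch: indicators standardized with ddof = 1, outer weights
initialized to +1, inner proxies by the path-weighting scheme (predecessor
weights = multiple-regression coefficients, successor weights = score
correlations), Mode A weight updates (indicator–proxy correlations),
convergence when the unit-variance-scaled weights change by less than
1e−7 (maximum 300 iterations; non-convergence is flagged, not raised).
Sign indeterminacy is resolved by forcing each latent score to correlate
positively with its first listed indicator. Path coefficients and R² come
from OLS among the final scores; standardized paths may exceed 1 in
magnitude under collinear exogenous constructs and are deliberately never
clamped (a regression test constructs such a case).

Observations are animals pooled across pens within an age group,
complete cases only (isolated animals have no dominance index; the dropped
count is available from the fit). Bootstrap inference resamples animals
with replacement (default 5000 replicates, minimum 500), refits, aligns
each replicate's latent signs with the original fit via the dot product of
block loadings, and reports SE = replicate standard deviation and two-sided
p from t = estimate/SE with n − 1 df. Measured on null simulations this is
slightly conservative (bootstrap SE ≈ 9% above the sampling SD at n = 200).
Quality gates follow the usual reflective-measurement thresholds:
indicator reliability > 0.7, composite reliability 0.6–0.9 (exploratory
range; higher values are flagged as redundancy, not passed silently),
AVE > 0.5, and R² verbal bands at 0.25/0.50/0.75.

## Synthetic data generator

The generator emulates a mixing event with a known ground truth so that
recovery is checkable end to end:

- latent dominance `theta_i ~ N(0,1)` per animal;
- event times from a non-homogeneous Poisson process with intensity
  `λ0·exp(−t/decay_tau)` on observed hours, `λ0` calibrated so expected
  events per pen equal `n·events_per_animal_target/2` (each event counts as
  a participation for two animals, so participations per animal hit the
  target — the convention in which the field reports "interactions per
  animal");
- initiator drawn with probability ∝ `exp(alpha·theta_i)`; receiver uniform
  among the rest (a theta-biased receiver option exists but defaults off so
  in-degree carries rank information only through outcomes);
- the initiator wins with probability
  `logistic(beta·(theta_init − theta_recv) + delta)` — a Bradley–Terry
  contest with an initiator advantage; with probability `p_indecisive`
  (default 0.1; the true exclusion rate is not reported for this kind of
  data) the fight is indecisive.

Age-group presets fix the study conditions: piglet (93 pens, sizes 6–11
around 8.9, 28 h, target 18.4 participations/animal), fattener (26 pens,
17–25 around 20.9, 17 h, 5.9), gilt (12 pens, 16–27 around 20.8, 17 h,
5.3). Remaining defaults were chosen once: `decay_tau = 3 h` reproduces a
clear drop in fighting within the first ~6 observed hours; `beta = 2`
gives strong but noisy outcome discrimination so that rank recovery is
good yet imperfect; `alpha = 0.5` and `delta = 0.2` jointly put the
initiator-win proportion in the low 0.60s, the range observed in newly
mixed pens. Per-pen RNG streams spawn deterministically from the master
seed, so identical configurations produce byte-identical files.

What the generator does *not* emulate: dyadic persistence (real early
aggression concentrates on few repeat-fighting dyads, so real pens start
with a much larger fraction of still-isolated animals — around half or
more in the first observed hour — than the generator, whose uniform
receiver choice spreads participation quickly); familiarity structure,
body-weight/sex covariates and pen geometry are likewise absent, and the
latent order is static where real hierarchies may drift. Passing tests
therefore demonstrate that the pipeline recovers structure correctly under
a plausible contest model, not that real pig data will show the same
effect sizes.

## Problem sizes in the test suite

The simulation-property tests run the full piglet design (93 pens) over 20
seeds; PLS parameter recovery uses 50 seeds at n = 500 and the null
calibration 20 seeds at n = 200 with 500 bootstrap replicates; oracle
equivalence sweeps all 3–4-node digraphs exhaustively plus 1000 random
digraphs up to 7 nodes. These sizes make the whole suite run in a few
minutes while keeping every Monte-Carlo margin wide.

## Known limitations

- The fixed-effects contrast model ignores pen-level correlation between
  comparisons; with many pens the practical difference from a mixed model
  is small, but singleton-pen designs are rejected rather than guessed at.
- Closeness/betweenness normalization conventions are assumptions (library
  defaults of the field), not published choices.
- The pooled correlation series treats animals from different pens as
  exchangeable after standardization; the per-pen series is provided for
  designs where that is unacceptable.
- PLS Mode A estimates are attenuation-biased toward zero at low indicator
  reliability; the recovery guarantees quoted in the tests hold for the
  high-reliability regime the dominance/centrality indicators actually
  occupy.
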