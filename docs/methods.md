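# Model and methods

`telosen` simulates the proliferation of telomerase-negative budding-yeast
cells from telomerase inactivation (generation 0) to replicative
senescence, at two scales: single tracked lineages, as observed in a
microfluidics "mother machine", and competing populations grown under a
daily saturation–dilution protocol.  This note documents the model, its
parameters, the synthetic stand-ins used for inputs that are not published
in closed form, and the numerical choices the implementation makes.

## Cell state and telomere shortening

Each haploid cell carries 32 telomeres (2 ends x 16 chromosomes), stored
as a 2x16 integer matrix of lengths in bp.  At every division, for each
chromosome independently, exactly one of the two telomeres is shortened by
the replication overhang `h` (default 7 bp) with equiprobability; the end
shortened in one daughter is the end left intact in the other, so the two
daughters are coupled complementarily.  Consequences used as test oracles:

* each daughter loses exactly `h` bp per chromosome (pre-clamping);
* a fixed telomere loses `h/2` bp per division in expectation;
* every length is non-increasing along a lineage, and lengths clamp at 0
  (a telomere cannot carry negative repeats).

## Arrest laws and the per-division fate kernel

A daughter's fate depends on its mother's state and on its own shortest
telomere `l`, measured after shortening.  The three length-dependent laws
share one form, `p(l) = min(1, b e^{-a l})` for `l > l_min` and `p = 1`
at or below the hard threshold:

| law | a | b | l_min | role |
| --- | --- | --- | --- | --- |
| p_nta | 0.02 | 0.44 | — | first/non-terminal arrest onset (cell becomes type B) |
| p_sen,A | 0.19 | 0.73 | 27 bp | terminal senescence of type-A cells (near-deterministic threshold) |
| p_sen,B | 0 | 0.12 | 0 bp | terminal senescence of type-B cells (length-independent) |

Constant rates: accidental, telomere-independent death `p_accident` =
0.43% per division; exit of an nta sequence by repair/adaptation
`p_repair` = 0.65 per long cycle; death ending a senescent sequence
`p_death` = 0.58 per senescent cycle.  Both sequence lengths are therefore
geometric (means 1/0.65 and 1/0.58), which the tests verify by Monte
Carlo.

Events are resolved in a fixed order per daughter: accident → inherited
senescence (with the per-cycle death draw, applied to each daughter
independently) → inherited nta (repair or continue) → senescence onset →
nta onset.  Senescence is absorbing.  Two consequences of this ordering
are worth making explicit:

* an ongoing nta sequence exits only by repair (or accident); a cell
  cannot slip from an nta cycle directly into senescence.  This is the
  reading under which the arrest-sequence lengths are exactly geometric;
  hidden type-B cells (type "M": ground-truth B, observationally A)
  arise when an arrest sequence ends in accidental death before any
  recovery is seen.  Their frequency is small, consistent with the
  reported marginal impact of type M;
* the threshold branch `p = 1` for `l <= l_min` fires at `l = 0` even
  when `l_min = 0`, so a telomere-free end always triggers senescence in
  a normally cycling cell.  "Immortal-control" parameter sets used in
  tests therefore also set `h = 0` so lengths never reach the clamp.

## Initial telomere lengths

Initial lengths are i.i.d. draws from a transformed base distribution.
The true base — the telomerase-positive equilibrium distribution — is not
available in closed form; the default stand-in is a triangular density on
`[l_inf, l_mode, l_sup] = [100, 300, 500]` bp, sampled by inverse CDF.  A
plain-text sample file (one bp per line) can replace it.  The transform
dilates the left flank `[l_inf, l_mode]` onto `[l_inf + l_0, l_mode]` and
the right flank `[l_mode, l_sup]` onto `[l_mode, l_mode + l_1]` (the mode
is a fixed point), then adds the signed translation `l_trans`, rounds
half-up to integer bp and clamps at 0.  With the best-fit dilations
`(l_0, l_1) = (40, 58)` the default support becomes `[140, 358]` bp.

The triangular stand-in matters: its left tail is thinner and starts
higher than the (unpublished) equilibrium distribution's.  Quantities tied
to *when* the shortest telomere crosses a threshold are robust to this
(the type-A onset signature sits at the 27-bp threshold regardless), but
quantities tied to *where in length-space* type-B conversions happen are
not — with a left tail starting at 140 bp, first arrests occur over a
broader, higher range of lengths, which shifts the upper tail of type-B
onset lengths upward relative to a base distribution with a longer left
tail.  Passing population tests therefore validate the machinery and the
threshold signatures, not the exact shape of type-B onset-length
distributions in real cells.

## Cell-cycle durations

Durations are resampled uniformly from four empirical subdatasets keyed by
(type, cycle): normal cycles of type-A cells, normal cycles of type-B
cells, nta cycles, senescent cycles (arrest banks pooled across types).
The threshold `D` = 180 min partitions the banks: normal < D <= arrest.
The synthetic stand-in bank (500 values per category) uses log-normal
shapes: normal cycles with median ~88–92 min (mean ≈ 90 min, the wild-type
division time), clipped to [60, 179] min; arrest cycles D plus a
heavy-tailed log-normal excess (medians 60 and 120 min for nta and
senescent cycles), clipped at 1000 min.  These shape parameters are
configuration, not constants, and are echoed into every run's resolved
configuration and fixture manifests.  What the stand-in does not emulate:
measurement noise, mother/daughter cycle-time asymmetry, and day-scale
drifts of the microfluidics device.

## Lineage simulation and classification

A lineage tracks one cell: at each division one daughter is kept with
equiprobability.  The founder is type A, cycling normally, and completes
one cycle before its first division, so fates are first evaluated on
generation-1 daughters.  Classification uses durations only, mirroring
the experimental read-out: a cycle is long iff >= D, and a lineage is
observed type B iff some long cycle is later followed by a normal one.
Arrest-generation curves (first nta; first senescent cycle among
observed-A, observed-B, and all lineages) are ascending sorted lists, the
x-axis being lineage rank.

## Population simulation

All `N_init` founders start as type A with i.i.d. telomeres.  Cells divide
in continuous time (division at birth time + cycle duration; both
daughters kept, each with independent fates and durations).  When the
living count reaches `N_sat = r_sat * N_init` the culture freezes: pending
divisions are deferred with their remaining cycle time intact and resume
after the next dilution.  Every 24 h the population is diluted to `N_dil`
(= `N_init`) cells sampled uniformly without replacement; the end-of-day
count is read at the dilution instant, pre-dilution.  Dead cells are
removed immediately.

The event queue is processed in sub-windows no wider than the shortest
bank duration: every daughter born inside a window divides strictly after
it, so each window is one vectorized batch processed in time order (the
ordering decides which divisions land before the saturation cut).
Boundary events belong to the window they end.  Snapshots are taken at
least hourly: counts, type/cycle composition, telomere mean and mode
(mode = most frequent integer bp over all telomeres of all cells, ties
broken toward the smaller length), per-cell shortest-telomere statistics,
generation mean/variance, and ancestry-decile shares (founders ranked
once, at t = 0, by their shortest telomere).  Senescence onsets are logged
per event with the cell's ground-truth type and shortest length.

The senescence-rate summary is the half-saturation-limit time (HSL): the
time at which the end-of-day count first falls to `N_sat / 2`, linearly
interpolated between the last day at or above half-saturation and the
first day below.  If the counts never fall below half within the horizon
the HSL is right-censored (reported as infinite); if the first measured
day is already below, the crossing was not observed and the extinction
time (if any) or the first measurement time is reported.

Default protocol: `N_init` = 300 (the published minimal unbiased size) or
1000, `r_sat` = 1000 (~10 population doublings to saturation; 720 matches
the OD-calibrated experimental protocol), 10 days.  For display against
OD600 measurements, counts map linearly with OD 0.0125 ↔ 3.75e5 cells/ml.

## Perturbation scans

Scans vary one knob of the initial distribution (global translation
`l_trans`; left-flank dilation `l_0`) or the constant mortality
(multipliers of `p_accident`), with paired seeds: every condition of
replicate *i* reuses bit-identical RNG streams, so per-replicate HSL
differences against the control isolate the parameter effect (common
random numbers); the paired differences are then averaged.  The 20x
mortality condition (`p_accident` = 8.6%) still saturates during the first
days — the net growth factor per division is 2 x (1 − 0.086) ≈ 1.83 — so
its effect is reported as the HSL *anticipation* (control HSL minus
perturbed HSL), which is about one day.  The rad51-deletion scenario sets
`p_accident` = 5.4% and simulates 1000 virtual microfluidics experiments
of 11 lineages each.

## Calibration

Ten parameters are free: the three law coefficient pairs, both hard
thresholds, and the two dilations `(l_0, l_1)`.  A candidate is scored by
simulating lineage batches and comparing arrest-generation curves with
the targets: each sorted curve is quantile-matched onto a common 21-point
rank grid, squared differences are averaged per category and summed, and
a squared penalty (weight 200) on the observed type-B proportion is
added; an empty simulated category against a non-empty target is
penalized by the target's own squared quantiles.  The cost callable is
pluggable so an alternative published formula can be dropped in.

Minimization uses CMA-ES (an in-package, standard (mu/mu_w, lambda)
implementation with cumulative step-size adaptation and rank-one plus
rank-mu covariance updates; box constraints by clipping).  Candidate
evaluations reuse a fixed set of simulation seeds (common random
numbers), which makes the objective deterministic and the whole fit
reproducible bit-for-bit from its seed.  Because finite-sample curves
make the landscape rugged and the steep-exponential/hard-threshold
parameterizations nearly degenerate, the default search bounds stop the
decay rates at 0.3/bp (steeper laws are indistinguishable from the
threshold) and the fit is staged:

1. a reduced six-parameter fit (the nta and sen-A coefficient pairs, the
   type-A threshold, and the type-B rate) with the type-B channel held at
   its parsimonious null — length-independent hazard, `a_sen_B = 0`,
   `l_min_B = 0`, rate initialized at the inverse of the median gap
   between first arrest and senescence in the targets, a standard
   initialization for hazard models — and the dilations pinned at the
   configured baseline distribution.  This low-dimensional problem is
   optimized with restarts at base fidelity;
2. the reduced fit is polished at higher fidelity (4x the lineages,
   fresh seeds): with the dilations pinned there is no
   threshold/dilation trade-off, so this stage is what actually pins the
   type-A threshold;
3. all ten parameters are then released from that anchor, and the
   released solution is accepted only if it improves the cost by more
   than the measured seed-to-seed noise — otherwise the anchored
   solution is kept.  Without this significance gate the release stage
   walks along near-degenerate directions by noise-fitting alone.

Thresholds are optimized on a continuous scale and rounded to integer bp
at the end.

The gate exists because of a structural caveat, measured directly on the
cost surface: the type-A threshold `l_min_A` trades off against the left
dilation `l_0` — lowering the threshold while compressing the left flank
leaves the observable generation curves nearly invariant (both only move
*when* the shortest telomere crosses the threshold).  The degeneracy is
softened, not broken, by the mode-anchored (non-uniform) dilation, so
even the staged fit recovers `l_min_A` only to within the ridge's shallow
curvature (about +-10 bp at high simulation fidelity, weaker on the
upper side); across recovery runs most, but not all, seeds land within
+-5 bp of the generating threshold.

## Problem sizes and defaults used by the shipped checks

The package's own test suite and the results-reproduction script use
desk-scale sizes chosen to keep full runs in the minutes range: 1000
lineages per virtual microfluidics experiment; population runs at
`N_init` = 300–1000 with `r_sat` = 1000; scans with 3–10 paired
replicates; calibration recovery against targets of 2000 lineages with a
3000-evaluation budget, 200 lineages and 2 common-random-number repeats
per evaluation.  Envelope widths shrink with more replicates; the means
reported are stable at these sizes.

## Known limitations

* Post-senescence survivor emergence and telomere re-lengthening are out
  of scope; simulated and experimental cultures are expected to diverge
  once survivors matter (after day ~4–5).
* The base initial-length distribution is a parametric stand-in (see
  above); all population-level numbers inherit its left-tail shape.
* Chromosome-end-specific thresholds, checkpoint mechanics, and nutrient
  dynamics (saturation is a hard cap) are not modeled.
* The published calibration cost formula is not reproduced; calibration
  quality is assessed by parameter recovery on synthetic targets.
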