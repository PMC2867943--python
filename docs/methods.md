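# Methods

## The model

`sepalsim` simulates the emergence of the cell-size pattern of the
*Arabidopsis thaliana* sepal abaxial (outer) epidermis from a single rule:
cell size is set by *when* a cell stops dividing and switches to
endoreduplication (endocycles — DNA replication without mitosis). All
cells grow exponentially in area at the same rate, so a cell that commits
to endocycling early keeps growing without dividing and becomes a large,
high-ploidy cell (up to a 16C "giant cell"), while cells that keep
dividing stay small and diploid.

The simulated tissue is an intercalary-growth abstraction:

* A **generative layer** of `generative_width` (default 8) basal cells —
  a stand-in for the proliferative zone at the sepal base — repeatedly
  divides transversely, emitting one apical daughter per division and
  retaining one basal generative cell per column.
* Each apical daughter founds a **patterning lineage** with exactly three
  patterning cell cycles. At the end of cycle k ∈ {1,2,3} a 2C cell
  irreversibly enters the endocycle with probability p_k, else divides.
  An endocycling cell doubles its ploidy at the end of every remaining
  cycle and terminates after the third, so commitment at cycle 1/2/3
  yields a terminal 16C/8C/4C cell. Cells that divide at the end of
  cycle 3 produce terminal 2C daughters.
* Each terminal 2C daughter undergoes an extra **stomatal-lineage
  division** with probability `p_s`, for at most `stomatal_max_rounds`
  rounds (default 1). A cell that declines terminates immediately; one
  that accepts runs one more cycle, divides, and its daughters decide
  again while rounds remain. Guard-cell geometry and identity are not
  modeled — the rounds exist only to contribute the extra small cells
  that stomatal divisions add to the size distribution.
* Cells are axis-aligned rectangles (`area = length × width`). Growth is
  isotropic and exponential: one areal doubling per `doubling_time_hours`
  (default: the mean cycle time), i.e. `area ← area · 2^(dt/T_d)`.
  Dividing cells may split transversely (across the apical–basal length)
  or longitudinally (across the width); the plane chosen minimizes
  `|log r − log 2|`, where r is the even-split daughters' length:width
  aspect ratio — daughters as close as possible to 2:1. The log metric is
  symmetric between too-slender and too-squat daughters; exact ties
  (e.g. a square cell) are resolved by a fair RNG draw.
* Terminated cells stop growing; their recorded area is the area at
  termination.

Two empirically motivated noise sources act on the patterning lineages:

* **Cycle-time variability.** Each cell's cycle duration is drawn from a
  configurable distribution (default lognormal, mean 24 h, SD 9 h,
  moment-matched). Longer cycles mean more growth before the next
  decision, spreading each ploidy class's sizes around its mean. An
  empirical 6-h-binned histogram (the form live-imaging data takes) or a
  gamma family can be supplied instead, with optional round-up
  quantization to the imaging resolution.
* **Division asymmetry.** The split fraction s of the parent's area given
  to the first daughter is Normal(0.5, `split_sd`) truncated to
  [`split_min`, `split_max`] (defaults 0.05 and [0.3, 0.7]). The relative
  daughter-area deviation 2s−1 then has SD 2·`split_sd` = 10%, the level
  the simulator is parameterized to reproduce (the in-vivo measurement is
  8.5%; use `split_sd=0.0425` for that regime).

With `noise_free=True` (and `sd_hours=0`) both sources vanish and the
model collapses to its deterministic limit: terminal areas take exactly
four values in ratios 1:2:4:8 for ploidies 2C:4C:8C:16C — the
karyoplasmic proportionality the decision model predicts. This also holds
including stomatal daughters: a stomatal division doubles then halves,
landing back on the 2C size.

### Generative-layer dynamics (a deliberate design choice)

Generative cells cycle at exactly the areal doubling time and split
evenly, so every apical founder is born at the same area and the terminal
size distribution is stationary over the run. Had generative cells
sampled noisy cycle times like patterning cells, their birth areas would
perform a zero-drift multiplicative random walk (SD ≈ 0.375 doublings per
generation at the default distribution), making the output distribution
drift between seeds: replicate runs of the same configuration would be
statistically distinguishable, which contradicts both the layer's role as
a steady proliferative zone and the observed stability of sepal size
distributions. The measured noise sources (cycle-time spread, 10% split
SD) were measured on patterning-region cells, and that is where the model
applies them.

### Scheduler and reproducibility

A fixed-step scheduler (`dt_hours`, default 0.5 h; validated to be at
most a quarter of the mean cycle) processes cells in ascending `cell_id`.
Within a step, a cell is grown exactly to its cycle-completion time
before the completion event fires, so per-cycle area doublings are exact
and `cycle_elapsed` never exceeds `cycle_duration`; daughters created
mid-step are advanced through the remainder of the step immediately. One
`numpy.random.Generator` (PCG64) stream is consumed in a documented
order: per completed cycle, one uniform for the fate decision (always
exactly one, whatever the branch), then any plane-choice/split draws,
then the daughters' cycle durations, first daughter first. Identical
seed and configuration give byte-identical output tables.

A run steps until the number of non-generative cells (terminated plus
in-progress) reaches `target_cells` (default 1,600, the approximate
abaxial epidermal cell count of a mature wild-type sepal); generative
divisions then cease — the check is applied per generative completion,
so the target is not overshot by a whole synchronous wave — and all
in-progress lineages run to termination. A generous time cap guards
against non-terminating configurations.

## The branching (population) model and fitter

Per founder, the expected terminal counts are

    n16 = p1, n8 = 2(1−p1)p2, n4 = 4(1−p1)(1−p2)p3,
    n2 = 8(1−p1)(1−p2)(1−p3)·m(rounds),   m(r) = (1−p_s) + 2·p_s·m(r−1)

normalized to expected fractions. The closed form is validated in the
test suite against a brute-force enumeration of the full decision tree
(every fate assignment with its probability) to 1e-12, and against
Monte-Carlo runs at n ≥ 10,000 within 3 binomial standard errors. Note
m(1) = 1+p_s; deeper rounds grow sub-geometrically because a cell that
declines its stomatal division terminates rather than re-deciding.

`fit_probabilities` inverts the map by bounded least squares on fractions
(multi-start over a coarse [0,1]^k grid; tolerances 1e-15), with a
multinomial maximum-likelihood objective available behind
`method="multinomial"`. Partial observations are supported and are the
recommended use: flow cytometry pins down the 16C and 8C fractions, but
the observed 4C pool mixes endoreduplicated cells with mitotic G2 cells,
so fits on f4/f2 conflate the two. The wild-type preset therefore fits
(p1, p2) to the measured 16C = 1.0% and 8C = 5.5% epidermal fractions
with p3 = 0.8 and p_s = 0.3 held fixed. Those two fixed values are
package defaults, not measurements — p3 high because endocycle entry
rises steeply across the cycles, p_s moderate for the stomatal
contribution — and the fitted configuration reproduces the two printed
fractions exactly regardless of their choice (they reallocate probability
only between the unconstrained 2C and 4C classes). `bootstrap_fit`
resamples multinomial counts at a given nucleus count (the pooled
experiment counted 31,744) and refits for percentile intervals.

Scenario presets: `wildtype` as above; `lgo` (loss of the LGO/SMR1 cyclin
inhibitor) sets p1 = 0 — no first-cycle commitment, hence zero 16C giant
cells — with a 0.8× mean cycle time; `krp1` (epidermal KRP1
overexpression) sets p1 = 0.5 with a 1.25× mean cycle time. The cycle
scale factors are package defaults standing in for reported qualitative
shifts (shorter/longer than wild type), overridable per run. Mutant
scenarios keep the areal doubling time pinned at the wild-type mean
cycle: the growth rate is a tissue property, and holding it fixed is what
makes longer cycles shift the size distribution upward.

## Lineage statistics

Lineage tables are long-format records (cell, parent, time, area, fate)
on a fixed 6-h grid, the shape of tracked live-imaging data. Cycle
durations are estimated per divided cell as observation span + one bin
(unbiased when birth phases are uniform over the grid). Cells born near
the window end are observed to divide only if their cycle was short, so
the naive mean is length-biased low (≈ −2.5 h for a 96-h window at the
default distribution); `max_first_time_h` restricts the estimate to cells
first seen several mean cycles before the window closes, recovering the
true mean within ±1.5 h at n ≥ 500. Division asymmetry is the SD of
2·a1/(a1+a2) − 1 over daughters' first observed areas — both daughters
are first seen at the same timepoint, so shared growth cancels and the
estimate recovers 2·`split_sd` exactly in expectation. Distribution
comparisons use the two-sample Kolmogorov–Smirnov test on log2 areas,
this package's reconstruction of an unspecified original test.

The synthetic lineage generator grows a few progenitor cells (default 6,
initial areas lognormal around 100 area units) through sampled cycles and
truncated-normal splits, records areas on the grid, and censors at the
window end; a configurable fraction of cells can be endoreduplicating
(never dividing). It emulates the *structure* of tracked data, not its
biology: no cell neighborhoods, no guard-cell program, no segmentation
error, and cycles shorter than the sampling interval are clipped to it
(below 0.02% of draws at the defaults). Passing recovery tests on these
fixtures validates the estimators, not the realism of real imaging data.

## Distinct-size counting

Areas are sorted and split into clusters wherever the relative gap
exceeds 1e-6; the count is reported for noise-free runs (where classes
are exact up to float rounding) and is not meaningful for noisy runs,
where the CLI omits it unless asked.

## Problem sizes and numerical choices

The default study configuration is 8 generative columns, 1,600 target
cells, 24 ± 9 h lognormal cycles, 0.5-h steps, and initial area 100
(area units are arbitrary; the model makes no claim about absolute
areas, only ratios and distribution shapes). Replicate experiments in
the tests use 30 seeded runs; the acceptance script uses 400 to shrink
the Monte-Carlo standard error of the rare 16C fraction (per-run SD
≈ 0.23 percentage points → SE of the mean ≈ 0.012). The KS
self-consistency property is exercised at 20 replicate pairs (≥17
required with p > 0.01, matching the 95% rate measured over 100 pairs).
Fit tolerances are 1e-6 on round-trips; area conservation at division is
exact to 1e-9 relative; ties in the plane metric are declared below a
1e-12 absolute difference.

## Known limitations

* No tissue mechanics, curvature, or neighbor interactions: `column` and
  stacking order are bookkeeping only, and the spatial arrangement
  (e.g. clustering of giant cells) carries no information.
* Generative cells cycle deterministically (see above); the model of the
  proliferative base is deliberately minimal and its width never changes.
* Stomatal lineages are area-bookkeeping only; guard cells, meristemoids
  and their asymmetric-division geometry are absent.
* Absolute areas are not calibrated to µm²; comparisons to measured area
  distributions are meaningful on log-ratio scales only.
* The rare in-vivo division of an endoreduplicating cell is excluded:
  commitment is strictly irreversible here.
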