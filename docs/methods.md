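# Methods

## Model

The simulator is a discrete-time, discrete-space, agent-based range
expansion. The atomic unit is the tribe (~300 people, one language); cells
are 50 km squares holding 0–10 tribes; only the central cell is occupied at
the start. Within each generation the order of operations is: synchronous
dispersal of all cells computed from the pre-step state, then reproduction
cell by cell, then (on generations divisible by the loss time L) the
phoneme-loss sweep. Languages are presence bit-vectors; loss clears one
uniformly chosen set bit per affected tribe, independently per tribe, so
tribes sharing a language diverge after a sweep. Languages never gain
phonemes, and an empty language is a fixed point (loss on it is a no-op):
the model has no extinction or innovation rules.

### Parameters

| parameter | symbol | default | units | origin |
|---|---|---|---|---|
| node spacing | d | 50 | km | ethnographic dispersal distance per generation |
| generation time | T | 32 | y | pre-industrial parent–child age gap |
| persistence | p_e | 0.38 | – | fraction of tribes not dispersing |
| net fecundity | R0 | 1.4 | per generation | e^{aT} with growth a = 0.01/y |
| carrying capacity | N_s | 10 | tribes/cell | 1.2 people/km² ÷ 300 people/tribe × 2,500 km² |
| loss threshold | N_thr | 10 | tribes/cell | cells below it lose phonemes |
| phonemic loss time | L | 80 | generations/phoneme | calibrated; 60–120 matches the observed count cline |
| master inventory | nph | 908 | phonemes | distinct phonemes across the reference database |

R0 = 1.2 is used for the two-language diversity (t_F) experiment; the t_F
cline is well behaved only for 1.1 < R0 < 1.4 (higher R0 saturates the
front too quickly for loss to act; at R0 ≤ 1.1 the integer demography
degenerates — see below).

### Dispersal rule

Per cell with N tribes and k available neighbours (4 interior, 3 edge, 2
corner), nearest-int(N·p_e) randomly chosen tribes stay; the movers — at
most N − stay, and at most k·q with the per-neighbour quota
q = nearest-int(N·(1−p_e)/k) — are dealt round-robin over the neighbours in
random order. For a saturated interior cell this yields the canonical
4-stay/6-move split with every neighbour receiving at least one tribe. The
quota matters at low density: cells with N ≤ 3 (at p_e = 0.38) have q = 0
and do not emigrate. Without that retention the founding population
fragments into single-tribe cells which, under nearest-integer growth
(nearest-int(N·R0) = N for N ≤ 2 at R0 = 1.2), can never grow, and the
colonization wave freezes at low fecundity; with it, waves at R0 = 1.2 are
possible. Dispersal conserves the total tribe count exactly. Rounding is
half-away-from-zero throughout (3.8 → 4, 2.5 → 3).

Even so, integer-tribe demography at R0 = 1.2 retains a substantial
probability (roughly half to two-thirds of seeds) that the founding
population fragments before a coherent wave forms and the expansion stalls.
Stalled runs are detected (no population growth for 300 consecutive
generations before coverage), flagged on the result, and excluded from
ensembles, which draw further seeds instead; the count of stalled runs is
reported in the ensemble summary. All analyses therefore condition on a
successful expansion — the regime the observed data come from.

### Run termination

A run ends at its generation cap or, by default, as soon as the lattice is
fully covered (every cell occupied). Phoneme counts freeze behind the front
once cells reach the loss threshold, so the clines are laid down at the
front; continuing to iterate long after the front has crossed the domain
lets diffusive migration slowly mix languages spatially and erode the
diversity cline (the count cline, already frozen per-cell, is less
affected). The full-scale configuration (1,000 × 1,000 cells, 2,280
generations ≈ 73 kyr) ends close to its own crossing time, so stopping at
coverage is the faithful scaled-down analog.

### Scaled-down analyses

Slope analyses run on 301 × 301 lattices (origin to edge 7,500 km). The
near-origin cline is grid-size independent (verified against 501- and
1001-cell runs), so this measures the same per-km decline at ~3% of the
cost. One caveat: under fast loss (L = 20) the full-scale cline reaches
zero phonemes ~19,000 km out and flattens, so a full-domain fit at full
scale is shallower than the near-origin decline rate that the scaled
window measures. Ensemble means use 50 runs for the count-cline checks and
30 for the costlier diversity check (the reference analysis uses 100); each
run's slope pools the four axis transects (statistically identical samples
of one run), which roughly halves the per-run spread without moving the
mean.

## Initial languages

Each ancestral language draws its phoneme count uniformly from the
scenario's range — (35, 40) for the moderate scenario, (66, 76) for the
click-language-sized one — and its phoneme set from one shuffled ordering
of the master inventory under an overlap policy: nested prefixes (default),
disjoint blocks, or a shared core of a given fraction. The initial 10
tribes are split round-robin over the languages (2 each for 5 languages).
For the two-language diversity experiment the package supplies a synthetic
stand-in for a pair of real 40-phoneme inventories: two languages sharing
20 of their 40 phonemes, about the overlap two unrelated natural languages
of that size show (near-universal stops, nasals and basic vowels; divergent
remainders). The t_F intercept is sensitive to this overlap (fewer shared
phonemes → larger union → higher initial t_F); the slope is less so.

## Statistics

* `t_f`: 1/Σp_i² − 1 over relative phoneme frequencies; frequencies weight
  each tribe's language once (a saturated cell contributes 10 language
  tokens even if some coincide), matching the 200-languages-per-1000-km-bin
  arithmetic of the simulated transect. For observed tables each database
  language is weighted once.
* Binning is half-open, [k·w, (k+1)·w), anchored at 0 km; bin centers at
  (k + ½)·w; empty bins omitted. Widths of 1,000–3,000 km give essentially
  the same slope.
* `fit_cline`: ordinary least squares; the slope CI uses the t distribution
  with n − 2 df. A constant response returns an exact zero-slope fit (r =
  0, p = 1) rather than NaN.
* Ensembles report per-run slopes, their mean, σ, mean ± 2σ, and a
  normality check: D'Agostino–Pearson for ≥ 20 runs, Shapiro–Wilk below
  that (the test used is recorded in the output).

## Synthetic observed-data fixtures

`make_fixture` emulates a converted phoneme-inventory database: n languages
(default 359) with distances uniform on [0, 25,000 km], counts following a
linear cline (default intercept 37 phonemes, slope −5·10⁻⁴/km) plus
Gaussian noise (σ = 5 phonemes), clipped to ≥ 1, and phoneme identities
taken as consecutive runs of a fixed master ordering (908 tokens) whose
offset drifts with distance — so nearby languages share most phonemes and
binned t_F is non-degenerate. What fixtures do not emulate: the real
database's uneven spatial sampling, language-family structure, borrowing,
and the abrupt regional peaks of observed diversity; tests passing on
fixtures validate the pipeline's arithmetic, not claims about real data.
Observed tables are consumed as pre-converted delimited text with
precomputed great-circle distances; spreadsheet parsing and distance
recomputation are out of scope.

## Numerical and engineering choices

The lattice engine stores tribes as flat arrays grouped by cell and
languages as rows of an append-only bit-string pool (copy-on-write on
mutation), with per-generation kernels JIT-compiled by numba. Kernels draw
from an inline xorshift128+ stream seeded per call from the run's
`numpy.random.Generator`, so a run is reproducible bit-for-bit from its
single seed; bounded draws use a modulo whose bias (~n/2⁶⁴) is irrelevant
at the bound sizes used. The per-cell reproduction rule also exists as a
plain list-of-strings reference implementation, which the tests use as an
oracle against the vectorized engine.

## Known limitations

* Homogeneous space: no landmasses, coastlines, sea crossings, or
  migration-route geometry; distances are lattice distances along
  transects.
* The loss process abstracts all mechanisms (copying error, competition,
  contact loss) into one deterministic-periodic rate; loss is applied per
  tribe, not per distinct language per cell (the alternative reading is not
  implemented).
* Integer-tribe demography departs from continuous-density front models at
  low R0 (stalls, corner cells cycling below saturation); results at
  R0 ≤ 1.1 are not meaningful.
* Published slope intervals for the count cline are reproduced to within a
  few percent but not exactly; the residual difference is consistent with
  unstated implementation details of the original dispersal bookkeeping
  (sweep order, rounding of per-neighbour flows).
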