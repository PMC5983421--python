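# phonosfe

A serial-founder-effect simulator of worldwide phonemic clines.

Languages spoken today tend to use fewer phonemes the farther they are from
Africa. One proposed explanation is a serial founder effect during the
Out-of-Africa dispersal: small pioneering populations at the edge of the
range expansion repeatedly lost phonemes, and the expansion spread those
reduced inventories outward. `phonosfe` implements a stochastic lattice
model of that process, the t_F phonemic-diversity statistic, and the
cline-regression analyses used to compare simulated and observed language
data. It is aimed at researchers in cultural evolution and quantitative
linguistics who want to explore founder-effect dynamics of discrete
cultural traits.

## The model

Hunter-gatherer *tribes* (~300 people, one language each) live on an
n x n lattice of 50 km cells, all descended from 10 tribes seeded at the
central cell. Each generation (T = 32 y):

1. **Dispersal** — in each cell with N tribes, nearest-int(N·p_e) randomly
   chosen tribes stay (persistence p_e = 0.38); the rest are dealt
   round-robin to the k available von-Neumann neighbours, each of which can
   receive at most nearest-int(N·(1−p_e)/k) tribes.
2. **Reproduction and transmission** — each cell grows to
   min(nearest-int(N·R0), N_s) tribes, with net fecundity R0 = e^{aT} ≈ 1.4
   (a = 0.01/y) and carrying capacity N_s = 10 tribes/cell; new tribes are
   exact copies (clones) of randomly chosen residents.
3. **Phoneme loss** — every L generations (the *phonemic loss time*), every
   tribe in every cell below the saturation threshold (N < N_thr = 10)
   loses one uniformly chosen phoneme from its inventory.

Because only low-density cells lose phonemes, and low densities occur at
the advancing front, loss accumulates with distance from the origin and a
negative cline of inventory size vs distance is laid down and frozen behind
the front.

A language is a presence/absence vector over a master inventory of
`nph = 908` phonemes, stored compactly as a bit-string over its ancestral
language's initial phoneme list. Diversity of a set of languages is
measured by the evenness statistic

    t_F = 1 / Σ_i p_i² − 1

where p_i is the relative frequency of phoneme i across the set (t_F = 0
when one phoneme dominates; n − 1 for n equally frequent phonemes).
Clines are summarized by OLS fits of phoneme count per language — or
distance-binned t_F — against distance from the origin, with t-based 95%
confidence intervals for single fits and mean ± 2σ across ensembles of
runs.

## Worked example

```python
import phonosfe as ph

# a scaled-down run: 301 x 301 cells (origin to edge = 7,500 km),
# 5 initial languages of 35-40 phonemes, one phoneme lost per 80
# generations in below-threshold cells, run until the front crosses
cfg = ph.scaled_config(loss_time=80, grid_side=301, seed=1)
res = ph.run(cfg)
fit = ph.count_cline_from_run(res)
print(f"crossed after {res.generations_run} generations")
print(f"slope = {fit.slope:.3e} phonemes/km, r = {fit.r:.3f}, n = {fit.n}")
```

prints

```
crossed after 609 generations
slope = -4.055e-04 phonemes/km, r = -0.376, n = 6010
```

i.e. this run's simulated languages lose about 0.4 phonemes per 1,000 km of
distance from the origin, a moderately noisy but clearly negative cline
(6,010 language records: every tribe in every cell of the four pooled axis
transects). Repeating the run over an ensemble of seeds
(`ph.ensemble_slopes(cfg, 30)`) gives a mean slope near −4.8·10⁻⁴
phonemes/km for L = 80, and steeper clines for shorter loss times.

The same machinery analyzes observed-language tables (tab- or
comma-delimited, one row per language with a distance and a phoneme list;
see `phonosfe.observed_data`), and a fixture generator emulates such tables
with a controlled cline so every analysis is testable offline:

```bash
phonosfe make-fixture --n 359 --nph 908 --slope -5e-4 --seed 1 --out langs.tsv
phonosfe observed-cline --input langs.tsv --bin-km 1000 --out results/
phonosfe tf --input langs.tsv --bin-km 1000
```

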