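# Methods

## The model

Extrachromosomal DNA (ecDNA) carries amplified oncogenes but no centromere,
so at mitosis its copies are not partitioned faithfully: after replication
the `2c` copies of a mother cell are distributed between the daughters as
`x ~ Binomial(2c, 1/2)` and `2c − x`. This single asymmetry generates the
extreme cell-to-cell copy-number heterogeneity seen in ecDNA-positive
tumors, and — because a daughter can receive zero copies — continuously
produces ecDNA-free cells. Whether those ecDNA-free lineages take over or
stay marginal depends on selection.

`ecdnasim` models an expanding tumor as a stochastic birth–death process
with three parameters inferred from data:

* **k** — ecDNA copies in the tumor-initiating cell,
* **s** — the selection coefficient under a *constant selection* model:
  cells divide at rate `1` if ecDNA-free and `1 + s` if they carry at least
  one copy, independent of the copy number (so at `s = 2` an ecDNA-positive
  cell divides 200% faster than an ecDNA-free one),
* **q** — the spatial constraint: how far (in lattice units) a dividing
  cell can push its neighbors to make room.

### Spatial engine

Cells occupy sites of a bounded 2D square lattice. Events (division at the
class rates above, death at rate `d`, default 0) are drawn by rejection-free
kinetic Monte Carlo: event class proportional to summed propensity, cell
within class by uniform draw with acceptance `rate_i / rate_max` (an exact
O(1) sampler), and time advances by `Exp(1/Σrates)` for every drawn event.
A dividing mother looks along the 8 Moore rays; a ray is eligible if its
nearest empty site lies within `q` steps. One eligible ray is chosen
uniformly, the contiguous run of occupied sites shifts one step outward, and
the daughter takes the freed adjacent site. If no ray is eligible the
division is consumed without a birth (time still advances). `q = 1`
reproduces strict boundary growth; `q = inf` (and in practice `q = 1000` at
desk-scale sizes) approaches well-mixed growth. Base division rate is fixed
to 1, so all times are in units of the ecDNA-free cell-cycle time.

The pushing geometry (straight Moore rays, uniform tie-break, abort on
block) is this package's concrete reading of "push neighbors within a
radius q"; alternatives (shortest-path displacement, re-drawing a blocked
direction) would change microscopic details but not the q-limits, which are
what the inference uses.

### Well-mixed engine

The same rules with no lattice (every division succeeds) give an exponential
growth Gillespie process used (i) as the independent oracle for the spatial
engine's weak-constraint limit and (ii) for culture-like dynamics, where an
optional fixed-passage mode (subsample to `passage_to` cells whenever the
population reaches `passage_trigger`, for `n_passages` rounds) reintroduces
the possibility of losing the last ecDNA copy, which pure growth forbids
(binomial splitting conserves the population total).

## Spatial sampling

A simulated tumor is sampled the way multiregion FISH samples a resection:

* **core** — circular region centered on the founder cell's coordinates;
* **infiltrating margin** — 10 circular regions centered on the occupied
  cell nearest to a point at 75% of the tumor radius (max distance from the
  founder) at independent uniform angles;
* **leading edge** — same construction at 95% of the radius (the margin
  fraction is the measured convention; the leading-edge fraction is this
  package's choice, exposed as a parameter).

Each sample grows its radius until it encloses at least `n` cells and then
subsamples exactly `n` uniformly without replacement, size-matched to the
observed region it will be compared with. Cells with fewer than 3 total
copies are filtered out of both simulated and observed samples before
distribution comparison — the convention used to exclude stromal nuclei
from FISH fields — while ecDNA-positive fractions are computed unfiltered.
If a margin angle finds no occupied cell within tolerance
(`max(2, 0.05 R)`), the angle is re-drawn up to 20 times and the best
attempt is used.

## ABC inference

`ABCRejection(observed, prior, settings).fit(seed)` draws `(k, s, q)` from a
uniform prior grid (defaults `k ∈ {1..150}`, `s ∈ {0, 0.25, …, 4}`,
`q ∈ {1, 2, 5, 10, 50, 1000}`), simulates a tumor to `n_final`, samples one
core and 10 margins, and treats the 10 core–margin pairs as independent
acceptance candidates (they share the core; this follows the source
procedure). A pair is accepted when each region individually satisfies
`W1(filtered sim, filtered obs) ≤ eps_region` **and**
`|positive-fraction difference| ≤ delta_fraction` (unfiltered). The summed
Wasserstein distance σ of an accepted pair summarizes fit quality. The
procedure's published description does not state numeric thresholds; the
defaults `eps_region = 5`, `delta_fraction = 0.1` make an accepted
core+margin pair satisfy σ < 10, consistent with the reported fit quality,
and are echoed in all outputs. The positive-fraction term is a hard gate
rather than a σ summand so that σ remains a pure distribution distance.

`ABCResults.summary()` reports, per parameter, the most frequent accepted
value (ties broken toward the accepted median) with an asymmetric interval
spanning the central 68% of accepted values, printed as `mode −lo +hi`.
`param_estimate(..., point="median")` is provided for rank-statistics, where
the median of a sparse accepted set is more stable than its mode.

**Desk-scale defaults.** The source procedure runs ~3.2×10⁶ simulations of
10⁶-cell tumors per patient; this package defaults to `n_final = 10⁴` and
budgets ≤ 2×10³ (its own robustness check — inferences at 10⁶ vs 10⁷ cells
strongly correlate — supports size reduction). Two consequences, verified
in the acceptance suite: `k` recovers well (±50% at budget 2000), but `q`
is only weakly identified at 10⁴ cells — the core–margin Wasserstein signal
separates `q = 1` cleanly while `{5, 10, 50, 1000}` remain close, so the
`q` posterior is diffuse; and `s` is weakly identified when `k` is large
(the constant-selection fitness plateau: when nearly every cell is
ecDNA-positive, selection has little to act on). Regional sample sizes in
the recovery experiments are 400 cells, chosen so the sample radius stays
near 0.2 of the tumor radius and regions remain spatially distinct at
desk-scale tumor sizes; patient-scale sizes (hundreds to thousands of cells
against a 10⁶-cell tumor) would otherwise be geometrically inconsistent
with a 10⁴-cell tumor.

For the joint two-species fit the prior is 4-dimensional and fixed
thresholds become too sparse at desk-scale budgets, so the settings support
`accept_mode="quantile"` (accept the best `accept_quantile` fraction of
pairs by σ — standard quantile-ABC practice); the threshold mode remains
the default and is what the single-species recovery uses.

## Extensions

### Wild-type / variant heteroplasmy

Two copy types per cell (wild-type, variant), independent binomial
segregation, fitness dominated by the variant (`1 + s_var` with any variant
copy, `1 + s_wt` with wild-type only; defaults `s_wt = 1`, `s_var = 2`:
moderate advantage for the pre-existing wild-type ecDNA, strong advantage
for the activating variant). The variant either initiates with the clone
(`vvar = 0`, `kvar` founder copies) or arises when the population first
reaches `vvar` cells, by converting one wild-type copy chosen
per-copy-uniformly (mutation converts, never creates, a copy).
*Heteroplasmy* is the percentage of copies that are wild-type; with equal
selection and no mutation its replicate mean is conserved at
`100·kwt/(kwt+kvar)`. *Covariegation* is the probability that a core and a
random margin sample both contain the variant; it is high for
clone-initiating variants and collapses for late arrivals, whose subclone
is spatially localized.

`mutation_origin_distribution` runs well-mixed wild-type-only growth where
each newly replicated copy mutates with probability `mu`; it records the
wild-type abundance of the first-mutating cell as (copies at the moment of
mutation) − 1: `2c − 1` at a division of a cell with `c` copies, and
`k − 1` when the founder's own `k` copies (treated as one replication
round) include the variant — matching the convention that maps a patient's
inferred `k` to `k − 1` wild-type copies at mutation.

### Two ecDNA species

Distinct species (different oncogenes on different circles) with founder
copies `k1, k2`, fitness `1 + s_p` for cells carrying exactly one species
("pure") and `1 + s_m` for cells carrying both ("mixed"), and cosegregation
strength `rho ∈ [0, 1]`: after duplication, `round_half_even(rho · min(2c1,
2c2))` cross-species pairs each follow a single fair coin into one daughter,
and unpaired copies segregate independently. This pairing construction was
chosen for exact per-species conservation, a tunable [0, 1] range, and exact
limits — `rho = 0` is independent segregation, `rho = 1` forces equal splits
whenever `c1 = c2`. The published cosegregation formulation it stands in for
lives in supplementary material not available here; any mechanism with the
same limits should reproduce the qualitative behavior tested.

## Synthetic data

`generate_synthetic_patient` simulates a tumor at known truth parameters
and emits an unfiltered long-format copy table (core + margins, optionally
leading edge) with a truth sidecar and checksum. It emulates: integer foci
counts per nucleus, region size-matching, and regional spatial structure.
It does **not** emulate FISH optics, foci clustering into hubs,
segmentation error, stromal contamination (beyond what the <3-copy filter
would remove), or aneuploid background signal — so a green recovery test
establishes that the inference machinery recovers parameters *of this
generative model*, not that the model is identified against real staining
artifacts.

## Numerical choices

* Lattice half-width defaults to `ceil(2√(n_final/π)) + 16`; a run that
  touches the boundary raises rather than silently distorting geometry.
* Event budget `400·n_final + 10⁵` guards against pathological parameter
  combinations; exceeding it raises.
* Kernels are numba-compiled; each run reseeds the kernel RNG from its
  config seed, so every trajectory is reproducible from `(config, seed)`.
  Python-level sampling and ABC use `numpy.random.Generator` streams derived
  from the fit seed.
* Statistical tests in the suite use 3-SE bands for martingales, chi-square
  goodness-of-fit at α = 0.01 for segregation laws, and split-half replicate
  noise floors (95th percentile) for distribution-equality checks.

## Known limitations

2D lattice only; constant (copy-number-independent) selection only; no
microenvironment, no chromosomal co-alterations, at most two ecDNA species;
rejection ABC only (no SMC or regression adjustment). `q` and `s` posteriors
at desk-scale tumor sizes are diffuse for the reasons above — point
estimates of `q` from 10⁴-cell runs should not be over-read.
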