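# Methods

`pottsgrowth` simulates the growth of a planar epithelial tissue from a
single founding cell inside a rigid square confinement, coupling two
layers that tick on the same clock (one Monte Carlo step, MCS):

1. a **physical layer** — a Cellular Potts Model (CPM) in which each cell
   is a connected set of lattice sites sharing an integer identity, with
   mechanical energy

       E = Σ_{⟨i,j⟩, n_i ≠ n_j} J(τ_i, τ_j) + λ Σ_α (A_α − A_α^T)²,

   relaxed by Metropolis identity-copy attempts between adjacent sites
   (one MCS = side² attempts at uniformly random sites and random Moore
   neighbors as sources);

2. a **decision layer** of cell-autonomous rules: target-area growth
   suppressed by crowding, dA^T/dt = G·exp(−k(A − A^T)²); a G1 *sizer*
   (a cell leaves G1 only when its actual area strictly exceeds its
   individually drawn threshold As_i) followed by an S/G2/M *timer* of
   individually drawn duration τ0_i, after which the cell splits along a
   plane through its centroid perpendicular to its long axis and each
   daughter takes its own post-split area as target; a sigmoidal,
   density-dependent apoptosis hazard P(ρ) = p_max/(1 + e^{−α(ρ−ρ_½)})
   that sets the target area of a dying cell to zero so it drains away
   through the lattice dynamics; and live-cell extrusion when a cell's
   area falls strictly below a quarter of the mean live-cell area.

A zero-dimensional companion model treats the whole colony as one
elastic medium: dA/dt = −λ(A − A0), dA0/dt = (G/a0)·e^{−k(A−A0)²}·A0·
(1 − A0/Amax), integrated with fixed-step RK4 from A = A0 = a0.

## Unit system and parameters

Areas are in lattice sites, time in MCS; the reference parameter set is
expressed in units built from the sizer mean AS, the timer mean τ0 and
the elastic modulus λ. `resolve_lattice_units` applies those conversion
factors verbatim (kBT = 1.95·10⁻⁴ λAS², Jcc = 1.17·10⁻⁴ λAS^{3/2},
Jcm = 1.96·10⁻⁴ λAS^{3/2}, G = 1.16·AS/τ0, k = 1.897·10⁵/AS²,
ρ_½ = 1.5015/AS, α = 0.968·AS, p_max = 0.0015 per MCS at τ0 = 225,
AS = 1377 ± 34.4 sites, τ0 = 225 ± 5.625 MCS, box ≈ 1600·AS).
`rescale_params` moves a configuration to a different (AS, τ0) while
holding every dimensionless group fixed — including p_max·τ0, the SD
ratios, box/AS and t_max/τ0 — so desk-scale runs are replicas of the
full-scale condition.

### Calibration of the temperature/crowding pair

The growth law's sensor scale 1/√k must sit between two other scales for
the model to behave at all:

- **above the area-noise floor** of the lattice layer, otherwise the
  factor e^{−kΔA²} is ≈ 0 even for isolated, perfectly tracking cells
  and *nothing grows*;
- **below the cell area**, otherwise crowding is never sensed.

At the reference temperature (kBT = 1.95·10⁻⁴ λAS², i.e. ≈ 370 at
AS = 1377, two orders of magnitude above the contact energies) the
boundary of a cell is entropically rough: a single cell equilibrates
about +0.105·AS *above* its target (measured: +144 ± 14 sites at
AS = 1377), so the noise floor is ≈ 0.1·AS, while the reference sensor
scale is 1/√k ≈ 0.002·AS — fifty times *below* the floor. Literally
combined, these two constants suppress all growth by factors of order
e^{−2000}; simulations then contradict the model's own design targets
(timer-phase accrual G·τ0 = 1.16·AS, early divisions at τ0 intervals,
colony growth to confluence). The package therefore ships calibrated
default groups

    kBT/(λAS²) = 2·10⁻⁵      (noise floor ≈ 0.006·AS)
    k·AS²      = 400          (sensor ≈ 0.05·AS)

chosen once from this noise-floor ordering (noise ≪ sensor ≪ AS), with
all other constants at their reference values. With this pair, isolated
and boundary cells grow at ≈ G and divide timer-like, compressed bulk
cells arrest, and the colony growth time responds to G, λ and k through
the boundary pressure gradient. `resolve_lattice_units` still reproduces
the reference factors exactly; `calibrated_params` (and the packaged
default YAML) applies the calibrated pair.

### Density scale of the apoptosis hazard

The local density of a cell is the sum of inverse areas of the cell and
its touching neighbors (`local_density`). That sum grows with the number
of neighbors: in confluent tissue it is ≈ 7/Ā, i.e. 5–10/AS — several
times beyond the hazard midpoint ρ_½ = 1.5015/AS, which would pin the
hazard at its maximum everywhere and erase its density dependence. The
midpoint is calibrated on a *number* density scale, so the decision
layer evaluates the hazard at the neighborhood-normalized density (the
sum divided by the number of cells in it, ≈ the true local number
density). Homeostatic tissues then sit near the sigmoid midpoint
(measured ≈ 1.3–1.6/AS), giving genuinely density-regulated turnover.
Apoptotic (draining) cells are excluded from density sums: their areas
tend to zero and would contribute divergent terms.

### Why apoptotic cells may fragment

Live cells never fragment: a copy that would locally disconnect the
losing cell (the standard Moore-neighborhood connectivity test) is
rejected. Draining apoptotic cells are exempt, because shrinking cells
otherwise anneal into diagonal-ring remnants in which *every* single-site
removal fails the local test — the remnant freezes at finite area and,
over long runs, the tissue accumulates undrainable dying cells.
Fragmenting corpses (apoptotic bodies) are biologically unobjectionable,
and every fragment keeps draining to zero.

## Decision-step order

Per MCS, after the lattice step: (1) remove apoptotic cells that reached
zero area, (2) extrusion (strictly below a quarter of the mean
non-apoptotic area; a shrinking apoptotic cell crossing the threshold is
logged as an apoptosis removal, keeping the two elimination channels
distinct), (3) apoptosis sampling (once per cell per MCS), (4) growth of
target areas, (5) sizer checks, (6) timer advance and divisions
(deferred while a cell has fewer than 2 sites). Changing this order is a
breaking change. Divisions log one birth per daughter with the mother as
parent; the mother's id is retired without an elimination event, and
rate bookkeeping counts a division once via distinct (t, parent) pairs.

Per-cell thresholds are drawn fresh for each daughter (no inheritance)
from Gaussians truncated at ±3 SD and floored at 25 sites (area) / 1 MCS
(time). The founder starts as a centered disk of area AS/2 — below its
sizer threshold — with target equal to its area.

## Confinement, neighborhoods, conventions

Interfacial energy and copy sources use the 8-neighbor Moore
neighborhood (the common anisotropy-reducing CPM choice); each unordered
pair counts once. Sites outside the box are immutable medium: they are
never copy targets or sources, and boundary cells pay Jcm per wall
contact. Coordinates are 0-based (row, col) with the origin top-left;
lattice side = ⌈√box_area⌉, recorded in the run manifest. Pressure
follows p = −2λ(A − A^T) (compression positive); the continuum model's
pressure is λ(A0 − A) without the factor 2, matching its single-λ
relaxation. The boundary pressure gradient is reported as mean interior-
ring pressure minus mean boundary-ring pressure — positive when the bulk
is compressed relative to the rim, the state that drives colony
expansion — where boundary cells are those with at least one cell–medium
contact and the interior ring is their non-boundary cell neighbors.

## Stochasticity, seeds, extinction

One seeded RNG stream drives all Python-level draws; the lattice kernel
uses a splitmix64 state derived from it, so a (parameters, seed) pair
reproduces bit-identical runs. Under density-dependent apoptosis a
single small founder has a ~15–25% chance of dying before establishing a
colony; such runs carry no growth or homeostasis information, so
`run_surviving` advances the seed deterministically past extinct runs
and analyses condition on survival.

## Problem sizes and analysis choices in the test suite

Tests run at desk resolution AS = 100 sites, τ0 = 40 MCS (all default
dimensionless groups preserved): growth-to-homeostasis runs use a
100·AS box (≈ 130–170 cells at confluence, 4000 MCS, three seeds per
condition); sweep runs measuring the colony fill time use a 400·AS box
so the colony develops a genuine bulk, varying one parameter at a time
(λ varied alone — the Metropolis temperature is an algorithmic constant,
not a cell property). Homeostasis onset is detected as the earliest time
after which τ0-smoothed cell count and mean density both stay within a
relative band for 5·τ0; the band is 2% by default and 3% in desk-scale
analyses, where turnover noise among ~10² cells makes a 2% band
unattainable for fluctuating (apoptosis-on) tissues. Early-cycle
statistics pool divisions completed before 5·τ0.

The synthetic lattice fixtures (Voronoi tessellations, block cells)
exercise exact bookkeeping and energetics; they do not emulate realistic
cell-shape distributions, and desk-scale runs have only ~5–11 cell
diameters of colony radius, so spatial profiles are coarse. Passing
tests demonstrate the model's mechanisms (sizer-set homeostatic density,
pressure-regulated growth, boundary-localized proliferation), not
quantitative agreement with any experimental tissue.

## Known limitations

- No cell motility, chemotaxis, or Glazier–Graner perimeter constraint;
  the physical layer is deliberately minimal.
- The calibrated temperature/crowding pair is the package's own
  resolution of an inconsistency in the reference constants; anyone
  wanting the literal reference values can build them with
  `resolve_lattice_units` (and will observe growth arrest).
- The continuum model is zero-dimensional by design and shares only
  trends, not numbers, with the lattice model.
- At desk scale the colony radius is only 5–11 cell diameters, so the
  positive coupling between growth speed and boundary pressure gradient
  holds across the mechanical (λ, k) axes but is confounded along the G
  axis: fast-growing colonies hit the box before bulk compression
  develops.
- Label images use 16-bit ids; runs exceeding 65535 ever-created cells
  refuse to write snapshots.
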