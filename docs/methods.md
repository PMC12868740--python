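# Methods

## Model and estimand

The estimand is the annual origin–destination matrix `E(t)` over census
block groups (CBGs): `E_ij(t)` is the expected number of people resident in
CBG `i` in year `t−1` and CBG `j` in year `t`. Rows therefore sum to
year-`t−1` populations and columns to year-`t` populations, with one
convention: people who die or emigrate during year `t` stay on the diagonal
at their last residence, so the matrix describes the closed universe of
people with a US residence in year `t−1`. Entries are real-valued expected
counts, not integers, because individual histories contribute probabilities.

## Survey-response simulation

The raw signal is a per-person list of addresses with month-resolution
effective dates plus a listed start/end date. These are inconsistent in
messy data, so the pipeline:

- reconciles `[min(first effective, listed start), max(last effective,
  listed end)]` and pads ±12 months into an *activity interval*. The
  padding keeps edge years usable and makes terminal addresses persist one
  extra year, which is what encodes deaths/emigrants as diagonal stayers;
- drops undated records (unless sole, which inherit the reconciled start),
  territory records, and PO boxes with a non-PO-box record within 12 months
  (inclusive — month resolution cannot distinguish finer);
- forward-fills each address from its effective date to the next distinct
  effective date; simultaneous effective dates split probability uniformly
  and the split persists unchanged until the next dated record (the decay
  of such splits is genuinely underdetermined by the data; persisting is
  the simplest defensible rule).

The annual flow is built by asking, for each month `m` of year `t` covered
by the activity interval, where the person lives now versus in month `m` of
year `t−1`. Identical monthly distributions are treated as permanence
(diagonal contributions `p_a` per address); otherwise the outer product of
the two distributions is emitted. Months are weighted by their day count
*in year `t`* (the year the survey question is asked; leap years honored),
normalized over the covered months, so every person contributes exactly 1
per covered year — partially covered persons contribute 1 over their
covered months rather than being discarded.

## Address-to-CBG collapse

Geocoded addresses are one-hot rows of the mapping matrix `G`; ZIP-only
addresses get the crosswalk snapshot nearest their last-seen month, tracts
weighted by residential share and CBGs within a tract by population share.
Unmappable addresses are dropped and counted rather than imputed. The
collapse

    E = Gᵀ (A − diag A) G + diag(Gᵀ diag A)

applies the product of endpoint distributions to movers but routes stayer
mass through the diagonal only — an uncertainly located stayer never
manufactures an apparent move. "Evenly across the sub-block" is implemented
as this matrix product (probability-weighted); the uniform reading is the
special case of uniform ZIP distributions.

## Constraint construction

Yearly CBG populations are not published; they are interpolated per CBG from
the 2010 decennial count and the ten rolling five-year averages ending
2010–2019 by solving `min ‖A x − b‖, x ≥ 0` with a fixed 11×11 averaging
matrix over 2009–2019 (`x₁ = 2009 … x₁₁ = 2019`; the first four survey rows
are partial windows of widths 2–5 because pre-2009 years are not modeled).
`A` is nonsingular, so consistent inputs are recovered exactly; NNLS guards
noisy inputs against negative populations. The row-scaling stage uses the
year-`t−1` estimate, matching the row marginal of `E(t)` — the survey
window's nominal alignment is ambiguous by one year, and this choice is the
internally consistent one.

Census targets are adjusted to the matrix universe: state non-mover counts
`R` (and the within-state flow `F_rr`, which includes the non-movers — the
diagonal belongs to the `r=s` block) gain deaths + emigrants, where
emigrants = max(immigrants − net international migration, 0); the state
mover target is `S − R_adj − immigrants`, since year-`t` immigrants had no
US residence in year `t−1`; county year-`t` populations lose natural
increase and net international migration so national totals of the two IPF
marginals agree. Negative adjusted quantities floor at zero with a warning
instead of aborting, since noisy inputs should not kill a run. Survey
margins of error use the 90%-CI convention: CV = (MOE/1.645)/estimate,
aggregation in the L2 norm.

## Harmonization

Four multiplicative stages in the default order: CBG-population rows →
state non-movers/movers → state-to-state flow blocks → county IPF. Only the
county stage iterates (the county targets are the most precisely estimated;
iterating the noisier targets would overfit them). The IPF alternates
column-block and row-block scalings, checks the L1 change between iterates
after each full cycle, and stops at `tol` (default 1e−9 of total mass) or
6000 iterations, whichever comes first — small systems typically converge
in a few hundred iterations.

Numerical contracts, applied uniformly:

- **Zero preservation.** No entry is ever scaled to a zero target, zero
  entries stay zero, and a block with a positive target but no support is
  reported as unmet, never densified — multiplicative updates cannot create
  support, so this is forced, not optional.
- **Sparsity.** Every stage works on the coordinate representation with
  integer prefix codes for state/county blocks; cost per pass is linear in
  the stored entries and nothing ever materializes an `n²` dense structure.
- **Determinism.** No stage uses randomness; stage order is configurable
  and the per-stage reports (factors, skips, pre/post deviations, IPF
  trace) make order sensitivity auditable.
- Because all targets are absolute counts, the pipeline output is invariant
  to any positive rescaling of its input.

When the observed support misses cells that the marginals require, IPF
converges to the best matrix on that support; the reported marginal
deviation then reflects the infeasibility honestly rather than being forced
to zero.

## Synthetic study system

The generator exists to give every stage a known-truth system, not to mimic
US magnitudes. Fixed study conditions (defaults):

- geography 2×2×2×2 (16 CBGs, 4 counties, 2 states) on a coordinate grid
  with ~0.5°/0.15°/0.05°/0.02° offsets per level, CBG populations lognormal
  around 200 (σ=0.4, floor 20);
- ground-truth flows from a gravity model: annual mover share 12%
  (approximately the US rate across the 2010s), destination weight
  ∝ population × distance^(−1.0) × 3.0 homophily boost for same-group
  pairs. Rows are integerized by largest remainder so row sums equal
  origin populations exactly, which is what allows individuals to realize
  the truth *exactly*;
- individuals routed through years by deterministic (seeded-shuffle) pool
  slicing, all moves effective January 1; messiness injected independently
  per record at 5% (missing dates, PO boxes, simultaneous same-CBG
  addresses) and 10% ZIP-only addresses, one ZIP per tract;
- observation bias: person-level retention 0.9 / 0.55 by the group label of
  the origin CBG;
- components of change zero by default (closed population, exact IPF
  feasibility); an open mode generates per-state components at ~1% of
  population to exercise the adjustment arithmetic, with county chains
  kept nationally consistent by construction;
- constraint noise off by default; when on, multiplicative lognormal with
  the configured CV and MOE = 1.645·CV·value, county totals rescaled along
  the year chain to preserve feasibility.

What the generator does *not* emulate: within-CBG churn, correlated record
messiness, demographic attributes of individuals, mover/stayer-differential
observation bias, ZIP codes that straddle tracts, and real US flow
magnitudes. Passing tests therefore demonstrate the estimator's mechanics
and its bias-correction behavior under these structured conditions, not
fidelity to any real dataset.

One interaction worth knowing: ZIP smearing leaks some within-tract mover
mass onto the diagonal (a mover whose two addresses resolve to the same ZIP
distribution looks like a stayer), and the mover-stage rescale then inflates
the surviving off-diagonal entries uniformly. Matrix-level error still drops
sharply, but rate statistics along the within/cross-county axis can locally
get worse than a raw matrix whose rates were nearly unbiased to begin with.
The bias-correction evaluation therefore isolates observation bias on clean
histories, while the messy-history conditions are evaluated on matrix-level
(Frobenius) recovery.

## Problem sizes

Tests and the acceptance script run on the 16-CBG default geography with
2009–2019 truth (a few thousand persons per replicate), 20-replicate
evaluations for the bias-correction properties, 50 randomized runs for the
support/non-negativity invariants, 200 random instances for the collapse
oracle and 1000 for the interpolation recovery. These sizes were chosen so
the full suite completes in a couple of minutes while every property is
exercised well beyond its tolerance.

## Known limitations

- Address strings are never parsed; geocoding is assumed done upstream and
  only the ZIP fallback is computed here.
- The great-circle CBG-centroid distance used in the distance statistics is
  a modeling choice; the appropriate distance definition for move-distance
  statistics is not uniquely determined.
- The three one-shot scalings are not re-checked after IPF (their post-IPF
  deviations are reported, not enforced).
- No uncertainty propagation: the output is a point estimate, and the
  per-stage deviation reports are diagnostics, not confidence statements.
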