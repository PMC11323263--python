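# Methods

## The weighted-ensemble data model

A weighted-ensemble (WE) simulation runs N trajectories ("segments") in
parallel, each carrying a statistical weight w_i with Σ w_i = 1 within every
iteration. After each fixed resampling interval τ the ensemble is split and
merged across progress-coordinate bins to keep sampling even; trajectories
that reach the target state are recycled back to a basis (initial) state
with their weight preserved, maintaining a nonequilibrium steady state.

`wedana.io` fixes a concrete HDF5 dialect for this tree: contiguously
numbered iteration groups, a per-segment table (weight, parent_id,
endpoint), per-frame data under `pcoord` and `auxdata/<name>`. A
non-negative `parent_id` points at a segment of the previous iteration;
negative values encode the basis-state origin as `-(parent_id) - 1`, both at
the start of the run and after recycling. `frames_per_seg` counts the
inherited first frame plus the frames propagated during one τ, which makes
lineage continuity exactly testable: the first stored frame of a segment
equals the last frame of its parent, bit for bit. Weight-sum violations on
read are logged warnings rather than errors, because third-party files can
carry benign float drift; writes validate strictly before touching the disk.

## Per-frame weighting and normalisation

Histograms weight frames, not segments: each frame inherits
`w_seg / frames_per_seg`, the only apportionment that keeps per-iteration
frame totals at one. Normalisation blocks are:

- evolution matrices: each iteration row renormalised to 1 (each row spans
  the colour scale);
- averaged 1-D/2-D histograms: the whole selected iteration range sums to 1.

Binning is half-open `[e_i, e_{i+1})` with the final bin closed, preventing
double counting at interior edges while keeping the data maximum inside the
range. Default edges span `[min, max]` of the collected data with 100 bins,
overridable per axis. Frame-stride subsampling deliberately does not
renormalise weights; the stride is a thinning device and the histogram
renormalises afterwards anyway.

Free energies are the inverted natural log of the normalised histogram,
`F = -ln(P / P_max)` in units of k_B·T, scaled by k_B·T in kcal/mol
(k_B = 0.0019872041 kcal/mol/K, default T = 298 K) for kcal units. The
minimum finite value is exactly zero by construction; empty bins are NaN and
rendered as background, and values above `pmax` are masked rather than
clipped. Gaussian smoothing (sigma in bin units, reflective boundaries so no
mass leaks at the edges) is applied to the free-energy surface when drawing
contours; NaN cells are filled with the maximum finite value first so
contour lines close over unsampled regions. Sigma 0 is the bit-exact
identity.

Hexagonal binning uses the standard dual-lattice geometry (two interleaved
rectangular lattices in scaled coordinates; a point joins the nearer centre
with the squared y-distance weighted by 3, ties to the integer lattice) and
reduces each occupied cell by Σ(w·z)/Σw for WE data or a plain mean for
conventional-MD data. The geometry is implemented in the package rather
than delegated to the plotting library because the weighted-mean reduction
needs both w and z per point; rendering then draws polygons directly from
the computed cell values, so the pixel path consumes only the module's
output.

## Lineage algorithms

Tracing walks parent pointers from an anchor back to a negative parent
(iteration 1, or a mid-run recycling restart). Trace-by-value anchors on the
frame minimising Euclidean distance to the requested values after min–max
scaling each axis over the collected range — axes in different physical
units (Å vs Å², say) would otherwise dominate arbitrarily; raw distance is
available by flag. Ties break toward the lowest (iteration, seg_id, frame).
Note that frame continuity guarantees duplicated values across a parent/child
boundary, so an "exact hit" may legitimately resolve one iteration earlier
than expected; the tie-break makes this deterministic.

The successful-only filter marks exactly the segments lying on the ancestry
of at least one recycled segment, computed in a single backward sweep
(equivalent to the union of per-event traces, but linear in the tree).
Recycled walkers' post-recycling continuations are not included — they
belong to the next attempt. Basis-state filtering decodes each segment's
lineage root in a forward pass and drops skipped origins. Both filters
compose by conjunction, and downstream histograms renormalise the surviving
weights within their normalisation block, yielding conditional
distributions.

## Kinetics

By the Hill relation the steady-state flux into the target equals 1/MFPT.
The per-iteration recycled probability (flux per τ) is averaged cumulatively
over iterations 1..i and divided by τ in seconds; the levelling-off of this
estimate monitors steady-state convergence. A sliding-window mean is
available as an alternative statistic. For bimolecular processes the rate is
divided by the effective concentration (1/M/s); for equilibrium
(non-recycling) runs each iteration's flux is divided by the cumulative mean
source-state population over the same prefix, keeping numerator and
denominator on the same information set. A pre-computed RED-corrected flux
series, when present in the kinetics file, is consumed through the same
pipeline; it is never computed here.

Single-run uncertainties use circular block bootstrapping: ⌈n/b⌉ contiguous
blocks of length b (default ⌊√n⌋, balancing within-block correlation capture
against the number of independent blocks) resampled with replacement,
truncated to n, mean per replicate, central percentile interval (default
95%, 1000 replicates). Bounds are computed per plotted point on the
corresponding flux prefix — O(n²·n_boot), acceptable at the few-hundred
iteration lengths in scope and behind an opt-in flag. Replicate-simulation
uncertainties use Bayesian bootstrapping: flat-Dirichlet weights over the
replicate estimates, weighted mean per draw, percentile region.

## The synthetic simulator and its oracles

The generator runs real WE bookkeeping — digitised bins, split/merge
resampling, recycling, per-iteration flux and source-population recording —
over two toy propagators, and emits exactly the files the readers consume.
Defaults mirror a standard fixed-bin 1-D setup: evenly spaced bins, target
count 4 per bin, τ = 100 ps with 5 saved steps per interval, one basis state
holding all weight, recycling on.

- `double_well`: overdamped dynamics in U(x) = β(x²−1)², unit mobility,
  noise variance 2·D·dt. D = 0 reduces to deterministic gradient descent —
  the frozen-dynamics limit used in tests.
- `discrete_chain`: a nearest-neighbour walk hopping with total probability
  h (half each way), full reflection at the ends (an attempted off-chain
  move lands on the inward neighbour). Under this convention first-step
  analysis gives hand-checkable values (3 states, reflecting/absorbing,
  h = 1: MFPT = 4 steps) and the stationary law puts half the interior mass
  on each boundary state. An optional absorbing threshold freezes walkers at
  the target so the recorded flux counts first passages exactly.

Resampling splits the largest-weight walker into equal halves, one child at
a time, while a bin is under target; over-target bins merge the two
smallest-weight walkers, with the survivor drawn from the pair
proportionally to weight. Total weight is conserved to machine precision and
every occupied bin ends at exactly the target count. All randomness derives
from one root seed through named substreams (dynamics, merges, recycling),
so identical configs reproduce byte-identical payloads.

The exact MFPT oracle (dense linear solve of (I−Q)E = 1 over non-absorbing
states) anchors rate recovery: the long-run mean recycled flux per step of a
recycling run must equal 1/MFPT. One discretisation subtlety matters:
recycling is applied at interval boundaries, so a walker absorbed
mid-interval is parked until the interval ends, and with several steps per
interval the measured flux underestimates 1/MFPT by O(τ/MFPT). The
rate-recovery tests therefore run at one dynamics step per interval, where
the renewal argument is exact; the remaining discrepancy is purely
stochastic and is asserted within three bootstrap standard errors at roughly
10⁴ aggregate dynamics steps (6-state chain, h = 0.5, 600 iterations,
burn-in 100).

What the generator does not emulate: multidimensional progress coordinates
(the emulator writes 1-D pcoord plus a deterministic scalar auxiliary
observable; readers and analysis support N-D), realistic force fields,
correlated multi-dimensional observables, and heavy-tailed weight spectra
spanning many orders of magnitude. Passing tests therefore demonstrate the
correctness of the bookkeeping, weighting and estimators — not that any
particular molecular system is well sampled.

## Numerical choices

- Weight-sum tolerances: 1e-8 on file read/write (accommodates third-party
  drift), 1e-12 inside the resampler (own arithmetic only).
- Free-energy conversion divides by P_max before the log, so the floor is
  exactly 0 regardless of bin count.
- Degenerate histogram input (all values equal) opens a ±0.5 window rather
  than erroring.
- Tie-breaks: splitting picks the lowest-index maximal weight; merging the
  two lowest (weight, index) pairs; hex assignment ties go to the integer
  lattice; trace-by-value ties to the lowest (iteration, seg_id, frame).
- GIF frame count: ⌈(last − first + 1 − avg_plus)/step⌉, frame k averaging
  iterations [first + k·step, first + k·step + avg_plus]; the colour scale
  must be pinned via histrange/pmax for frames to be comparable.

## Known limitations

- The reader requires contiguous iteration numbering; sparse or skipped
  iterations are a structural error by design.
- Per-point bootstrap bounds are quadratic in the series length.
- The equilibrium-mode population normalisation assumes the recorded source
  population is positive at every iteration.
- Multi-file 2-D plots are rendered as side-by-side panels with shared
  normalisation conventions, not overlaid.
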