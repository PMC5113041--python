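# Methods

## Model

wormabm simulates early *C. elegans* embryogenesis as a set of cell agents
inside a rigid ellipsoidal eggshell. The model is deliberately
*descriptive*: every behavior is driven by a statistical summary of
observed wild-type cells (a mean and a standard deviation per cell), not
by a regulatory mechanism. The wild-type lineage is invariant, so a cell's
name fully identifies it, and the three input tables are keyed by name:

* division timing: absolute division time and cycle duration, each with an
  SD, in minutes on disk (converted once to seconds at load);
* division direction: the unit vector along which daughter 1 separates
  from daughter 2;
* migration target: the 3-D destination the cell heads to, where its own
  division will take place.

Assumptions inherited from this design: no cell death, no cell–cell
mechanical interaction or adhesion, no polarity signaling, no gene-level
regulation (a reserved, unused `extension_state` field on each agent marks
where such state would attach), and a strictly binary, name-driven
lineage. The population is therefore non-decreasing and each division
changes the cell count by exactly +1.

## Timekeeping and kinematics

All internal arithmetic is in seconds on a fixed 1 s tick; the 90 s split
phase and the 60 s output cadence are only expressible at that
granularity. A cell divides on the first tick whose clock has reached its
scheduled time.

The two movement rules are per-tick updates:

* **Split phase** (first `div_cycle_time` = 90 s after a division): each
  daughter advances by `(cell_size/2)/div_cycle_time` along its division
  direction per tick, so the full phase displaces it by half a diameter
  and the sister pair ends exactly one diameter apart — complete
  separation without overlap. The displacement uses the *daughter's*
  diameter; under the default volume-conserving size rule (below) the
  final separation is the daughters' common diameter, and under the
  size-inheriting rule it equals the parent's.
* **Interphase**: the cell moves by `(target − position)/(div_time −
  clock)` per tick. This is a displacement update (adding it to the
  current position is the only dimensionally consistent reading of the
  underlying rule) and has the property that repeated application lands
  the cell exactly on its target on the tick its division is due. When
  the remaining time is less than one tick the cell is placed on the
  target directly; this guards the `div_time ≤ clock` degenerate case and
  prevents overshoot when a noisy division time falls between ticks.

Founders are hatched already in interphase (their split phase is
disabled): they were not created by an in-model division and carry no
division direction.

Containment: after every move the cell is tested against the ellipsoid
`Σ((pᵢ−cᵢ)/aᵢ)² ≤ 1` (closed boundary) and, if outside, projected
radially about the shell center onto the surface. The projection is
idempotent and is the simplest correction consistent with a containment
*check*; no reflection or sliding is modeled. When no eggshell is given it
is fitted to the data: centered on the target table's centroid with
per-axis semi-axes 1.1× the maximum centered coordinate.

Note the interphase rule re-aims at the target from the current position
every tick, so an intermediate boundary clipping never prevents exact
arrival as long as the target itself is strictly inside the shell.

## Stochasticity

Division-time noise is Gaussian: `60·(t_div + ε)` seconds with
`ε ~ Normal(0, σ_div)` (the `absolute` policy, default). The alternative
`cycle` policy draws `born + 60·(cycle + ε)` with the cycle-duration SD;
absolute timing is the default because the validation statistics compare
absolute born/divided times. An SD recorded as unavailable (−1 on disk,
`None` in memory) contributes zero noise — the only non-arbitrary choice —
and the −1 is never allowed into arithmetic.

One RNG stream (numpy `default_rng(seed)`) serves the whole run. Cells
are processed in lexicographic name order each tick and the per-division
draws are consumed in sorted daughter-name order, so identical inputs and
seed give byte-identical output. (The original interactive implementation
of this model class schedules agents in nondeterministic order; fixed
ordering is a deliberate deviation in favor of reproducibility.)

## Sizes

No observational rule for daughter size is available, so the default
halves the volume at each division (diameter × 2^(−1/3)); `inherit` keeps
the parent diameter. Size only affects the split-phase excursion.

## Output format and lineage reconstruction

Snapshots are emitted every `out_time_resolution` = 60 s (including t = 0
and the end time) in a 20-field comma-separated record per cell: index
(1-based within the time point), validity flag, predecessor index at the
previous time point, two successor indices at the next time point
(successor 2 is −1 unless the cell divides in between), x/y/z, diameter,
name, and ten reserved fields (zeros, field 15 blank). The stream dialect
separates time points with `# time <s>` header lines; one-file-per-time-
point output is also readable. Writing then reading a record list is an
exact identity (floats are rendered with shortest round-trip
representation; integral values print as integers, matching the
conventional look of nuclei files).

`build_lineage` uses only the linkage indices: birth is the first frame a
name appears, division is the frame at which the two successors appear.
Born/divided times are therefore quantized *up* to the output grid (at
most one resolution step after the engine-internal event). If two
successive divisions fall inside a single output interval the stream
cannot encode them and linking fails loudly rather than silently dropping
a generation; at the default 60 s cadence this needs a cell cycle shorter
than a minute, far below the biological range.

Newick export gives each internal node its cycle length as branch length;
a leaf carries the span from its birth to the last snapshot, and an
isolated single cell gets length 0 by convention.

## Validation statistics

* `rmse(d, use_bessel=True)` = √(Σdᵢ²/(n−1)); with `use_bessel=False` the
  plain √(Σdᵢ²). **Both variants are kept on purpose**: the bundled
  benchmark's count and cycle RMSE values (2.491 cells, 52.877 s)
  reproduce only with the n−1 divisor, while its per-axis dividing-
  position aggregates (0.0059/0.0067/0.0033) reproduce only with the
  undivided form. Whether that positional aggregate intentionally omits
  the divisor or is an arithmetic slip in the benchmark's provenance
  cannot be determined from the numbers alone; the package defaults the
  position report to the undivided variant so the published values are
  reproducible, and documents rather than silently "fixes" the
  inconsistency.
* Count sampling follows the benchmark's three-tier rule: sample at each
  multiple of 5 minutes when both series have data there; otherwise at
  the nearest whole minute with data in both; otherwise pair the
  simulated/observed times with minimal mutual difference (the two
  sampled times may then differ). Ties break toward earlier times.
* Cycle SDs propagate in quadrature, σ_c = √(σ_b² + σ_d²), and the
  cycle report counts cells whose deviation is below a configurable
  fraction (default 60%) of that SD.
* Deviations are reported as absolute values throughout.
* One row of the bundled position benchmark is internally inconsistent:
  cell C's tabulated x-deviation (0.0004) does not equal the difference
  of its tabulated coordinates (0.0067). The deviation columns are kept
  verbatim and the aggregates are computed from them.

## Synthetic fixtures

`make_fixture` generates a complete binary lineage over 1–4+ founders
(default names `ABa ABp EMS P2`, daughters suffixed `a`/`p`), with
per-cell cycles drawn uniformly from `mean_cycle ± cycle_jitter` minutes
(defaults 15 ± 2, in the range of early blastomere cycles), absolute
division times accumulated from the root, a per-cell SD (`sd_level`,
default 0.5 min) written to the table, random unit division directions,
and targets rejection-sampled inside 0.9× the eggshell with a minimum
spacing (leaving room for split-phase excursions). The generator returns
the ground-truth tree, so round-trip tests can demand exact topology
recovery and (noise-free) time recovery up to output quantization.

The fixtures emulate the *mechanics* of observation-derived inputs, not
their biology: targets are random rather than stereotyped, all cells share
one size rule, and depth stops far short of the ~350-cell stage. Passing
fixture-based tests therefore demonstrates the correctness of the
machinery (scheduling, kinematics, linkage, reconstruction, statistics),
not biological fidelity of any particular embryo.

Test problem sizes were chosen to probe each property at the smallest
scale that exercises it: a 28-cell/2-generation lineage for end-to-end
runs, 20 seeds for topology recovery, and 1000 seeded runs of a 3-founder
fixture for Monte-Carlo recovery of the tabulated timing SDs (sampling
error of an SD at n = 1000 is ≈ 2%, comfortably inside the 10% check).

## Known limitations

* No mechanics: overlapping non-sibling cells are not resolved; the
  eggshell is the only spatial constraint.
* Division timing is per-cell independent Gaussian noise; correlations
  between related cells' timings are not modeled.
* The lineage reconstruction requires at most one division per cell per
  output interval (enforced, see above).
* The benchmark tables cover early founder cells only; statistics on
  deeper lineages rely on user-supplied observational data.
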