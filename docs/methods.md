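# Methods

## The statistic and its traditional evaluation

For angles φ₁ ≤ … ≤ φₙ in [0, 2π) the spacings T₁,…,Tₙ are the arcs
between circular neighbours (including the wrap-around arc through 0), and
Rao's statistic is U = ½ Σ |Tᵢ − 2π/n|. The factor ½ makes U the total
one-sided deviation, since Σ(Tᵢ − 2π/n) = 0. U is invariant to rotation
and reflection of the sample and to the input order; it ranges from 0
(exact equal spacing) to 2π(n−1)/n (all points coincident). Ties are legal
and preserved — a tie contributes a zero spacing, which is exactly the
phenomenon that rounding induces.

The traditional test compares U in degrees with the critical values of
Russell & Levitin (1995), transcribed into
`src/raospace/_data/rao_critical_table.csv` (levels α ∈ {0.001, 0.01,
0.05, 0.10}; n = 4…30 consecutively, then 35…1000; a SHA-256 of the file
is pinned in the test suite). For a non-tabulated n between 30 and 1000
the critical value is interpolated linearly in n between the bracketing
rows. Because the α grid is finite the traditional p-value is reported as
a bracket between adjacent levels, e.g. (0.01, 0.05]. Monte-Carlo
validation of the transcription: at the α = 0.05 column the null rejection
rate on continuous uniform samples is 0.0495–0.0501 for
n ∈ {10, 20, 30, 50, 100} (4 × 10⁵ replicates per n).

## Simulation-based p-values

**Continuous variant.** U_o is the observed statistic; N_R samples of size
n are drawn from the continuous circular uniform and scored. With N_e the
number of null statistics ≥ U_o (ties count, making the p-value
conservative), p = (N_e + 1)/(N_R + 1). p is therefore bounded in
[1/(N_R+1), 1] and can never be zero. Default N_R = 10,000.

**Discrete (perturbation) variant.** When data is recorded on a grid of K
equal bins, continuous null samples are not comparable to the observed
sample: the observed ties inflate U_o relative to untied null draws. The
procedure therefore (a) adds i.i.d. von Mises(0, κ) perturbations to the
observed values — once; the resulting single U_o is used — and (b) draws
each null sample from the continuous uniform, rounds it to the same
K-bin grid, and perturbs it with fresh jitter before scoring. Rounding a
continuous uniform to K equal bins yields equiprobable bins, so step (b)
is the exact null of "uniform data recorded at this precision", and under
that null the observed and null statistics are exchangeable, giving a
valid (slightly conservative, due to the +1 correction) p-value.

Rounding is to the nearest grid point, half-way values rounding away from
zero, and a value rounding to 2π wraps to 0. The half-tie rule is
measure-zero for continuous draws and is fixed purely for reproducibility.
If observed values are off the declared grid, strict mode raises;
permissive mode (default) rounds them onto it with a warning.

**Perturbation size.** κ is the concentration of the jitter; its circular
SD is ≈ κ^(−1/2), i.e. ≈ 1.81° at the default κ = 1000. The jitter only
needs to break ties identically on both sides of the comparison, but it
should stay well below the grid spacing so that it does not blur bin
structure. The package warns when κ^(−1/2) exceeds 10% of the bin width —
which the κ = 1000 default does trip for 10°-and-finer grids. We keep
κ = 1000 as the default because the calibration study shows it controls
the type I error at that setting; users with coarse grids can raise κ
(the warning threshold corresponds to κ ≥ (10/width_rad)²).

**Reproducibility.** One root seed feeds a `numpy` `SeedSequence`; null
resamples are generated in fixed-size batches of 2,048 rows with one
spawned sub-stream per batch, so results are bit-identical for a given
(sample, config, seed) regardless of how the batches are executed. Von
Mises draws use numpy's generator (Best–Fisher rejection sampling); its
correctness is property-tested against the Bessel-ratio mean resultant
length I₁(κ)/I₀(κ) and the large-κ normal approximation.

## Synthetic data generators

`circdist` provides the three seedable samplers the study needs:

* circular uniform on [0, 2π);
* von Mises(μ, κ) — defaults μ = π, κ = 2 for the power study; κ = 0
  falls back to the uniform;
* wrapped skew-normal — linear skew-normal draws by the two-normal
  representation (δ = α/√(1+α²), X = ε + ω(δ|Z₀| + √(1−δ²)Z₁)) wrapped
  modulo 2π; defaults ε = π, α = 30, ω = 2 (radians). The
  location/scale/shape convention is the standard one, and wrapping is
  explicit: with ω = 2 rad a non-trivial fraction of mass wraps, which is
  part of the alternative being simulated.

These emulate idealised measurement: i.i.d. draws, no angular bias, and
rounding (when requested) to exactly equal bins. Real instruments can add
direction-dependent error, unequal bin widths, or serial correlation —
none of which the generators model, so passing tests demonstrate
calibration and power under clean sampling, not robustness to those
artefacts.

## The simulation study

`study.rejection_rate` estimates P(reject) over replicated datasets for a
configured (variant, distribution, binning, n). Conventions: with uniform
data (type I error) a replicate counts as rejected when p < α; with
non-uniform data (power) when p ≤ α. The two rules are deliberately
asymmetric — for Monte-Carlo tests p lies on the grid k/(N_R+1), so
p = 0.05 exactly is attainable (e.g. N_R = 19) and the convention matters;
for the critical-value test both reduce to U > U_crit. The traditional
variant on the study grid is fully vectorized (millions of replicates per
minute); the simulation variant runs one seeded test per replicate.

Default scale is 2,000 replicates with N_R = 2,000 per test, which
reproduces the qualitative and quantitative behaviour of the full
10,000/10,000 experiment (binomial SE at the 5% level: 0.0049 vs 0.0022)
while keeping a full grid run at desk timescales; `at_full_scale()` /
`--full-scale` restore the original scale. The default sample-size grid
{10, 20, 30, 50, 100, 200, 500, 1000} spans the table-supported range and
includes the anchor sizes 10, 50 and 100.

Measured behaviour (recomputed by `scripts/acceptance.py` and the test
suite, not quoted from elsewhere): on continuous uniform data both
variants hold the 5% level at n = 50. On rounded uniform data the
traditional test inflates — with 10° rounding from ≈ 6.7% at n = 10 to
≈ 100% at n = 100; with 1° rounding the inflation is milder at n = 100
(≈ 6.7%) and grows with n (≈ 15% at n = 200) — while the perturbation
test stays at the nominal level. Power against von Mises(π, 2) at n = 20
is ≈ 0.94 for both variants.

## Numerical and design choices

* Internal unit is radians everywhere; degrees only at I/O boundaries and
  in the critical-value comparison (the published table is in degrees).
* Input ranges are restricted to [−4π, 6π) rad / [−720, 1080)°; values
  outside raise naming the offender. A finite window catches unit
  mistakes (e.g. degrees fed as radians) that unlimited wrapping would
  silently absorb. Units are always explicit — 350 is admissible in both
  units, so autodetection is unsafe.
* Exceedance is counted with ≥ (ties toward N_e): conservative.
* `normalize_angles` sorts stably; tie order cannot affect U.
* The CLI refuses the traditional method when `--bins` is given (that
  misuse is the package's raison d'être); `--force-traditional` exists
  for demonstrations such as the study itself.
* Degenerate inputs: n < 2 raises; n identical values is legal and gives
  U at its maximum; the traditional test requires 4 ≤ n ≤ 1000 (table
  support) and errors otherwise.

## Known limitations

* The traditional p-value is only a bracket; exact p-values require the
  simulation route.
* The discrete test's U_o depends on the single observed-sample
  perturbation, adding a small extra layer of Monte-Carlo variance that
  averaging over repeated perturbations would remove; the single-jitter
  design is kept for fidelity to the published algorithm and because the
  calibration study shows it suffices.
* Equal bin widths are assumed for rounded data; unequal binning schemes
  are out of scope.
* Axial (2θ) data, weighted observations and Rao's test of homogeneity
  (a different test sharing the name) are out of scope.
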