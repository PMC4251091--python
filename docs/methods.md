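# Methods

## Model

An HPLC-DAD acquisition is treated as an exact bilinear mixture
`X = A S` (m wavelength channels × t time points; n compounds). The
package's goal is to recover the rows of `S` (elution peaks) and columns of
`A` (spectra) from `X` alone, with `n` unknown.

Prior knowledge enters through the peak shape: each elution profile is
assumed to be a unit-maximum Gaussian `r(x; μ, σ) = exp(−(x−μ)²/2σ²)` on
the integer time axis `x = 1..t`. The normalising factor is deliberately
dropped — peak amplitude belongs to the spectra, the reference encodes
shape only. Admissible parameters are integers with `1 ≤ μ ≤ t` and
`1 ≤ σ < t/6`; the width bound requires the central 99.73 % of the Gaussian
mass (μ ± 3σ) to fit inside the elution window, so truncating the curve to
the window loses less than 0.27 % of its mass and no renormalisation is
applied. Sub-integer (μ, σ) refinement is out of scope: the search grid is
integer, matching the resolution at which elution peaks are recorded.

### Constrained single-unit fit

`X` is centred and whitened with the population (1/t) covariance,
retaining every eigendirection above `1e-10` of the leading eigenvalue —
deliberately *all* numerically nonzero directions, because discarding small
eigenvalues is precisely the failure mode (lost minor compounds) this
method is meant to avoid. For a candidate θ, one constrained ICA unit
maximises

    J(b) = E{G(bᵀx̃)} − γ · ‖y − r(θ)‖²,   G(u) = u⁴/4,   ‖b‖₂ = 1,

where `y = α·(bᵀX̃) + d·1` is the unit's output calibrated to the raw
signal domain. The scale `α` and offset `d` are re-solved in closed form at
each iteration (an ordinary 1-D least-squares fit of the projection against
the reference): the offset absorbs the centring shift between the whitened
and raw domains, and the scale absorbs the unit-variance normalisation that
whitening imposes. Without the scale term the constraint `‖b‖ = 1` forces
`var(y) = 1`, and the distance to a unit-maximum reference could never
approach zero even on noiseless data — the calibrated form is what makes
ε(θ*) vanish exactly at a true compound.

The update is a Newton-style fixed-point step in the fastICA family:

    b⁺ ∝ [E{x̃ g(u)} − 2γα X̃(y − r)] − [E{g′(u)} − 2γα²t] · b,
    b⁺ ← b⁺ / ‖b⁺‖,

(expectations are means over the t time points; the penalty terms are raw
sums, matching the unnormalised distance in the objective)

with `g = G′`, `g′ = G″`; both the gradient and the (scalar) curvature of
the penalty enter with the signs of the penalised objective. Iteration
stops when `|1 − |b⁺·b|| < 1e-6` (default) or after 200 iterations;
non-convergence is reported in the result, never raised, because the
genetic search treats every θ evaluation alike. The ICA sign indeterminacy
is resolved by forcing positive correlation with the reference (hence a
positive peak).

**Penalty weight γ.** The distance term enters as the raw sum over all t
time points and `γ` defaults to 10. This is a deliberate, load-bearing
choice: `E{G(u)} = mean(u⁴)/4` grows with the kurtosis of the underlying
source (20+ for sparse elution peaks), so if the penalty is scaled down to
O(1) (for example by dividing by t) the contrast term drags the fitness
minima two to three grid steps away from every true peak — verified by
brute-force evaluation of the full (μ, σ) grid on the five-compound
benchmark, where the dominant-contrast weighting leaves *zero* of the five
generating parameters as local minima. At γ = 10 all five generating
parameters are the only deep interior minima of the surface and the
contrast term still contributes away from the minima. γ is configurable
(`FitOptions.gamma`).

**Initialisation.** `b₀ ∝ X̃(r − mean r)`, the least-squares projection of
the reference. It is deterministic, so ε(θ) is a pure function of
(X, θ, options) and the fitness surface is identical across runs — a random
init would make the surface noisy under the genetic search's memoisation.

**Least-squares mode.** `fitness_mode="ls"` skips the contrast term
entirely: `b` is the closed-form maximum-correlation direction and ε is the
affine-fit residual. On noiseless data this mode is exact (ε(θ_true) ≈
1e-29) and serves as the independent cross-check of the default mode in the
test suite, where the exhaustively evaluated `ls` surface's local minima
are compared against the search output.

### Measurement operator and fitness

ε(θ) = Σⱼ (y(j) − r(j; θ))², the plain squared Euclidean distance between
the calibrated output curve and the reference. ε is memoised per θ — the
grid is finite and the genetic search revisits points constantly.

### Parallel refinement

Once the solution set θ* is known, all units are iterated jointly and the
final peak matrix `Y*` (rows ordered by ascending μ, positive peaks) is
assembled from the calibrated curves. Classical symmetric decorrelation
`B ← B(BᵀB)^{−1/2}` is available but **off by default**: overlapping
elution peaks are genuinely correlated in time, and forcing orthogonal
outputs caps the attainable per-point recovery error near 1e-2 on the
benchmark (the best orthogonal approximation to the true unmixing
directions, whose Gram matrix has off-diagonals up to 0.55), whereas the
reference constraints already pin each unit to its own compound and give
per-point errors below 1e-6. With `decorrelate=True` the `BᵀB = I`
postcondition holds to machine precision.

### Spectra estimation

`A = X pinv(S)` with the Moore–Penrose pseudo-inverse — the exact inverse
of the bilinear model when `S` has full row rank and noise is ignored.
Rank-deficient peak sets raise; negative spectral entries (physically
meaningless, a symptom of imperfect peak recovery or noise) are logged,
never clipped. Recovery is scored by greedy nearest-θ matching followed by
mean squared error on unit-maximum-scaled curves and spectra, which makes
the score invariant to compound order and positive rescaling.

## Multi-areas genetic search

Chromosomes encode (μ−1, σ−1) as fixed-width plain binary
(⌈log₂ t⌉ + ⌈log₂ σmax⌉ bits; 8 + 6 on the benchmark axis). Distances in
the (μ, σ) plane are Euclidean; ties are broken everywhere by
(fitness, μ, σ) so runs are bit-reproducible from the seed. Off-grid bit
patterns arising from crossover are discarded, keeping every evaluated
chromosome inside the admissible domain.

Per generation:

1. **Area separation** — greedy: the fittest unassigned chromosome becomes
   a centre, every unassigned chromosome within the user radius r₀ = 5
   joins, the radius is updated to the largest member distance; repeat.
2. **Reproduction** — in areas with radius > 1.5 and ≥ 2 members, each of
   the top 5 elites mates with the member at maximal Hamming distance
   (ties: fitness order); every differing bit yields one child (the elite
   with that bit flipped); children beating the worse parent (optionally:
   both parents) replace the area's inferior members.
3. **Emigration** — only the top 3 per area stay. If stayers would exceed
   80 % of the population, the globally worst stayers are evicted too
   (emptied areas disappear). This immigrant reserve is essential: without
   it the area count grows until every chromosome is a stayer, the
   immigration quota hits zero and the whole search freezes in a fixed
   point.
4. **Immigration** — boundary-centred areas (μ ∈ {1, t} or σ ∈ {1, σmax})
   are ignored; areas whose circles overlap (centre distance < sum of
   radii, transitively) merge into one receiving group; each group's quota
   is ∝ 1/(1 + elite count), largest-remainder rounded. Per group,
   pop_size candidates are drawn uniformly in a circle around the group's
   best centre with the group's largest area radius (min 1), and the top
   quota by fitness immigrate. Candidates that fall inside a fitter
   area's circle outside the group are discarded — they would be captured
   by that area at the next separation, permanently re-inflating its
   radius; this capture filter is what lets area radii actually contract
   to the stopping threshold.

The loop ends when no area can reproduce (all radii ≤ 1.5, i.e. every
member within one grid step of its centre — a converged area containing a
diagonal neighbour has radius √2, so a threshold of 1 would never be
reached) or after `max_generations` = 50, in which case the result carries
a warning flag. Finally each distinct area centre is screened: it is a
solution iff it is interior and ε there is ≤ ε at all 8 grid neighbours.
On the benchmark, runs that terminate by the radius criterion do so in
8–13 generations.

Defaults (`MGAConfig`): population 60, 6 μ-subspaces for stratified
initialisation, 5 elites and 3 stayers per area, r₀ = 5, stop threshold
1.5, merge factor 1.0, immigrant reserve 20 %, 50 generations. All are
plain dataclass fields, overridable from the CLI/YAML config.

## Synthetic data

The generator emulates a noiseless DAD acquisition: `S` from the Gaussian
reference family itself, `A` as sums of 2–3 seeded Gaussian absorbance
bands per compound (positive, unit maximum, small baseline), re-drawn until
columns are well-separated (pairwise |correlation| < 0.95, full rank; the
benchmark's condition number is < 1e3). The benchmark mixture uses five
compounds at (50,21), (75,12), (90,10), (155,17), (175,9) — the last two
and the middle pair overlap substantially — on t = 241, m = 101, chosen as
the smallest round dimensions that give all five peaks their ±3σ support
and satisfy the σ < t/6 bound with room to spare. Optional i.i.d. Gaussian
detector noise can be added (`noise_sd`), but the default benchmark is
noiseless and the estimator deliberately ignores noise.

What passing the synthetic benchmark does **not** show: robustness to
tailing/fronting (asymmetric) peaks, baseline drift, heteroscedastic
detector noise, or reference-model mismatch — real elution profiles are
only approximately Gaussian, and on real data the residual spectra errors
are dominated by exactly that mismatch plus noise. The search itself is
stochastic: a single run occasionally freezes an area one step off a
minimum or merges two basins; the library exposes a repeated-run consensus
(`separate(..., repeat=k)` keeps thetas found in at least half the runs)
as the standard remedy.

## Degenerate inputs and numerical edges

- `t < 7` admits no integer σ and is rejected at the domain layer.
- Constant input (zero variance) cannot be whitened and raises.
- Rank-deficient recovered peak sets raise in the estimator rather than
  silently producing pseudo-inverse artefacts.
- A candidate reference with zero projection norm falls back to the first
  whitened axis for initialisation (never observed on real surfaces, but
  the fit must stay total).
- Fitness evaluations that fail to converge in 200 iterations are used at
  whatever value they reached; the local-minimum screen at the end is what
  guarantees solution quality.

## Known limitations

- Gaussian references only; log-normal/gamma/Weibull peak families and
  multi-parameter references are not implemented.
- The estimator is noise-blind (`A = X pinv(S)`); under real noise the
  spectra inherit it unchanged.
- MATLAB v7.3 (HDF5) `.mat` files are not supported, only v5.
- The compound count is bounded above by the number of wavelength
  channels (separability needs m > n); the generator enforces m ≥ n + 1.
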