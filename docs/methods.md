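# Methods

## Signal model

A digitized single-channel ECG window `x̃ ∈ R^N` is treated as compressible
in the orthonormal DCT-II basis: `x̃ = Ψs̃ ≈ x = Ψs` where `s` keeps only the
`K` largest-magnitude transform coefficients. `Ψ` is the synthesis
(inverse orthonormal DCT-II) matrix, so analysis is `s̃ = Ψᵀx̃`, Parseval
holds exactly, and the retained-K truncation is the best K-term
approximation over every coefficient subset. Compression is
`y = Φx + v = As + v` with `A = ΦΨ`, `Φ` an i.i.d. equiprobable
`±1/√M` Bernoulli matrix (unit-norm columns, drawn reproducibly from a
seed), and `v` white Gaussian measurement noise added to `y` — whether the
distortion physically arises during compression or transmission, it enters
the model identically as additive noise on the measurement. A nominal SNR
in dB fixes the per-sample variance from the realized signal power,
`σ² = ‖As‖²·10^(−SNR/10)/M`, the common convention in compressed-sensing
benchmarks; σ² can also be set directly.

## The recovery algorithm

The tree search maintains layers of partial supports ("paths"):

* **Pre-scan.** `Θ` = the `|Θ|` indices maximizing `|aⱼᵀy|` (ties to the
  lower index). Because `‖A_Iᵀy‖₂²` is a sum of per-column terms this is
  the exact argmax over all size-`|Θ|` subsets. Default `|Θ| = K` — the
  minimal scan; larger values widen the tree.
* **Layer expansion.** Layer `i` expands every surviving path of layer
  `i−1` with branches from `Θ` (visited in descending pre-scan correlation,
  which tends to tighten the pruning threshold sooner without affecting the
  final best-so-far result). Supports already expanded within the layer are
  skipped (paths are unordered sets).
* **Full-size costing.** Each new path `Λᵢ` is completed to cardinality `K`
  by the inner solver acting on the path residual `r_Λᵢ = P⊥_Λᵢ y` over the
  remaining columns `Ω∖Λᵢ` (optionally restricted to `Θ∖Λᵢ`), and its cost
  is the joint least-squares residual norm of the completed candidate.
  Partial and full paths therefore compete on the same footing. Inner
  solvers: subspace pursuit (default), multipath matching pursuit,
  exhaustive enumeration (for tiny test instances), or greedy continuation
  ("omp"), which refits each new atom jointly with the path — equivalent to
  OMP on the path-projected dictionary — so the completion of the top
  pre-scan branch reproduces the plain OMP solution exactly, giving the
  incumbent a structural never-worse-than-OMP guarantee under that inner
  solver.
* **Pruning.** A candidate costing more than the layer's threshold `ε_i` is
  pruned. `ε₁ = ∞` (the true support can never be pruned before it is first
  seen); the threshold for the next layer is the running minimum candidate
  cost. By default `ε_i` is frozen at layer entry and improvements apply
  from the next layer on; `epsilon_update="running"` lets mid-layer
  improvements prune immediately (never worse, usually fewer evaluations —
  both semantics are defensible readings of the two-threshold scheme).
* **Incumbent.** The best-so-far candidate (ties broken toward the
  lexicographically smaller support) is returned. A literal mode that
  overwrites the incumbent with every surviving candidate is available
  behind `literal_incumbent=True` for fidelity experiments; the default
  matches the stated intent of minimizing the cost globally.
* **Early stop.** The search terminates once `‖r_{I*}‖² ≤ c·N·σ²`,
  a fraction `c ∈ [0, 1]` of (an upper bound on) the expected noise energy.
  The multiplier `N` follows the algorithm's stated bound even though the
  noise vector has length `M` (`E‖v‖² = Mσ²`); `stop_multiplier="m"`
  selects the dimensionally-correct variant, which stops strictly later.
  With `c = 0` and `σ² = 0` the stop degenerates to "first zero-residual
  candidate"; numerically, a candidate counts as zero residual when
  `‖r‖ ≤ 10⁻⁹·max(‖y‖, 1)` (the `zero_tol` knob).
* **Budget.** A safety cap (`max_candidates`, default 10⁵ evaluations)
  bounds pathological trees; hitting it returns the best-so-far with a
  truncation flag.

`k ≤ M` is enforced; all tie-breaks (correlations, residuals, top-K
magnitude selections) go to the lower index / lexicographically smaller
support, making every run deterministic.

## Baselines

OMP, subspace pursuit (stop when the residual fails to improve by a 10⁻¹⁰
relative tolerance or after 2K iterations, returning the best support
seen — so its reported residual is monotone), multipath matching pursuit
(breadth- or depth-first, L branches per node, paths deduplicated as sets,
node budget with truncation flag; L=1 reduces to OMP), basis pursuit as the
split-variable linear program solved by HiGHS (support read off above a
10⁻⁶ relative magnitude threshold to shed LP dust), oracle least squares on
the true support, an exhaustive ℓ₀ minimizer (enumeration capped at 10⁵
subsets, lexicographic tie-break), and a linear MMSE estimator under an
i.i.d. zero-mean coefficient prior. The MMSE baseline is otherwise
unspecified in the literature this mirrors; the prior variance defaults to
the ground-truth nonzero variance on synthetic runs and to the
`(‖y‖² − Mσ²)/K` energy heuristic otherwise, and it is labelled as such.
All solvers return the estimate (zero off support), the support, a
from-scratch residual norm, and solver-specific diagnostics; rank-deficient
least-squares steps fall back to the min-norm solution and are flagged.

## Recovery guarantees

For tiny dictionaries the restricted isometry constant of order `k`,
`δ_k = max_{|I|=k} max(σ_max(A_I)² − 1, 1 − σ_min(A_I)²)`, is computed
exactly by enumerating all `C(N,k)` supports (capped at 10⁵; no convex
relaxations — exactness is the point when verifying a sufficient
condition). δ is non-decreasing in the order, which the tests assert on
every computed profile.

* **Noiseless.** `δ_2K < 0.5` certifies exact support identification: the
  pre-scan then contains at least one true index (the extreme correlations
  satisfy `κ ≥ (1−δ_2K)‖s_T‖/√K` on the support and
  `ζ ≤ δ_2K‖s_T‖/√K` off it), and the greedy completion of every true
  partial path selects only true indices while the zero-residual true
  support can never be pruned.
* **Noisy.** Support identification is certified when every nonzero
  satisfies `min_j |s_j| > γ‖v‖₂`, `γ = max(ν, μ, ω)` with

  ```
  ν = 2√(1+δ_K) / (√K (1 − δ_K − δ_2K))                       (pre-scan)
  μ = √2 (1+δ_K) √(1+δ_{K−1}) / ((1 − δ_K − δ_{2K−1}) √(1+δ_K²))   (completion)
  ω = √2 (1+δ_K) / ((1 − δ_2K) √(1+δ_K²))                     (non-pruning)
  ```

  Each constant multiplies the noise norm; all reduce to
  `max(2/√K, √2)` as the deltas vanish, and a bound whose denominator is
  non-positive is reported as unavailable rather than raised. **Caveat:**
  the closed forms of μ and ω pass through a projection-tail inequality
  (`‖s̄_{T∪Υ}‖ ≥ √(2(1+δ_K²))/(1+δ_K)·‖s_{T∖Υ}‖`) that is not valid in
  general — for orthonormal columns the left side equals `‖s_{T∖Υ}‖` while
  the claimed factor exceeds 1 — so μ and ω should be read as conventional,
  conservative certificate constants rather than sharp theorems. The
  Monte-Carlo harness treats them accordingly: it checks the certificate
  *empirically* (every draw satisfying `min_j|s_j| > γ‖v‖₂` on a
  `δ_2K`-certified dictionary must be exactly recovered) and has found no
  counterexample; the energy-split identity
  `‖s̄‖² = ‖s_{T∖Υ}‖² + ‖z‖²` is asserted instead of the invalid tail bound.

The harness also witnesses the correlation inequalities directly on every
draw (noiseless `κ/ζ` and stage-residual `λ_l/γ_l` bounds; noisy `ρ/η` and
`β_l/α_l` counterparts with the `√(1+δ)` noise inflation terms), counting
violations, which must be zero.

**Ensembles.** At exhaustively-checkable sizes the `±1/√M` Bernoulli
ensemble never satisfies `δ_2K < 0.5` (e.g. exact `δ₄ ≥ 1.58` across 200
seeds of 6×12 matrices): the sufficient condition is simply silent there,
and certified-recovery checks on that ensemble are vacuous. To exercise the
guarantee non-vacuously the harness offers a `perturbed_orthogonal`
ensemble — column-normalized `Q + ε·G` with Haar-orthogonal `Q`
(default ε = 0.1, `m = n`) — whose exact `δ_2K` lands in `(0, 0.5)` often
enough that certification, noiseless recovery, and the noisy `γ`
certificate are all genuinely tested.

## Synthetic data

`synthesize_sparse_ecg` draws exactly K-sparse DCT coefficient vectors:
support indices without replacement, by default biased toward low
frequencies with weights `exp(−4j/N)` to mimic the energy compaction of
real ECG (a uniform option exists and is used wherever a guarantee
quantifies over all K-sparse signals); nonzero magnitudes uniform on
[0.5, 2.0] with random signs — amplitudes of order one so that a 40 dB
measurement SNR is meaningful and no coefficient is negligible. What this
generator does **not** emulate: the approximation error of real windows
(its signals are exactly K-sparse, so the PRD floor is 0), baseline wander,
QRS morphology, quantization, or inter-lead structure. Passing tests
therefore demonstrate correctness of the recovery machinery and its
guarantees, not clinical reconstruction quality; the benchmark harness
accepts CSV windows (`data_source: "csv"`) for experiments on real records,
where the best-K-term PRD floor becomes strictly positive.

## Evaluation protocol

Metrics: exact-recovery ratio ERR (fraction of trials whose recovered
support equals the sparsified ground truth — on real windows the only
available ground truth is the K-term truncation of the window itself), PRD
`= 100·‖x̃−x̂‖₂/‖x̃−mean(x̃)‖₂` (scale-invariant, undefined for constant
references; a raw-ratio mode exists), its best-K-term lower bound, and the
compression ratio `(N−M)/N·100`. The benchmark sweep draws, per trial, a
fresh window, a fresh sensing matrix and fresh noise from a seed derived
from `(seed, m_index, trial_index)`, so records are reproducible and
solver-order-independent; runtimes are recorded but never asserted
(hardware-dependent).

Default sweep sizes (N=128, K=8, M ∈ {24,…,64}, 200 trials/point) keep the
whole suite and the acceptance script to a couple of minutes on one CPU
while leaving binomial standard errors around 2–3 percentage points —
comparisons between solvers are therefore made within two standard errors.

## Known limitations

* Exact RIC computation is exponential by design; orders beyond the 10⁵
  subset cap are refused, so certification is restricted to toy sizes.
* The early-stop bound can only shorten trials in which some full-size
  candidate actually reaches `c·N·σ²`; in regimes where recovery mostly
  fails (e.g. M = 3K) candidate counts with and without the stop coincide
  in most trials.
* Basis pursuit is implemented for the equality-constrained (noiseless)
  program; on noisy data it is still usable but inherits the equality
  constraint rather than a denoising formulation.
* The linear MMSE baseline's prior is a modelling choice, not a reference
  specification.
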