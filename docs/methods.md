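# Methods

This note documents the models, numerical choices and known limitations of
`dissopt` for users who need to judge what its results do and do not mean.

## Experimental design

The training corpus is a four-factor central composite design: a full 2⁴
factorial at coded levels ±1, eight axial points at ±α on one factor at a
time, and replicated center runs. The default specification — centers
(60 mg, 50 mg, 10 mg, 12 %), steps (30 mg, 25 mg, 5 mg, 4 %), α = 2, six
center replicates — spans the domain Methocel 0–120 mg, xanthan 0–100 mg,
Carbopol 0–20 mg, Surelease 4–20 % w/w in 30 runs with five levels per
factor. For k = 4 the rotatable axial distance (2⁴)^¼ happens to equal 2,
so the design is rotatable as well. Output order (factorial, axial,
center) is fixed for reproducibility; a seeded shuffle utility emulates
randomized manufacture order when needed.

Compositions are validated into this domain by default; the `check=False`
constructor escape exists for deliberate extrapolation experiments, since
a surrogate fitted on the design is only trustworthy inside it.

## Surrogate model

Architecture: 4 inputs → one hidden layer of H logistic-sigmoid nodes →
6 linear outputs, all data min–max scaled per dimension to [−1, 1] with an
exact inverse. Constant dimensions scale to 0 and invert to the constant.

Training is Levenberg–Marquardt on the scaled-target MSE with an analytic
residual Jacobian. Per epoch: compute J and the gradient Jᵀe; if its
infinity norm is below 10⁻⁷, stop (converged). Otherwise solve
(JᵀJ + μI)δ = −Jᵀe and accept the step only if the training MSE drops,
dividing μ by 10 on acceptance and multiplying by 10 on rejection
(μ₀ = 10⁻³, ceiling 10¹⁰; exhausting the ceiling also counts as
convergence — no descent step exists at any damping). Accepted-epoch
training MSE is therefore non-increasing by construction.

Records are split 67 % / 33 % at the formulation level — all six time
points of a record travel together, so no formulation leaks across
partitions — and 67 % of the non-training pool serves as the validation
monitor (20 / 7 / 3 records for the 30-run corpus, rounding half up).
Training stops at 800 epochs or after 200 consecutive epochs without a
validation improvement, whichever comes first, and the weights of the
best-validation epoch are restored. With LM convergence this fast, the
200-failure budget rarely triggers before substantial overfitting has
occurred — the best-checkpoint restore, not the stop itself, is what
protects generalization. Weight initialization is uniform [−0.5, 0.5]
scaled by 1/√fan-in, seeded.

Model quality is summarized per sampling time as the squared Pearson
correlation (R²) between predicted and observed release across records.
Zero observed variance makes R² undefined (reported missing); constant
predictions are reported as 0 with a warning so sweep tables stay total.
Held-out R² is evaluated on the pooled validation + test records (10 of
30): the 3-record test partition alone is too small for a stable
correlation, and neither partition contributes to the weight updates.

The hidden-layer size is chosen by trial and error: for each candidate H
(default 3–10), several networks are trained with distinct derived seeds
(fresh initialization *and* fresh partition per repeat), and the candidate
with the highest mean over time points of mean held-out R² wins, ties
going to the smaller network. The per-time-point table is always returned
so other selection rules can be applied. The chosen H is then retrained on
the full corpus (no held-out partitions; epoch or gradient stopping only)
to produce the network used for optimization.

## f2 similarity and optimization

f2 = 50·log₁₀(100·[1 + (1/n)·Σ(Rₜ−Tₜ)²]^(−1/2)) = 100 − 25·log₁₀(1 + msd).
It is symmetric, permutation-invariant over time points, equals 100 iff
the profiles coincide, and decreases strictly as any single gap widens.
All six sampling times enter by default; the regulatory convention of
truncating after the reference passes 85 % released is available as a
flag (`truncate_after_85`), as is the minimum-points requirement
(default 3). Out-of-range values are scored as given: raw surrogate
predictions may transiently leave [0, 100] and clipping them before
scoring would silently reorder candidates. Clipping is applied only when
profiles are reported or serialized.

Optimization enumerates the Cartesian grid min, min+step, … ≤ max per
factor (defaults: 5 mg / 5 mg / 2.5 mg / 2 %, i.e. 25·21·9·9 = 42,525
candidates, ~4 % resolution per axis — exhaustive search stays well under
a second with batched forward passes) and returns the f2-argmax with
first-in-enumeration-order tie-breaking, plus a ranked top-k audit list.
Batching is purely an implementation detail; results are identical to
one-at-a-time evaluation.

## Synthetic dissolution study

The real corpus exists only as published figures, so the package ships a
generative stand-in used by the tests and the examples. Release follows a
Weibull curve y(t) = 100(1 − e^{−(t/τ)^β}) — bounded at 100 %, concave
for β < 1, matching diffusion-controlled release of a soluble drug from a
hydrophilic matrix. The time scale responds log-linearly to the scaled
composition u ∈ [−1, 1]⁴:

τ = exp(a₀ + a₁u₁ + a₂u₂ + a₃u₃ + a₄u₄ + a₁₂u₁u₂),  β = β₀ + β₁u₁.

Positive a-coefficients make every excipient retard release monotonically;
the u₁u₂ interaction mimics joint HPMC/xanthan gelling. Defaults
(a = 1.135, 0.45, 0.325, 0.15, 0.225, 0.075; β₀ = 0.765, β₁ = −0.07;
noise sd 1 percentage point) were calibrated once so the noiseless 30-run
corpus spans 24.7–46.7 % released at 1 h and 82.4–99.0 % at 12 h — the
envelope reported for the real study — and are not meant to be adjusted
per experiment. The negative β slope makes polymer-rich formulations
flatter as well as slower, which is what holds their 12-h release near the
bottom of that envelope; it never overcomes the τ effect, so release
remains monotone non-increasing in every factor (worst case
|β₁·ln(t/τ)| ≈ 0.12 < β·(a₁ − |a₁₂|) ≈ 0.26). Noise is additive Gaussian
on the percent scale, clipped to [0, 100] and repaired to be
non-decreasing in time by a running maximum, since cumulative release
cannot fall.

The default synthetic reference product is the noiseless profile at
(45 mg, 30 mg, 5 mg, 10 % w/w), an in-domain point on the default grid;
the real reference product's profile was never tabulated, so any
in-domain composition is an equally arbitrary choice.

**What the generator does not emulate.** Replicate-level scatter (the
study reports mean profiles), tablet-to-tablet variability, pH-stage
effects of the dissolution protocol, and — most importantly —
identifiability: the Weibull family funnels all four factors through just
two kinetic parameters (τ, β), so entire surfaces of compositions share
one noiseless profile. A consequence users must understand: profile
matching is sharp (f2 ≈ 99 is routinely reached) but the *composition* of
the optimum is not unique — the optimizer legitimately returns any member
of the near-tie set, and tests of composition recovery against a planted
reference fail on distance even while the matched profile is essentially
exact. Passing pipeline tests therefore demonstrate profile-matching
ability, not composition identification; on real data, where different
excipients shape the curve in more than two independent ways, the search
may localize compositions better than this synthetic benchmark suggests.

## Problem sizes and determinism

The default test and example workloads use the 30-run corpus, node sweeps
over 3–10 nodes with 2–3 repeats, 800-epoch training limits and the
42,525-candidate grid; a full pipeline run takes a few seconds on one
core. Every random operation (noise, splits, initializations) derives
from one global seed through a fixed spawn scheme, and all stage artifacts
are written to disk so any stage can be rerun in isolation;
rerunning with the same seed reproduces numeric outputs byte-identically.
Model files are versioned JSON with full-precision decimal floats, so
save/load round trips are bit-exact.

## Known limitations

- LM forms JᵀJ explicitly; fine for networks up to a few hundred
  parameters, not intended for large architectures.
- The 200-validation-failure / 800-epoch protocol is retained for
  fidelity to the original workflow even though LM converges in far fewer
  epochs on this problem size; tighter budgets give the same models.
- R² with 10 held-out records is a noisy statistic; sweep decisions
  between adjacent node counts are not strongly determined and repeats
  should be increased when the choice matters.
- The f2 statistic ignores time-point correlation and measurement error;
  no confidence interval is provided.
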