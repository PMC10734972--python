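# Methods

## Model

**Fixed-effect contrast-based NMA.** The evidence is contrast-level: study
j's comparison of treatments a and b contributes an observed log odds
ratio y with known standard error, modelled as y ~ N(μ_ab, seTE²),
independent across rows. Under the consistency assumption every pairwise
effect is a linear combination of T−1 *basic parameters* (effects versus a
baseline treatment), so y ~ MVN(Xμ, S) with S = diag(seTE²) and X holding
one row per contrast: +1 in the column of `treat1` and −1 in the column of
`treat2` (baseline column omitted). The estimator is weighted least
squares, μ̂ = (XᵀS⁻¹X)⁻¹XᵀS⁻¹y with Var(μ̂) = (XᵀS⁻¹X)⁻¹, computed via a QR
factorisation of the weighted design; pairwise effects and SEs follow by
linear combination. The fit requires a connected comparison graph and is
invariant to the baseline (the default baseline, the lexicographically
smallest label, only fixes the internal parameterisation).

Multi-arm studies enter as multiple contrast rows sharing a `studlab`, and
S is kept diagonal: the within-study covariance between contrasts of a
three-arm trial is ignored. This is deliberate — it is exactly the stated
model — but it means the indirect SE of a network containing multi-arm
trials can differ slightly from implementations that adjust for those
correlations. On the empirical inputs shipped in the examples the SE was
produced by such an adjusting implementation; the design solvers take it
as a given number, so the difference does not propagate.

**Updating with the new trial.** Appending the new trial's contrast row
and refitting gives the *updated* estimate. For the comparison the new
trial makes, the refit obeys exact precision additivity,
1/σ²_uNMA = 1/σ²_trial + 1/σ²_eNMA (a rank-one information update;
verified to 1e−10 in tests), so the design formulas only ever need the one
scalar σ_eNMA from the existing network.

**Power.** Two-sided z-test of H₀: lor = 0 at level α (default 0.05,
z-quantile computed from α, not hard-coded). Both tails are kept:
Power = Φ(lor/sd − z) + Φ(−lor/sd − z), which equals α exactly at lor = 0.
Risks, group sizes and σ_eNMA are plug-in constants; no uncertainty is
propagated through them.

## Design solvers

Let a = 1/(p₁q₁), b = 1/(p₂q₂) (reciprocal binomial information per
subject), so σ²_trial = a/n₁ + b/n₂.

**Fixed total N (`ssanma`).** Minimising a/n₁ + b/(N−n₁) is convex in n₁
with continuous optimum n₁* = N√a/(√a+√b); the integer optimum is the
better of ⌊n₁*⌋/⌈n₁*⌉ (exhaustively verified). Ties go to the
higher-variance arm (smaller pq), preferring group 1 when equal. The split
is identical for the with- and without-network analyses, because the
network adds a constant to the precision; only the reported power differs.
Even allocation requires an even N (an odd N cannot be split equally; no
published case exhibits one, so it is an error rather than a silent
round).

**Target power (`ssnma`).** The target is inverted to a required sd by
Brent root-finding on the full two-term power formula (xtol 1e−15; the
second tail is negligible at typical settings but is part of the
contract), then to a required trial variance v (after subtracting the
network precision when analysing jointly), then to group sizes

    n₁ = ⌈√a(√a+√b)/v⌉,  n₂ = ⌈√b(√a+√b)/v⌉   (uneven)
    n₁ = n₂ = ⌈(a+b)/v⌉                        (even)

with **independent ceilings and no further refinement**. This convention
guarantees the power constraint but is not always the exact integer
optimum: because each group is rounded up separately, the total can exceed
the exhaustive-search minimum by one or two subjects (e.g. at risks
0.2/0.3, σ = 0.3, target 0.8 it returns 187+163 = 350 while the exact
integer minimum is 349 with power 0.8002). The convention is kept because
it is the one the published worked examples follow, and the package's
contract is to reproduce them; `oracle_grid` exposes the exact optimum
(per-n₁ enumeration with the minimal feasible n₂ computed by monotonicity)
for anyone who wants the last subject back, and the test suite pins the
gap at ≤ 2.

If the network alone already meets the target (required trial precision
≤ 0), the problem is degenerate: the minimum allocation (1, 1) is returned
with a warning and a `degenerate` flag rather than an error.

**Zero effect** (p₁ = p₂) makes any target power above α unattainable and
raises an infeasibility error (CLI exit code 3).

## Arm-level data and zero cells

Arm-level counts convert to contrasts by the Wald estimator
TE = log[(r₁/(n₁−r₁))/(r₂/(n₂−r₂))], seTE = √(Σ 1/cell) — identical to the
logistic-regression coefficient and SE for a saturated two-arm model. If
any of the four cells is zero, 0.5 is added to all four (Haldane–Anscombe);
the simulation protocols count how often this fires and log it per
scenario.

## Simulation protocols

Both protocols resample a synthetic network whose per-treatment risks and
per-arm sizes are specified up front; arm sizes stay fixed and event
counts are redrawn from Binomial(n_arm, p_treatment) each replicate, so
the network's indirect SE fluctuates realistically. The planned pair must
have no direct edge. The planned trial's risk for treatment B is derived
from A's risk and the scenario log odds ratio. Per replicate the planned
trial is drawn, analysed alone (Wald z-test) and by refitting the updated
network, and the closed-form powers/SEs are evaluated at the replicate's
fitted σ̂_eNMA; protocol II additionally re-solves the minimum-sample-size
problem per replicate with that σ̂. One root `SeedSequence` spawns a child
stream per replicate, so allocation strategies share the same resampled
network and runs are bit-reproducible.

The bundled example network (`example_network_spec`) is a star of four
treatments around an untreated control: control risk 0.68, active risks
0.19–0.30, 150 subjects per arm, three studies per planned-pair spoke.
These values emulate the shape of a published veterinary NMA (high-risk
untreated control, moderately effective treatments) and put the indirect
SE of the planned pair near 0.22, the order of magnitude seen in practice.
Default replication is 2000 per scenario — enough to resolve powers to
about ±0.03 at 3 binomial SEs while keeping a full protocol run in
seconds; 10⁴-replicate runs are a constructor argument away.

What the synthetic generator does *not* emulate: between-study
heterogeneity (the generator is exactly fixed-effect, so it validates the
formulas under their own model, not their robustness), multi-arm
correlation, and risk estimation error (risks are inputs, not pooled from
arm-level data). Passing tests therefore show internal consistency of
formulas and solvers, not real-data performance.

## Numerical notes and known limitations

* The Wald z-test with an *estimated* SE rejects slightly more often than
  the plug-in normal formula predicts — about one percentage point at a
  few hundred subjects per arm. With 2000 replicates this sits inside the
  Monte-Carlo band at moderate powers, but near power 1 the binomial SE
  shrinks below the bias and the discrepancy becomes statistically
  visible. It is a property of the normal approximation itself (published
  simulation tables of this design show the same-size gap) and fades as
  arms grow.
* Protocol II's achieved power hovers slightly above the target because
  each replicate solves with a noisy σ̂_eNMA and ceilings round up.
* The WLS information matrix is solved, never inverted explicitly; a
  singular system (effectively disconnected network) raises with a
  diagnostic rather than returning garbage.
* Out of scope: random-effects NMA, heterogeneity/inconsistency
  diagnostics, continuous outcomes, exact binomial power,
  continuity-corrected tests, cost-constrained designs, multi-arm new
  trials.
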