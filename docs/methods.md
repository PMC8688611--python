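# Methods

## Decay chain

The Ac-225 series is curated from evaluated nuclear data and shipped as a
text resource (`actlc/data/ac225_chain.tsv`):

| nuclide | half-life | decay | daughter(s) |
|---|---|---|---|
| Ac-225 | 9.92 d | α | Fr-221 |
| Fr-221 | 4.80 min | α (+218 keV γ) | At-217 |
| At-217 | 32.3 ms | α | Bi-213 |
| Bi-213 | 45.6 min | β 97.8% / α 2.2% (+440 keV γ) | Po-213 / Tl-209 |
| Po-213 | 3.7 µs | α | Pb-209 |
| Tl-209 | 2.16 min | β (+γ) | Pb-209 |
| Pb-209 | 3.23 h | β | Bi-209 (stable) |

Inventories evolve by the closed-form Bateman solution summed over
branch-expanded linear paths; the internal time unit is hours.  Nuclides
with half-life below a prompt threshold (default 1 s: At-217, Po-213)
are collapsed into their parent's decay and treated as in instantaneous
equilibrium — their *activity* equals the rate at which their parents
feed them.  Collapsing shifts downstream ingrowth by the prompt transit
delay (≈47 ms in mean-lifetime terms), so the collapsed solution differs
from the exact one by about `(d ln N/dt) × delay` — a few 10⁻⁴ relative
during the first tenths of an hour, under 10⁻⁷ late.  With the threshold
set to 0 the solver handles the full chain exactly; in that mode it
agrees with a stiff (Radau) ODE integration to ~10⁻¹¹ relative on a
0–48 h grid.  The test suite checks both statements.

Secular-equilibrium timing is defined on the activity ratio
`A_daughter/A_Ac` relative to its closed-form asymptote (for Fr-221,
`λ_F/(λ_F − λ_Ac)`), because the literature waiting times quote no
explicit criterion: the reported time is the first time the ratio comes
within a stated relative tolerance of the asymptote and stays there
(bisection on the analytic solution, resolution well under 0.1 min).
Under this definition Fr-221 (0.1%) equilibrates in ≈48 min, Bi-213 (1%)
in ≈5.2 h and Pb-209 (5%) in ≈15.5 h — inside the published 55 min /
6.5 h / 20 h waiting times.

## Plate model

A spotted aliquot is split at development start: the bound fraction *p*
of Ac-225 stays at the origin (S1, Rf 0.0–0.3, the product box); unbound
Ac-225 travels to the front (S3, Rf > 0.7) as its EDTA complex.  Spotted
daughters split element-wise by the chelator profile — DOTA-family
ligands hold Bi and Pb in solution (fraction 1.0 at 95 °C), macropa holds
none — bound daughters to S1, free ones to S3.  The aged stock carries
its daughters at secular equilibrium (`N_d = R_d λ_Ac/λ_d` per Ac atom);
the 1–15 min incubation is neglected.

During the development run (default 40 min, the middle of the 35–45 min
window) an atom born from a decay in S1 relocates at birth to S1:S2:S3
with fractions (1−m₂−m₃ : m₂ : m₃), defaults m₂ = m₃ = 0.05; atoms born
in S2/S3 stay where they are born.  The coupled decay–transport system is
linear with constant coefficients, so the run is solved exactly with a
matrix exponential on the (nuclide × section) state space; a small-step
event-ledger simulation in the test suite confirms the solution to its
own O(dt) accuracy.  After development the plate is dry: sections evolve
independently and a read at time *t* is instantaneous (the 2 min exposure
is short on every retained nuclide's timescale).

Detection weights per decay are α = 1.0, β = 1.0, with the γ that
accompanies some decays folded into its parent class at 0.1 (so
γ-accompanied classes weigh 1.1).  The screen is known to see the classes
with different efficiency but no values are published; these defaults are
pinned for reproducibility and configurable.  Measured RCP is the S1
signal over the total plate signal, the exact analogue of the printed
product-box/total-counts definition.

Consequences the model reproduces, with magnitudes the defaults imply:

* high-purity macropa preparations read low early (≈0.70 at 0.5 h for
  p = 1) because the spotted equilibrium load of Bi-213 and Pb-209 sits
  at the solvent front while the origin's own daughters regrow;
* low-purity DOTA preparations read high early (≈0.29 at 0.5 h for
  p = 0.03) because the chelated Bi/Pb load sits in the product box;
* DOTA high-purity preparations show only the few-percent migration gap;
* the bias decays with the spotted excess: the mid-purity DOTA cluster
  (0.50–0.75) reads within 5 pp of truth from the 3.5 h read, and all
  reads converge to within 0.5 pp of the 26 h value from ≈18 h (the
  Pb-209 excess, half-life 3.23 h, is the last to clear);
* at 26 h the read recovers p to within 1 pp for any composition.

## Synthetic study

The generator reproduces the published design: 11 conditions — RPS-072
(DOTA 9.0 µM, 95 °C), RPS-074 (macropa 8.9/0.89/0.089 µM, 25 °C), RPS-088
(macropa 10.4/1.04/0.104 µM, 25 °C), RPS-092 (macropa 8.4/0.84 µM,
25 °C), EuK-106 (18.2 µM, 95 °C), EuK-107 (20.0 µM, 95 °C) — × reaction
times {1, 5, 15} min × 3 replicates = 99 sets, each read at 0.5, 2, 3.5,
5, 6.5 and 26 h.  Latent labeling fractions are truncated-normal draws
whose means/spreads are anchored to the printed condition summaries
(98.8 ± 0.09% → RPS-074 8.9 µM at 1 min; 24.8 ± 2.36% → EuK-106 at
15 min; 93.2 ± 1.21% → RPS-072 at 15 min; 11.2 ± 5.25% → the dilute
RPS-074 stratum at 15 min); unprinted cells are interpolated so that
means are nondecreasing in incubation time, the three purity clusters
(>85%, 50–75%, <40%) all occur, and the dilute ~0.1 µM stratum is highly
variable (replicates spanning roughly 6–92%).  Counting noise draws the
three section signals as independent Poisson counts with an expected
5,000 counts per plate (phosphor exposures are count-limited; no counts
are published) and recomputes the ratio.  The design yields 594
observations; the published dataset has 585 for unstated reasons, so the
generator is complete by default with an optional dropout knob.

What the generator does *not* emulate: chemistry kinetics (yields are
drawn, not reacted), plate-to-plate development variability, lane-shape
artifacts, and any correlation of noise across reads of one plate.
Passing tests therefore demonstrate the statistical machinery under the
stated physical model, not radiochemical ground truth.

## Prediction model

One modeling row per (set, pre-equilibrium read): response `Y` = the
set's 26 h read (true RCP), regressors `t`, `y`, `t·y`.  Because `Y` is a
fraction, not a binomial count, the GLM is quasi-binomial: logit link,
IRLS (statsmodels) with prior weights — 10 for rows with `Y ≥ 0.9`, 1
otherwise — and dispersion estimated from the Pearson χ².  The 99 sets
are split 66/33 at the set level (uniform, seeded); other counts fall
back to 2:1 with a warning.

Prediction intervals are nonparametric: resample the 66 training sets
with replacement, refit, push the query through each refit, add a
residual resampled from the base fit's response-scale residuals, and take
the 2.5/97.5 percentiles, clipped to [0, 100]% (B = 2000 by default;
seeded).  This reproduces the qualitative widening of the published
intervals at the table's endpoints and achieves ≈0.97 coverage of the
true equilibrium value on simulated queries.  The prediction-table export
uses the published grid (measured 0–90% by decades, then 91–100% by 1) ×
read times {0.5, 2, 3.5, 5, 6.5} h, rounded half-up to integer percent.

Numerical notes: IRLS runs to a 1e-10 tolerance (≤100 iterations) and a
fit that fails to converge or returns non-finite coefficients raises
rather than returning garbage; the logit-linear model class is recovered
exactly (to ≤1e-8) when the data obey it, but a general monotone read→
truth mapping is *not* logit-linear, which leaves a few pp of
irreducible approximation error in mid-purity regions.  The chelator
identity is deliberately not a model feature (matching the published
model), so mid-purity macropa and DOTA reads are structurally ambiguous —
the main driver of per-stratum MAE on synthetic data (≈5.0 pp worst
stratum ≥2 h at the default seed, 7.9 pp at 0.5 h).

## Release classification and advice

Random forests (500 trees, one candidate feature per split, unlimited
depth, seeded) are trained on `(t, y)` against labels `Y ≥ τ` for
τ ∈ {0.90, 0.95}; predicted probability is the tree-vote fraction, AUC is
the trapezoid rule over the validation ROC, and the 95% CI is a
stratified bootstrap (resampling within classes; B = 2000) — chosen over
asymptotic formulas because the AUC sits near 1.  The confusion table is
reported at the conventional 0.5 vote cut.

The advisor ships the published calibration grid verbatim as
`actlc/data/calibration_table.tsv` (20 measured levels × 5 read times;
loading validates the shape, interval ordering and monotonicity and fails
loudly otherwise).  Lookups interpolate linearly in the measured
direction only — the time columns come from distinct model strata — and
round half-up.  Decisions: release iff interval lower bound ≥ threshold,
reject iff upper bound < threshold, hold otherwise; defaults follow the
published discussion (95% release threshold; the 90% guarantee also
holds: every entry above 90% measured at 2 h has expected ≥ 97% and lower
bound ≥ 90%).  Reads at ≥ 20 h are equilibrium reads: the measurement is
returned at face value with a degenerate interval, flagged as such, since
the published table intentionally has no 26 h column.

## Problem sizes and determinism

The default analyses run at the study's own scale: 99 sets (594
observations), 500-tree forests, bootstrap B = 2000 for shipped
intervals (tests and the acceptance script use 200–500 replicates, which
stabilize the percentiles at the reported precision).  Every stochastic
step takes an explicit seed and identical seeds give byte-identical
outputs, including the generated observation tables.

## Known limitations

* Detection efficiencies, migration fractions and the counting scale are
  pinned defaults, not measured values; absolute early-read biases (for
  example the ≈0.70 read of a pure macropa preparation at 0.5 h) scale
  directly with them.
* The calibration table is transcribed from the publication; the advisor
  treats its intervals as given and does not regenerate them.
* Equilibrium timings are criterion-dependent; the tolerances (0.1%, 1%,
  5%) are stated choices, not published definitions.
* Chains other than Ac-225 are supported structurally (any rooted acyclic
  branched chain ending in a stable nuclide) but no other nuclear data
  are curated.
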