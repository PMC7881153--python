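# Methods

## Model and assumptions

The core object is a competitive binding equilibrium: one pool of active
(GTP-bound) Ras shared mutually exclusively by a panel of effectors.  The
model is stationary — it describes the steady state of the mass-action
dynamics `R + E_i <-> RE_i`, not their time course — and deliberately
omits GDP/GTP cycling, GEF/GAP regulation, and any downstream catalysis.
The GTP load enters as a scenario parameter (fraction of each isoform's
total abundance that is active), not as a solved quantity.

Assumptions worth making explicit:

- **One shared Kd per effector across HRAS/KRAS/NRAS.**  The three
  isoforms are pooled into a single active species before solving; each
  complex is then attributed to isoforms in proportion to their active
  abundances.  An explicit 3×n model with identical per-isoform Kd is
  algebraically equivalent, so the pooling loses nothing while keeping the
  solve one-dimensional.  Percentage normalization happens on the pooled
  complexes; the isoform split is applied afterwards and is purely
  proportional.
- **Well-mixed concentrations in nM.**  All spatial effects are absorbed
  into effective affinities; membrane recruitment is modeled as an
  affinity enhancement (below), not as an explicit compartment.
- **Mutants change only the GTP scenario.**  Effector abundances are held
  at reference values across wild-type, mutant, and stimulated scenarios.
  Mutant levels above 1 (up to 1.5) model copy-number gain: the active
  amount of the mutated isoform then exceeds its wild-type total.

## Equilibrium solver

Substituting each effector's conservation into the Ras balance gives a
scalar equation `f(R) = R + Σ R·E_iT/(Kd_i+R) − R_T` whose left side is
strictly increasing in R, so the root in `[0, R_T]` exists, is unique, and
is found by Brent's bracketed method (relative tolerance at machine level,
iteration cap 200; a residual above 1e-9·R_T raises rather than returning
a degraded state).  Degenerate inputs short-circuit: zero active Ras or an
all-zero panel yields the all-zero state, and zero-abundance effectors are
retained with exactly zero complex so that downstream sensitivity of
absent effectors is exactly 0.

An ODE oracle (`ode_equilibrium`) integrates the mass-action dynamics with
a shared on-rate of 1 /nM/time-unit and per-pair off-rate `Kd(nM)·k_on`
until the largest relative derivative falls below 1e-10, doubling the
horizon as needed.  Only the ratio k_off/k_on is observable at steady
state, so the choice of k_on is immaterial (and tested to be).  The oracle
exists purely as an independent cross-check; the production path never
integrates.

Units: everything internal is nM.  Kd values enter files and constructors
in µM (the natural unit of the measured affinities, spanning 0.04–39 µM)
and are converted exactly once at the boundary (×1000).

## Receptor-mediated (piggyback) recruitment

A stimulus adds a receptor species Y (abundances of its receptor proteins
summed — for EGF, EGFR+ErbB2) that binds a designated set of effectors via
a secondary domain with Kd `K_YE` (default 1 µM), and the ternary complex
forms with a 100-fold enhanced Ras affinity:

    Y + E_j  <-> YE_j      K_YE
    R + YE_j <-> RYE_j     Kd_j / α          (α = 100)
    Y + RE_j <-> RYE_j     K_YE / α          (fixed by cycle closure)

The fourth edge's constant is not a free parameter: thermodynamic
consistency of the binding cycle forces
`K(Y+E)·K(R+YE) = K(R+E)·K(Y+RE)`, and the implementation derives it
rather than accepting independent rates.  Eliminating each targeted
effector's free concentration leaves conservation equations for free R and
each free Y that are monotone in their own unknown; the joint solve is a
damped fixed point (damping 0.5) over bracketed 1-D root-finds, converged
when the largest relative change falls below 1e-10, followed by one
undamped pass so each balance closes to solver tolerance.  With the inner
solves exact, convergence takes a handful of sweeps for the one or two
receptor species that occur in practice.  A full-network ODE oracle
(`ode_piggyback`, integrating all four edges) cross-checks the solution.

Stimulated scenarios use a 90% GTP load; the unstimulated comparator for
fold factors is re-solved at 20% GTP with no recruitment.  Fold factors
compare nM complex concentrations (RE + RYE per effector, or class sums);
a zero unstimulated pool with a positive stimulated pool is reported as an
explicit infinity rather than a capped value.  Overlapping stimuli
targeting one effector contribute additive YE/RYE terms.

## Sensitivity analyses

Local: each Kd is moved to 0.9× and 1.1× its reference (others fixed), the
equilibrium re-solved, and `ΔC` reported as the absolute difference of the
effector's complex share (percentage points) alongside `ΔC/ΔKd`.  Shares
are the primary output; nM deltas are emitted as well.  Global: the Kd is
swept over 81 evenly spaced points from 0.04 to 39 µM, making the first
(steepest) interval [0.04, 0.527] µM, whose share difference is the
summary statistic.  Only one-at-a-time variation is implemented: with 56
interacting parameters a factorial design would be both expensive and
uninterpretable, and the competitive structure makes the one-at-a-time
response the quantity of biological interest (robustness to error in one
measured affinity).  The heatmap-style outputs report absolute ΔC; the
sign is preserved in the records.

## Rewiring scores and the sweet-spot fit

`RS = tot complexes(mutant scenario) / tot complexes(WT scenario)`, with
the mutated isoform's active fraction set to the mutant level and the
other two at 0.2.  RS is dimensionless, equals 1 exactly when the mutant
level is 0.2 (the scenarios coincide), and is strictly increasing in the
mutant level because total binding is monotone in active Ras.

Mutation frequency vs RS is fitted with a 3-parameter Gaussian
`A·exp(−(rs−μ)²/2σ²)` by unweighted least squares with deterministic
moment initialization (μ₀ = frequency-weighted mean of rs, σ₀ = weighted
sd floored at 1e-3, A₀ = max frequency), bounds A ≥ 0 and σ ≥ 1e-6, and
tight convergence tolerances (1e-15) so noiseless recovery is exact to
1e-6.  Fits exclude the nine tissues rarely associated with cancer
(appendix, fat, heart, fallopian tube, placenta, smooth muscle, small
intestine, spleen, tonsil); PanRas fits pool all isoform points, and
isoform-specific fits are independent 3-parameter fits (no amplitude
sharing).  Where two source studies exist for one tissue, the input table
is expected to carry a single frequency per (tissue, isoform); combining
studies is the table author's concern.

## Landscape analysis

For a solved tissue, every effector at the same Kd lies exactly on a line
through the origin in the (abundance, share) plane with slope
`100·R*/((Kd+R*)·C_tot)` — this identity is the module's primary oracle,
and both the shared-Kd OLS fits and the singleton through-origin fits must
reproduce it to 1e-9.  Singletons whose share falls below 0.001% are
skipped (an absent effector's line is uninformative); the threshold is the
`min_fit_pct` argument.  Shared-Kd grouping uses exact value equality;
interval bins ([0.04,0.09], [0.21,1], [2.9,50] µM) are used only for
summary reporting.  Surface grids for plotting are piecewise-linear
evaluations of the analytic lines, since the surface is an interpolation
artifact rather than a model object.

Key effectors are those whose share reaches 5% (inclusive) in at least
one tissue at the stated scenario.

## Classification

Group 1 requires ≥5% share in ≥1 tissue unstimulated (20% GTP, reference
Kd).  The "enhanced" condition for Group 2 is operationalized as all
affinities divided by the piggyback factor 100 at a 90% GTP load — the
regime the global sensitivity analysis explores — because the grouping
rule keys on threshold outcomes, not on which domain does the recruiting.
Domain annotations are recorded as evidence, and a strict mode
(`require_domain=True`) additionally gates Group 2 on an annotated
recruitment domain (SH2/PDZ/PH/C1/C2).  Because higher GTP loads admit
extra effectors past the threshold, the package reports the 20%-GTP key
set and leaves any elevated-load set to the caller's scenario choice.

## Tissue composition

Per subtype, the three markers with the highest mean expression across
tissues are selected (ties broken by name; `statistic="max"` is available
as an alternative aggregation), a tissue's subtype score is the mean of
those three, and scores are normalized to percentages per tissue.  Output
is invariant to marker order and to global rescaling of the expression
table.  Marker lists ship as an editable CSV fixture; only the lymphoid
trio (PTPRC, CD68, CD19) is a fixed, well-established reference set.

## Synthetic study conditions

The generator reproduces the structure the analysis assumes, not any real
tissue's values:

- Panel: the real 56 effector names and 12-class memberships, the real
  SH2 set (RIN1/RIN2/RIN3/GRB7/GRB10/GRB14) and PDZ set
  (MLLT4/SNX27/TIAM1/TIAM2/RAPGEF2/RAPGEF6/RADIL/RGS12), and the known
  reference affinities (ARAF 0.07, MLLT4 3.03, SNX27 10, and 7.5 µM for
  PIK3CD/ARAP1/RADIL/MYO9A) regardless of seed.  Unanchored Kd's are
  sampled log-uniformly, with a 25% chance of falling in the high-affinity
  decade (≤1 µM) — high-affinity effectors are the minority of the real
  panel.  Non-SH2/PDZ effectors receive a PH/C1/C2 tag with probability
  0.3.
- Tissues: the 29 real tissue names; effector abundances log-normal with
  ln-mean 3.0 (≈20 nM median) and ln-sd 1.0, which spans the ~50-fold
  cross-tissue variation seen for well-expressed effectors; Ras totals
  log-normal around 100/400/100 nM (H/K/N) with KRAS forced dominant,
  except a pancreas-like tissue with equal thirds; receptor abundances
  log-uniform in 5–200 nM.  When the competition flag is set (default),
  effector sums are rescaled to exceed twice the active Ras pool at 20%
  GTP, so every tissue sits in the competitive regime.
- Mutation frequencies: `A·exp(−(rs−μ)²/2σ²) + N(0, sd)` truncated at 0,
  with truth (A=30%, μ=2.0, σ=0.3) and noise sd 1.5 (5% of A) recorded
  alongside for recovery tests.
- One seeded generator per artifact (panel, tissues, frequencies, offset
  from the config seed) makes every output bit-reproducible.

What the synthetic data do **not** emulate: correlated abundances between
functionally related effectors, tissue-specific effector clustering, the
real panel's exact Kd multiset, mRNA-protein discordance, and measurement
noise.  Passing tests on synthetic data therefore demonstrate the
correctness and internal consistency of the machinery — conservation,
oracle agreement, identities, recovery — not agreement with published
tissue-level numbers, which requires the original input tables.

## Problem sizes and runtimes

The test suite solves 29–100 synthetic tissues of 56 effectors per
scenario (each solve is a single bracketed root-find, well under a
millisecond), compares 500 random ≤10-effector panels against the ODE
oracle, and runs 200 replicate Gaussian fits; the whole suite completes in
a few seconds on one core.  The acceptance script uses 200 oracle panels
and the full 29-tissue pipeline.

## Known limitations

- Receptor activation is not modeled: a stimulus is "on" as a receptor
  abundance plus a recruitment rule, with no ligand binding or kinetics.
- The enhancement factor α = 100 is a literature-level effective value,
  not fitted; fold factors scale with it roughly linearly for weakly
  bound targets.
- Rank changes between scenarios are sensitive to near-ties; the
  deterministic name tie-break makes them reproducible but arbitrary at
  exact equality.
- The classification's enhanced condition boosts all effectors uniformly;
  the strict domain-gated mode is closer to mechanism but depends on the
  completeness of domain annotations.
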