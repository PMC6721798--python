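# Methods

This note documents the models implemented in `ftlrep`, their assumptions,
the defaults and why they were chosen, and what the synthetic-data
generators do and do not emulate.

## Exclusive-binding occupancy model (`ftlrep.occupancy`)

**Model.** The *FTL* transcript pool is partitioned into IRP-bound (x₁),
eIF3-bound (x₂) and free (x₃) states with translational efficiencies y₁,
y₂ and 1. Mutations are assumed to abolish the targeted factor's
regulation completely (the mutated site's y reverts to 1) and to
redistribute a fraction (α for the eIF3 site, β for the IRE loop) of the
released pool, with 0 ≤ α + β ≤ 1. The raw predictions for the four
reporters (wild type, Δ3RE, Loop, Double) follow directly; dividing by the
wild-type readout eliminates x₃ via x₃ = 1 − y₁x₁ − y₂x₂ and gives the
reduced three-equation system whose residual identity

Double − Loop − Δ3RE = α + β − y₁α − y₂β − 1 ∈ [−1, 0]

is the entire content of the feasibility test: exclusive binding requires
Double ≤ Loop + Δ3RE.

**Normalization convention.** The x fractions in the reduced model are
expressed in wild-type-normalized readout units, which is why they are not
forced onto the simplex there: the elimination x₃ = 1 − y₁x₁ − y₂x₂ is
algebraically incompatible with x₁ + x₂ + x₃ = 1 once mutant readouts
exceed 1. We therefore enforce the simplex only on parameter sets
constructed with an explicit x₃ (used by `predict_raw` and the
generators), and let reduced-model parameter sets omit x₃. This reproduces
the reduction as derived rather than silently reconciling the two
conventions.

**Error propagation.** The reported "±" values are treated as standard
deviations of the mean readouts (the source does not distinguish SD from
SEM; replicate counts are 3–6). Measurement error is propagated by Monte
Carlo: each construct mean is resampled independently from a normal with
its SD, truncated at zero by resampling (luminescence cannot be negative),
and `p_consistent` is the fraction of draws with Double ≤ Loop + Δ3RE.
Defaults: 100,000 draws (≈0.1% Monte-Carlo error on p), seed 2019.
A Gaussian-propagation z-score is reported alongside; "inconsistent" is
declared at p < 0.05, with the point test using the strict analytic bound.

**Constrained inversion.** `fit_exclusive` minimizes the SD-weighted
squared residual of the reduced predictions over the box
x₁, x₂ ∈ [0, 50], y₁, y₂ ∈ [0, 1], α, β ≥ 0, α + β ≤ 1 (the x upper bound
comfortably covers 40-fold derepression at any y < 1). The 6-dimensional
problem is non-convex, so 32 SLSQP runs are started from a seeded Latin
hypercube; ties are broken by χ² then lexicographic parameter order.
Feasibility is declared when the minimized χ² is below the 95th percentile
of χ²(3). Because the parameter→readout map is not injective, only the
predicted outputs are identifiable — parameter values in the report are
one minimizer, not an estimate.

## Competition EMSA kinetics (`ftlrep.kinetics`)

**Scheme.** Simple competitive bimolecular binding, R* + P ⇌ R*P and
C + P ⇌ CP, with a shared free-protein pool; the competitor appears at the
end of the pre-incubation. Free species are eliminated through the
conservation laws, so the integrated state is just the two complex
concentrations and mass conservation is structural. Heparin (present
experimentally as a nonspecific-competitor) is not modeled — no kinetic
parameters exist for it. Integration uses LSODA with rtol 1e−9 and
atol 1e−15 M; negative concentrations beyond tolerance abort with an
error.

**Defaults.** 300 pM labeled RNA, 225 nM IRP1, 30 min pre-incubation,
18 h competition (duration 1110 min), k_off = 0.006 min⁻¹ (the measured
value), and k_on = 10⁶ M⁻¹min⁻¹ — not measured; chosen so the
pre-incubation reaches well over 95% of equilibrium at the protocol
concentrations (k_on·[P] ≈ 0.23 min⁻¹, ≈7 association time constants in
30 min). Competitor rate constants default to the labeled-RNA values.
An optional `inert_fraction` freezes part of the labeled complex at
competitor addition to emulate a non-exchangeable residual; it defaults to
0 and is speculative — the observed ~15% residual is equally consistent
with slow exchange.

**k_off estimation.** Nonlinear least squares of
F(t) = F∞ + (F₀ − F∞)e^(−k_off·t) on the post-competitor segment.
The fit is flagged failed for flat courses, non-positive rates, or decay
amplitudes within 3× the residual noise. At 100,000-fold competitor the
re-binding term k_on·[P_free] ≈ 5·10⁻⁴ min⁻¹ biases the apparent rate by
under 1%; at lower excess the bias grows, which is why dissociation
courses are generated at the top of the published competitor range.

**Equilibrium checkpoint.** `equilibrium_reached` compares the bound
fraction at the two nearest sampled times with an absolute tolerance,
default 0.02 — below the resolution of gel densitometry. At
k_off = 0.006 min⁻¹ (t½ ≈ 115 min), 11 h is ≈5.7 half-lives, so the
11 h vs 18 h checkpoint passes as observed experimentally.

**IC50.** Four-parameter logistic on log₁₀(fold-excess), IC50 = inflection
dose. The asymptotes are constrained by default to the physical
bound-fraction range [0, 1]: the published dose window starts at
1,000-fold excess, which is already near the half-point of the transition,
leaving the top plateau under-determined — an unconstrained top drifts
above 1 and drags the inflection with it. With the unit-interval prior the
fitted IC50 agrees with a dense-grid bisection for the halfway dose to
better than 1%. For responses in arbitrary units pass
`asymptote_bounds=None`; IC50 is then invariant to uniform rescaling of
the response axis whenever the bounds are inactive. Curves with fitted
amplitude below max(3× residual scale, 0.02) are reported "IC50 not
determinable", mirroring a competitor that has lost binding entirely (the
IRE Loop mutant).

## 5ʹ-UTR element map (`ftlrep.elements`)

Coordinates are 1-based inclusive on the mature 5ʹ-UTR (+1 = annotated
transcription start). Defaults: PAR-CLIP site [53, 76], 3RE [58, 90],
IRP loop contacts {15, 16, 17}, C bulge {18}; cap-to-IRE distances 32 nt
(native) / 70 nt (extended); steric threshold 60 nt with *strict*
inequality (IRP further than 60 nt from the cap only partially blocks 43S
loading). The IRE 3ʹ end is fixed at nt 57 (five nt into the PAR site) but
its 5ʹ start must be configured — annotations differ and no default would
be authoritative. Cap distances are stored as construct metadata rather
than derived from C18's UTR coordinate because reporter constructs carry
vector-derived 5ʹ sequence of unknown length; the two coordinate systems
cannot be reconciled from published information.

Construct editing applies non-overlapping deletions/substitutions plus an
optional 5ʹ insertion in a single pass over reference coordinates,
validates reference bases (U/T equivalent, output alphabet follows input)
and returns a complete old→new lift-over table; unedited positions
round-trip to their original base, and composing edits in separate passes
equals the single-pass result.

## Synthetic data (`ftlrep.simulate`)

**Reporter tables.** Construct means come from the exclusive model
(`predict_raw`), from a four-state co-binding alternative, or directly
from fold targets (default: the published 38-fold Δ-PAR and six-fold Δ3RE
derepressions). Replicates are mean × LogNormal with unit expectation at
the requested CV (default 10%, a typical day-to-day spread for transfected
luciferase assays), then renormalized so the sampled WT mean is exactly 1.
The co-binding rule — doubly-bound mRNA translates at y₁·y₂ (configurable
to min(y₁, y₂)) — is an explicit generator assumption; no measured
co-binding mechanism exists.

**EMSA tables.** Time courses and dose-response series come from
`simulate_competition` plus additive Gaussian noise clipped to [0, 1]
(default 2%, roughly gel-quantification error).

**What this does and does not show.** Passing recovery tests demonstrates
that the estimators are unbiased and the pipeline is self-consistent under
the stated noise models. They cannot validate the noise models themselves:
real luciferase data have between-day batch structure and transfection-
efficiency covariance between constructs, and real gel data have
band-overlap and background artifacts, none of which are emulated. The
synthetic UTR sequence reproduces only the coordinate landmarks (A15, G16,
U17, C18, G51, G52) of the real 5ʹ-UTR, not its sequence or structure.

## Problem sizes

Defaults throughout are the full study conditions: 100,000 Monte-Carlo
draws, n = 100 synthetic replicates per construct, 49-point 8-h
dissociation courses with 50 noise replicates, and 13-dose competition
series; the complete test suite and the acceptance script each run in
seconds on one core.

## Known limitations

- The exclusivity test treats construct readouts as independent; shared
  transfection batches would correlate them and widen the true error.
- No thermodynamic link is made between EMSA affinities and the occupancy
  fractions x₁/x₂ (deliberately out of scope).
- IC50s are reported in fold-excess units, matching how competition data
  are plotted; conversion to absolute concentration requires the labeled
  RNA concentration and is left to the caller.
- `fit_exclusive` reports one χ²-minimizing parameter set; the parameter
  posterior is ridge-shaped and individual parameter values should not be
  interpreted.
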