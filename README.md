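# ftlrep

Quantitative analysis of **dual translational repression of ferritin light
chain (*FTL*) mRNA**. Translation of *FTL* is controlled by two repressors
binding adjacent elements in its 5ʹ-UTR: iron regulatory proteins (IRPs) at
the iron-responsive element (IRE), and eIF3 at a repressive element (the
"3RE", nt 58–90, overlapping the eIF3 PAR-CLIP site at nt 53–76). This
package is for researchers in post-transcriptional gene regulation who want
to (a) test whether reporter data are compatible with the two repressors
acting *mutually exclusively*, (b) analyze competition gel-shift (EMSA)
experiments for dissociation rates and IC50s, and (c) relate
hyperferritinemia-associated 5ʹ-UTR variants (e.g. G51C, G52C) to the
regulatory elements.

## The model

Under exclusive binding, the mRNA pool splits into three states — IRP-bound
(x₁), eIF3-bound (x₂), free (x₃) — translating with efficiencies y₁, y₂ ∈
[0, 1] and 1. Disrupting the eIF3 site redistributes a fraction α of its
pool; disrupting the IRE loop redistributes β, with 0 ≤ α + β ≤ 1.
Normalizing the wild-type reporter output to 1 eliminates x₃ and yields,
for the Δ3RE, Loop and Double (Δ3RE + Loop) reporters:

```
Δ3RE   = 1 + y₁α − α + (1 − y₂)x₂
Loop   = 1 + y₂β − β + (1 − y₁)x₁
Double = Loop + Δ3RE + (α + β − y₁α − y₂β − 1)
```

The bracketed term is bounded in [−1, 0] over the whole constrained
parameter space, so exclusive binding requires **Double ≤ Loop + Δ3RE**.
Measured readouts violating this bound — as the published values
41.8 ± 6.5 vs 12.5 ± 2.9 + 4.4 ± 0.4 = 16.9 ± 2.9 do — falsify the
hypothesis and imply that IRP and eIF3 can repress the same transcript in
cis. The package propagates the measurement SDs by Monte Carlo and also
exhibits the best constrained fit (`fit_exclusive`) with a χ² feasibility
check.

The EMSA module simulates the two-phase competition protocol (300 pM
labeled RNA + 225 nM IRP1, 30 min pre-incubation, then 1,000–100,000-fold
unlabeled competitor for 18 h) as mass-action competitive binding with a
shared protein pool, estimates k_off from post-competitor decay
(F(t) = F∞ + (F₀ − F∞)e^(−k_off·t)), checks equilibrium between two
time points, and fits four-parameter logistic dose-response curves on
log₁₀(fold-excess) for IC50.

## Worked example

Test the published reporter readouts against the exclusive-binding model:

```sh
cat > readouts.csv <<EOF
construct,mean,sd,n
FTL,1.0,0.0,6
D3RE,4.4,0.4,6
LOOP,12.5,2.9,6
DOUBLE,41.8,6.5,6
EOF
ftlrep test-exclusivity --readouts readouts.csv --draws 100000 --seed 2019 --out verdict.json
```

prints

```
feasible Double range: [15.9, 16.9]
point_consistent=False p_consistent=0.00024 z=3.493 -> inconsistent
exclusive binding rejected: IRP and eIF3 likely act in cis
```

i.e. the measured Double derepression (41.8-fold) exceeds the largest value
the exclusive model can produce (16.9-fold); in only 0.024% of
error-propagation draws does the inequality hold (z ≈ 3.5), so the model is
rejected. The full demo pipeline — synthetic reporter table at the
published effect sizes, exclusivity test, k_off re-fit, IC50 fit and
variant annotation — runs with

```sh
ftlrep run --config examples/pipeline.yaml
```

and ends with a summary like

```
exclusive-binding model vs reporter data: Double mean 42.5 vs feasible upper bound 18.9; p_consistent = 0 (inconsistent)
k_off re-fit from simulated dissociation course: 0.005942 min^-1 (true 0.006)
IC50 of simulated WT competition: 1481-fold excess
G51C: 2 nt upstream of PAR
G52C: 1 nt upstream of PAR
A15G: inside LOOP
G16C: inside LOOP
```

Library use mirrors the CLI: `ftlrep.exclusivity_test`, `fit_exclusive`,
`simulate_competition`, `fit_koff`, `fit_dose_response`,
`annotate_variant`, `apply_construct`, and the generators in
`ftlrep.simulate`.

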