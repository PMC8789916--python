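# Methods

This note documents the models implemented in `hotbio`, their assumptions,
the defaults and why, and what the synthetic data generator does and does
not emulate.

## Radiotracer turnover rates

A slurry incubation partitions an injected radiolabel between the
substrate pool and the product pool; assuming the tracer addition does not
perturb the pool and turnover is small over the incubation, the volumetric
rate is the labelled fraction times the pool inventory per unit sediment
volume and time,

    rate = A_p / (A_p + A_s) · pool · α · ρ / (t · m),

reported in pmol cm⁻³ d⁻¹ of wet sediment (sediment volume = m/ρ). The
isotope fractionation corrections default to α = 1.06 for ³⁵S sulfate
reduction and 1.08 for ¹⁴C methanogenesis and are per-vial overridable;
the AOM layout reuses the same arithmetic with ¹⁴CO₂ as product and
¹⁴CH₄ as substrate. Activities are accepted as pre-converted Bq; a
counting-efficiency helper is provided but defaults to pass-through, since
counting efficiencies are instrument-specific and not part of the model.
The pool inventory combines the medium (e.g. 5 mmol L⁻¹ sulfate or
0.677 mmol L⁻¹ DIC in 5 mL) with the porewater contribution
(concentration × porosity × sediment volume); tracer-added moles are
excluded by default as negligible.

**Detection limits.** The minimum biological quantification limit is the
mean of the killed (γ-irradiated) control rates plus three standard
deviations. The SD convention defaults to the sample (n−1) estimator and
is switchable to the population form; the choice moves the limit by a few
percent at typical n ≈ 3–6. Rates strictly below the MBQL are flagged
censored — values are preserved, never deleted, so the flag is
reversible. A consistency report checks that each non-medium control mean
lies within one SD of its assay's medium control.

A caution on the limit statistic: mean + 3·SD is *not* monotone in every
individual control value (raising a value far below the mean shrinks the
SD faster than it lifts the mean), which is why the tests assert
shift/scale equivariance and monotonicity in the largest value instead.

## Sulfate diffusion and budget

Post-burial diffusive exchange with the overlying sulfate-depleted section
is modelled as one-dimensional diffusion into a half space with a
zero-concentration boundary (600 mbsf), uniform initial concentration,
constant free-solution diffusivity D = 0.054 m² yr⁻¹ and tortuosity
θ² = φF = 0.35 × 14 = 4.9:

    C(z, t)/C₀ = erf( z / (2 √(D t / θ²)) ).

Two dialects of the argument are implemented. The `standard` form above is
the default and reproduces the reference percentages (~11 % lowering at
150 m below the boundary, ~3 % at 200 m, <1 % at 250 m after 4×10⁵ yr).
The `as_printed` variant, erf(z/√(2Dt/θ²)), which appears in some write-ups
of this solution, gives ~2.4 % at 150 m and is retained only for
transparency; the two differ by a factor √2 in the argument. The closed
form treats the column as semi-infinite; the impermeable bottom at
1200 mbsf matters only on much longer timescales, which the test suite
verifies by agreement (<1 % relative error on drawdowns above 1 %) with an
explicit finite-difference solution using a no-flux bottom boundary.

Budget arithmetic: depletion time τ = [SO₄²⁻]₀ φ / SRR converts a
porewater inventory and a volumetric rate into a lifetime (the φ factor
maps porewater concentration to bulk volume); the rearranged form gives
the mean rate a depletion implies over a period; and with the
oxidation-state-zero stoichiometry 2 CH₂O + SO₄²⁻ → 2 HCO₃⁻ + HS⁻ + H⁺,
each mol of sulfate consumes 2 mol organic carbon, giving the wt%-C_org
equivalent of a depletion at bulk density 2.2 g cm⁻³. The year is
365.25 d (configurable); at these defaults a 28 mmol L⁻¹ inventory at
0.3 pmol cm⁻³ d⁻¹ lasts 3.27×10⁷ d ≈ 8.9×10⁴ yr.

## In-situ Gibbs energies

ΔG_R = ΔG⁰_insitu + RT ln Q with R = 0.008314 kJ mol⁻¹ K⁻¹. The
standard-state energies at in-situ temperature and pressure are *input
data* (per reaction, editable YAML): computing ΔG⁰(T, P) requires an
equation-of-state thermodynamic database and is deliberately out of scope.
The packaged table covers the five catabolic reactions (AOM, sulfate
reduction from acetate and H₂, methanogenesis from acetate and H₂), each
charge- and element-balanced; the two acetotrophic values are anchored so
the packaged 920 mbsf / 100 °C / 55.8 MPa reference state yields
−105 kJ (mol SO₄²⁻)⁻¹ and −43 kJ (mol CH₄)⁻¹ exactly, pinning the
downstream threshold calculations to a reproducible fixture.

Activities are concentrations times extended Debye–Hückel (B-dot)
coefficients, log₁₀γ = −A z²√I/(1 + B å √I) + ḃI, with A(T), B(T) and a
global ḃ(T) linearly interpolated from a packaged 0–150 °C table of
standard literature values, per-species ion-size parameters, and
γ = 10^(ḃI) with ḃ = 0.1 for neutral species (the usual salting-out
approximation). Ionic strength defaults to 0.64 mol L⁻¹. pH (default 7.5)
supplies the H⁺ activity directly; water activity is 1. Sulfide below
detection takes a 0.1 µmol L⁻¹ floor. Temperatures come from a linear
geothermal model, default 2 °C + 100 °C km⁻¹ × depth; the gradient is
fully configurable because site estimates in the source literature vary
between 100 and 110 °C km⁻¹, and neither value is exactly consistent with
every quoted depth–temperature pair.

## Per-cell energetics and biomass turnover

With volumetric rate r, cell abundance n and functional fraction f (share
of cells carrying out the process, 0.01–1):

* cell-specific rate = r / (n f), in fmol cell⁻¹ d⁻¹;
* per-cell power = |ΔG_R| · r / n — the magnitude is used because the
  catabolic ΔG_R are negative (exergonic) and the printed product would
  otherwise be a negative energy;
* maintenance rate = cost · n / |ΔG_R| (volumetric) and
  threshold = cost / |ΔG_R| (per cell), which satisfy
  maintenance/n ≡ threshold by construction.

**Repair cost model.** Two thermal-damage processes are priced with
Arrhenius kinetics k = A·exp(−Ea/RT): amino-acid racemization, with whole
proteins replaced once 3 % of their residues have racemized (default
proteome 10⁹ residues per cell at ~4 ATP per residue resynthesized,
Ea = 130 kJ mol⁻¹), and DNA depurination (10⁶ sites per megabase over a
default 4 Mb genome, plausible range 1.6–10 Mb, ~50 ATP per repair,
Ea = 110 kJ mol⁻¹). The literature kinetics compilations behind these
processes are not reimplemented; instead the defaults give a
racemization-dominated total of the right order, and `calibrated()`
rescales both terms jointly so the total at 100 °C equals the
10⁻¹⁴ kJ cell⁻¹ d⁻¹ anchor exactly. The calibrated model then reproduces
the ~0.1 fmol SO₄²⁻ and ~0.2 fmol CH₄ cell⁻¹ d⁻¹ repair thresholds at the
reference energy yields. The model is monotone in temperature and its
depurination term is linear in genome size.

**Biomass turnover.** T_b = n f · (22 fg C cell⁻¹) / (12 g mol⁻¹) /
(r · 2 mol C_org per mol substrate · yield). The growth yield defaults to
the conservative 0.01 mol C per mol C_org (plausible range 0.01–0.2). The
25 % extraction-recovery correction (divide counts by 0.25) is applied to
biomass estimates by default and *not* applied in the per-cell rate and
power formulas, which use counted abundances; both behaviours are
switchable. Cell counts below the 16 cells cm⁻³ quantification limit are
flagged; per-cell quantities there are bounds, not estimates.

## Synthetic data generator

Defaults are the study conditions: 5 mL sediment + 5 mL medium vials,
≤10 d incubations, ~5×10⁶ count-unit injections against a sub-unit
counting background, porosity 0.35, bulk density 2.2 g cm⁻³, 5 mmol L⁻¹
medium sulfate and 0.677 mmol L⁻¹ medium DIC, a 600 mbsf sulfate
boundary with the erf-shaped recovery beneath it, an acetate rise to
10 mmol L⁻¹ below 600 mbsf with consumption below ~1030 mbsf, and a cell
collapse from 3×10⁴ to 3×10² cells cm⁻³ across 320–360 mbsf with a
16 cells cm⁻³ floor. Where the source material states no value (exact
background magnitude, control replication n = 6, profile noise), values
were chosen once at realistic scintillation-counting and porewater-
analysis levels.

The forward model inverts the rate equation: expected product fraction
f = r·t·m/(ρ·pool·α), product counts ~ Poisson(f·injected) plus a
truncated-Gaussian background, substrate counts ~ Poisson((1−f)·injected).
Poisson-plus-Gaussian is the standard scintillation-counting model; no
distillation chemistry, tracer carryover or drilling contamination is
simulated, and profile shapes are idealized (noise-free by default). Tests
passing on these data therefore demonstrate correct arithmetic, detection-
limit statistics and estimator behaviour under counting noise — not
robustness to the chemical artefacts of real incubations. All randomness
flows from one integer seed through spawned child streams, so outputs are
byte-identical across reruns.

## Numerical choices and problem sizes

* Rates/percentages are computed in float64 throughout; no iterative
  solvers are involved, so there are no convergence tolerances to tune.
* The finite-difference oracle uses an explicit FTCS scheme at
  Δz = 2 m with Δt at 0.4 of the stability limit.
* Censoring at exactly the MBQL: strictly-below is censored (a rate equal
  to the limit counts as quantifiable).
* Default test problem sizes — 6–60 vials, 4000-sample convergence checks,
  a 601-node diffusion grid — were chosen so the whole suite runs in
  seconds while keeping Monte-Carlo errors well inside the asserted
  tolerances.

## Known limitations

* Single-solute diffusion with constant D; no advection, compaction or
  reactive transport.
* ΔG⁰_insitu is a per-reaction constant of the packaged reference state;
  depth-resolved ΔG profiles require a user-supplied ΔG⁰(T) table.
* The repair-cost constants are a calibrated parameterization, not a
  reproduction of the underlying kinetics compilations; only the anchored
  total at 100 °C and the scaling behaviour are quantitative claims.
* The activity model ignores ion pairing and complexation, which at
  I = 0.64 can shift γ for divalent ions noticeably; the B-dot form is
  used because it is the convention in the source workflow.
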