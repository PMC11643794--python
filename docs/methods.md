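# Methods

## The fixed-effects decomposition

For a balanced, complete crossing of storage time (9 levels), temperature
(2 levels) and packaging material (4 levels) with replicate vials, the
preprocessed spectra matrix is partitioned as

    X = μ + X_time + X_temp + X_mat + X_time×temp + X_temp×mat + X_mat×time + E

Main-effect rows are level means of the centered data; interaction rows are
cell means minus both level means plus the grand mean; the residual E
absorbs the three-way interaction and replicate error (the model is fit
with two-way interactions only). Balance makes the seven terms mutually
orthogonal, so their sums of squares are additive and each effect's share of
the total centered SSQ ("effect %") is well defined. Unbalanced designs are
rejected outright rather than fit with biased estimators; ASCA variants for
unbalanced data (ASCA+, LiMM-PCA) are out of scope.

Each effect matrix is summarised by SVD. Components are retained at the
numerical rank (singular value > 1e-10 × the largest): a main effect with L
levels has rank ≤ L−1, an interaction ≤ (L_a−1)(L_b−1), and with any noise
present the bound is attained, which the structural tests exploit (a
2-level effect always yields exactly one component carrying 100% of its
variability). "Spider" scores project the residual-augmented effect matrix
(effect + E) onto the retained loadings, the standard way to display
within-level dispersion around each level's position.

## Permutation significance

Effect significance uses an unrestricted randomisation test: each of B draws
shuffles the entire design-row assignment against the spectra, the
decomposition is recomputed, and the effect's SSQ recorded;
p = max(count ≥ observed, 1)/B with a ≥ (tie-conservative) comparison, so
the attainable floor is 1/B (0.0002 at the default B = 5000). The same
scheme is used for main effects and interactions — restricted permutation
schemes exist but are deliberately not implemented; the scheme is isolated
in one function. Implementation note: for a fixed design each effect's SSQ
is the squared norm of the data projected onto that effect's subspace, so an
orthonormal basis of the subspace is computed once and each draw costs one
small matrix product; the tests verify this path agrees with the explicit
decomposition to 1e-8 relative.

Two consequences worth knowing. First, under the null the p-values are
uniform up to discreteness — with the floor convention the exact rejection
probability at α = 0.05 and B = 200 is 11/201 ≈ 0.0547, which the
calibration test's tolerance band (±3 binomial SD over 300 null datasets)
accounts for. Second, the unrestricted shuffle redistributes *all* variance:
an effect is significant only when its SSQ exceeds what the remaining
(possibly dominant) effects would place in its subspace by chance, so a
modest real effect can receive a large p when another factor dominates.

## The synthetic generator

The generator emulates a hempseed-oil storage trial and is the package's
source of ground truth; its defaults are the study conditions.

**Design.** 9 sampling times {15…270 days} × 2 temperatures {10, 25 °C} ×
4 materials {PP, CG, AG, AGA} × 2 replicate vials = 144 measurements.

**Chemistry.** Peroxide value follows rise-then-decay kinetics
PV(t) = pv0 + A·r·(1 − e^(−g·r·t))·e^(−d·r·t) with r = temp_factor ×
material_factor: hydroperoxides accumulate (g = 0.02/day) then decompose
(d = 0.00105/day). The multipliers encode physics qualitatively: higher
temperature accelerates the radical chain (factor 1.0 at 25 °C vs 0.4 at
10 °C) and materials order PP > CG > AG > AGA by oxygen permeability × light
transmittance (1.0/0.55/0.35/0.12). With A = 45 and pv0 = 3 meq O₂/kg,
polypropylene at 25 °C peaks near 40 meq O₂/kg around 150 days while
foil-wrapped amber glass stays near baseline — the qualitative shape of a
real trial. K232 co-moves linearly with PV (0.17 per meq, from its time-zero
value 4.26); K268 rises monotonically toward ≈2.6 (secondary products, from
1.25). Gaussian measurement noise (0.5 meq on PV, scaled down for the
extinction coefficients) is added and outputs clipped at zero.

**Spectra.** A 4000–9000 cm⁻¹ grid at 8 cm⁻¹ (plausible FT-NIR resolution);
15 Gaussian bands at the wavenumbers of the main C–H/C=C/C=O overtone and
combination bands of an unsaturated oil. Each band's amplitude responds
linearly to the standardized (PV, K268) pair — a 2-vector sensitivity per
band, keeping the spectra–chemistry link linear so PLS recovery is provable.
Per-spectrum baseline offset and tilt model turbidity; iid channel noise
(0.002 AU) models the detector. Channels in [4000, 4440] and [5770, 5875]
cm⁻¹ rail at a 3.0 AU ceiling, reproducing the saturation a 4 mm optical
path causes. Not modelled, hence not demonstrated by passing tests:
multiplicative scatter, temperature-dependent band shifts, Beer–Lambert
path-length physics, antioxidant-depletion chemistry, non-linear
detector response near saturation.

A second construction, `simulate_effect_injection`, bypasses the forward
model: it places one rank-1 component exactly inside each effect's design
subspace with a prescribed variance share plus iid noise. The default shares
(time 0.20, temp 0.08, mat 0.08, time:temp 0.20, temp:mat 0.08,
mat:time 0.34) were sized against each effect's permutation-null mean —
which scales as subspace rank/(n−1) of the total SSQ, so the 24-dimensional
mat×time subspace needs the largest share — to make every effect
unambiguously strong. This is the dataset for significance-floor and
variance-recovery tests (e.g. a 4:1 injected split recovered within 20%).

## Preprocessing

Fixed order, recorded in provenance: (1) drop channels whose **mean**
absorbance exceeds 2.5 AU — masking on the mean spectrum keeps one shared
grid for all rows; (2) per-spectrum linear detrend (least-squares line in
wavenumber, via an orthonormal projection), the simplest correction that
exactly removes any affine turbidity contamination — whether the original
workflow used offset-only or polynomial correction is unknowable, and the
linear choice has a testable invariance; (3) mean-centering, with μ stored
so that centered + μ reconstructs the detrended data exactly. No SNV, MSC,
derivatives or smoothing — minimal preprocessing keeps loadings
interpretable.

## PLS calibration

Single-response PLS (NIPALS with per-component deflation, deterministic;
the fit is delegated to scikit-learn's `PLSRegression` with scaling off,
behind the package's model surface). Cross-validation leaves one packaging
material out at a time, re-centering on each training fold to avoid
leakage; RMSECV pools all held-out squared errors, bias is the mean signed
CV error, R²cv = 1 − SSE/SST, and RPD = sd(y, ddof=1)/RMSECV. The LV count
is chosen to minimise RMSECV with ties broken toward fewer LVs (the
selection rule in the original toolboxes is typically unreported; RMSECV
minimisation is the defensible default). The response is used untransformed
and no outliers are removed.

## Reference chemistry

PV = titrant volume (mL) × normality / sample mass (kg); K = A/(c·l) with c
in g/100 mL and l in cm, rounded once at output to two decimals (the
reporting convention for specific extinctions). Fatty-acid class sums total
the shipped hempseed composition table per saturation class. The univariate
three-way ANOVA reuses the multivariate decomposition on a single column
(the two stay consistent to 1e-10 relative, a tested invariant), tests each
term against the residual mean square, and runs Tukey HSD per factor using
the studentized-range distribution with the pooled MSE at family level 0.05.
A constant response returns an explicit "no variance" result; a design whose
model exhausts every degree of freedom is rejected.

## Problem sizes and determinism

The default dataset (144 × 626, 557 channels after masking) runs the full
pipeline, including a 5000-permutation test per effect, in seconds thanks to
the basis-projection path; tests use that size or smaller (36-row designs,
80-channel injected matrices, 12-channel null matrices for the 300-dataset
type-I calibration). All randomness flows through `numpy.random.default_rng`
seeds; identical spec/params/seed give bit-identical outputs, and the
pipeline writes its seed, config hash and package versions into the run log.

## Known limitations

Balanced complete designs only; fixed effects only; free (unrestricted)
permutation only; PLS1 only (no multi-response, variable selection, or
external test-set validation); the generator's effect sizes are stylised —
on the default dataset material dominates the spectral variance, so
per-effect percentages should be read as generator properties, not
predictions for any real oil.
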