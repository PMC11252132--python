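# Methods

This note records the models, numerical choices and limitations behind
`spinrelax`, in the order the pipeline runs.

## Relaxation model and constants

The two-spin ¹H–¹⁵N relaxation expressions (R1, R2, NOE, η_xy) are
implemented exactly as printed in `spin_physics`, with constants
γN = −27.116×10⁶ rad s⁻¹ T⁻¹, γH = 2.6752219×10⁸ rad s⁻¹ T⁻¹,
r_NH = 1.02 Å, Δσ = 172 ppm, θ = 17°, µ0 = 4π×10⁻⁷ H m⁻¹,
h = 6.62607×10⁻³⁴ J s.  Two choices deserve note:

* **Trace relation.**  The effective correlation time is implemented as
  τC = 1/(2 tr **D**): the form "τC = ½ tr **D**" sometimes written for
  this relation is dimensionally inconsistent, and only the reciprocal
  form reproduces 26.5 ns from (D_⊥, D_∥) = (0.56, 0.77)×10⁷ s⁻¹.
* **Cross-correlation constant p.**  p is built from γH·γN (p = d/(2√2)).
  With this choice p·δ_N = d·c/(4√3), which makes the exchange relation
  Rex = R2 − [(3d²+4c²)/(2√3cd(3cos²θ−1))]·η_xy an exact identity on the
  J(0)/J(ωN) part of R2 — the consistency the method relies on.
* Only |γN| enters the Larmor frequencies; the sign appears solely in the
  NOE through γH/γN.

η_xy keeps only the J(0) and J(ωN) terms.  At 900 MHz and τC = 27.8 ns
the dropped high-frequency terms are 0.29 % of the retained ones
(3J(ωN)/4J(0)); the untruncated expression is deliberately not
implemented.

**Accuracy of the quadratic ratio relation.**  R2/R1 = (2/3)(ωN τC)² + 7/6
follows from keeping only J(0) and J(ωN) in both rates.  The
high-frequency dipolar terms that remain in the full R1 shift the full
ratio by ≈1.2–1.5 % (nearly τC- and field-independent for τC ≳ 10 ns,
because both the J(ωN) and J(ωH) contributions to R1 scale as 1/τC).  On
the τC scale — which is how the relation is used, to convert between
ratios and correlation times — the error is half that, below 1 % over
τC = 10–40 ns at 800 and 900 MHz.  Tests and the acceptance script assert
the τC-scale bound.

## Rate extraction

Mono-exponential A·e^(−Rt) fits use unweighted nonlinear least squares
(scipy `curve_fit`), with σ(R) from the residual-scaled covariance; a
weighted variant is available.  Duplicate relaxation delays are ordinary
extra points.  NOE = I_sat/I_ref with quadrature error propagation from
user-supplied base-plane noise (the package does not estimate base-plane
noise itself — peak integration is out of scope).  η_xy =
−ln(I^β/I^α)/(2Δ) with Δ = 10 ms by default; its initial error comes from
the α/β mismatch of the Δ = 0 pair, then CCR errors are averaged across
the two available datasets and floored at 5 % relative (idempotent).
An optional monotone amplitude drift (off by default) emulates slow
sample degradation applied in acquisition order.

## Residue selection and tensor fitting

Selection applies, in order: (i) relative R2/R1-error thresholds of
10 %/15 %/25 % for 900 MHz, 800 MHz and CCR datasets; (ii) backbone-N
B-factor ≤ 35 Å²; (iii) a user-supplied peak-overlap exclusion list
(empty for synthetic pipelines — no published list exists); (iv) one
non-iterative trim of ratios beyond 2.0 SD (1.7 SD for CCR) of the mean
of the residues surviving (i)–(iii).  The trim statistics are computed
after criteria (i)–(iii), matching the listed order.  Every removal is
recorded with its criterion in an audit map.

The tensor (D_⊥, D_∥, α, β) minimises Σ[(ρ_exp − ρ_pred)/σ]², where
ρ_pred is the full R2/R1 prediction (Rex = 0) under the Woessner axial
expansion.  Direct ratios are used as the target (no internal ratio
transformation): at ns-scale τC this is equivalent to transformed
variants and simpler to verify.  The optimiser seeds D from the
mean-ratio isotropic estimate, scores a 12×12 (α, β) orientation grid at
two trial anisotropies, and refines the five best candidates with
Nelder–Mead (xatol 10⁻¹⁰ relative).  Orientations are canonicalised to
β ∈ [0°, 90°] with α ∈ [0°, 360°): the only orientational degeneracy of
an axial tensor is axis ↔ −axis, so the canonical axis lives on a
hemisphere and the azimuth cannot be restricted to [0°, 180°) without
changing the tensor.  Fits with ζ within 2 % of 1 warn that the axis
orientation is undefined; CCR-pathway fits carry a "qualitative" warning
(the pathway is calibrated, not independent, and η_xy is more sensitive
to internal motions).

**CCR pathway and S².**  η_xy converts to a per-residue τC via the TRACT
relation with an order parameter S² (default 0.88), then to a pseudo
R2/R1 ratio via the quadratic relation; σ propagates through both steps
(σ_ratio = (4/3)(ωN τ)²·σ_η/η).  S² is calibrated by equating the mean
CCR-derived and ratio-derived correlation times (τ ∝ 1/S² makes the
calibration a one-step fixed point).  This calibration also absorbs the
small systematic biases of the two truncations above, which is why the
two pathways agree on τC to ≪1 % on noiseless synthetic data.

**Uncertainties.**  Delete-d resampling: 100 refits (seeded, local
refinement from the full-data optimum) on random subsets with 20 % of
residues removed without replacement; the reported σ of each parameter is
√(n/d) times the SD over refits.  d = 20 % and 100 repeats are the
defaults; d is restricted to (0, 0.5) because fits degrade beyond half
deletion.  With n divisible by five the multiplier is exactly √5.  Two
domain fits are called distinct when both D_⊥ and D_∥ differ by more than
2 combined scaled-SDs.

## Exchange mapping

Rex per residue from the η_xy comparison, σ_Rex by quadrature, flag at
Rex/σ_Rex > 5 (strictly greater).  Note that a "consistent" (R2, η_xy)
pair in the truncated sense gives Rex = 0 exactly; pairs generated from
the full R2 expression leave the high-frequency dipolar terms
(~10⁻³ of R2 at τC ≈ 26 ns) in Rex — far below any significance
threshold, but not numerically zero.

## Structure tools

Amide hydrogens are placed geometrically: in the C(i−1)–N–CA plane on the
external bisector at 1.02 Å (prolines and chain N-termini skipped;
deterministic).  This differs from interactive tools' heuristics by <5°
for regular backbone, well inside fit errors.  Dihedrals are IUPAC-signed;
altloc atoms keep the highest occupancy; methyl contact maps enumerate
Ile/Leu/Val methyl carbons with an intra/inter-domain label split at
residue 574 by default.

**Bead-model hydrodynamics.**  The rotational diffusion tensor of a rigid
assembly of identical beads at the Cα positions, with pairwise
hydrodynamic interaction at the Rotne–Prager–Yamakawa level (including
the overlap form for separations < 2a, needed for 3.8 Å Cα spacing with
5 Å beads).  The 6×6 grand resistance matrix is assembled at the
centroid and inverted; its rotational block is origin-independent.  The
tensor is symmetrised, diagonalised and reduced to axial form (unique
eigenvalue = the one farthest from the mean of the other two).  Only the
anisotropy and axis are meaningful — absolute magnitudes depend on the
viscosity input.  The default bead radius is 5 Å; the anisotropy varies
<1 % over radii 3–6 Å and ~3 % at 7 Å, where beads overlap far beyond the
surface spacing.  This is not an atomic-shell (HYDRONMR-style)
calculation.

**Empirical τC.**  τC = k·MW·(η_w(T)/η_w(298 K))·(298/T) with
k = 0.61 ns/kDa by default, calibrated so a 43.6 kDa construct (mass
including the purification tag; the exact tagged mass is configurable)
predicts 26.6 ns at 298 K; the corresponding dimer computes to 53.2 ns.
Water viscosity uses a Vogel-type fit valid for liquid water.

## Ensemble PCA and rotamer states

Models are superposed on the Cα atoms of configurable rigid stretches
(defaults 344–467, 484–500, 510–562) onto an iteratively refined mean
structure (two passes; deterministic and symmetric, unlike aligning to an
arbitrary first model).  PCA is plain covariance PCA on flattened
Cartesian coordinates — no mass weighting, no variance scaling — so
loadings invert directly to structures; extreme structures along a
component are mean ± (min/max score)·loading.  Per-residue confidence is
read from the B-factor column when flagged as pLDDT (the
structure-prediction convention) and must lie in [0, 100].

Rotamer states come from two probe dihedrals (default: χ2 of the
tryptophan gate, anchors +80° outward / −100° inward; χ1 of the partner
tyrosine, anchors −93° / +57°).  Each angle is assigned to its nearest
anchor on the circle — equivalent to fixed boundaries at the circular
midpoints of the anchors — giving four states I (out, −93), II (out, +57),
III (in, −93), IV (in, +57).  Fixed midpoint thresholds, not k-means,
keep the assignment deterministic.  The side-chain selection of the
backbone-flavour PCA is config-supplied; a helper flags residues with
clearly bimodal χ2 distributions (circular split at the mean ±90°, minor
mode ≥5 %, mode centres ≥60° apart).

## Synthetic data

The relaxation generator forward-models the exact equations the analysis
inverts: rates from a known axial tensor (defaults: D_⊥ = 0.56×10⁷ s⁻¹,
D_∥ = 0.77×10⁷ s⁻¹, α = 11°, β = 59° — a ~26.5 ns two-domain monomer),
S² = 0.88 scaling all spectral densities (it cancels in R2/R1 and is
recovered by the CCR calibration), 116 Fibonacci-sphere N–H vectors, the
900 MHz delay schedules (with the repeated transverse delays measured
twice), TROSY/anti-TROSY pairs at Δ = 0 and 10 ms decaying at R2 ∓ η_xy,
independent Gaussian noise applied last, and optional Rex injection into
R2.  Default noise fractions (1–5 % by observable) sit at the
better-quality end of large-protein data so that recovery tests probe the
estimators, not the noise floor.

The ensemble generator is a deliberately minimal two-domain toy: a
zig-zag pseudo-backbone whose second domain rotates about a hinge through
the inter-domain point, two four-atom side-chain probes whose dihedrals
are drawn (SD 8°) around the state anchors, state labels drawn from
configurable fractions, and a coupling coefficient tying the hinge sign
to the first probe's rotamer (1 = deterministic, 0 = independent).  The
hinge clusters sit at ±10° with 1.2° spread: the flip is a discrete
two-state mode, well separated against the ensemble-mean offset that a
majority-outward population induces, so at full coupling the sign of the
leading PCA score predicts the rotamer state exactly.  Per-residue
confidence is state-dependent at the probe residue (outward states
higher) and flat elsewhere.  The toy has no sterics, no chemistry and no
realistic secondary structure: passing tests demonstrate that the
statistical machinery (alignment, PCA, circular state assignment,
population recovery) is correct, not that real ensembles behave this way.

## Problem sizes

The test suite and acceptance script use 40–116 vectors per tensor fit,
50 seeds × 100 resampling refits for coverage calibration, and M = 2000
models for population recovery — sizes chosen to make stochastic checks
statistically meaningful (binomial SDs of a few tenths of a percent)
while keeping a full run in minutes on one core.

## Known limitations

* No model-free (Lipari–Szabo) fitting of per-residue S², τ_e, and no
  relaxation-dispersion modelling; Rex mapping is a significance screen,
  not an exchange model.
* Fully anisotropic (three-component) tensor fitting is out of scope;
  near-isotropic data yield an undefined axis (warned, not fixed).
* The base-plane noise estimator is user-supplied; spectral processing,
  peak picking and integration are upstream of this package.
* The bead model ignores atomic detail and bound solvent; its anisotropy
  is a shape estimate, not a quantitative prediction of absolute D.
* The empirical mass→τC rule is linear; real proteins deviate with shape
  and glycosylation, and the calibration constant is per-construct.
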