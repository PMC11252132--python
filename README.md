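# spinrelax

Solution-dynamics analysis of multi-domain proteins from backbone ¹⁵N spin
relaxation, built around the two-domain paracaspase–Ig3 module of MALT1.
The package turns per-residue relaxation measurements and a crystal
structure into rotational diffusion tensors per domain, maps µs–ms
conformational exchange, and characterises conformational ensembles
(e.g. structure-prediction ensembles) by Cartesian PCA with side-chain
rotamer-state clustering.

## Who this is for

NMR spectroscopists and structural biologists who have measured ¹⁵N R1,
R2, heteronuclear NOE and/or TROSY/anti-TROSY cross-correlated relaxation
(CCR, η_xy) on a large (slow-tumbling) protein and want to ask: do the
domains tumble together or semi-independently, where is conformational
exchange localised, and do predicted conformational ensembles show
discrete coupled modes?

## The model

For an amide ¹H–¹⁵N pair, R1, R2, NOE and η_xy are linear functionals of
the spectral density J(ω):

    R1  = (d²/4)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + c² J(ωN)
    R2  = (d²/8)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
          + (c²/6)[4J(0) + 3J(ωN)] + Rex
    η_xy = p δ_N [4J(0) + 3J(ωN)] (3cos²θ − 1)

with the dipolar and CSA constants d, c, p, δ_N built from γH, γN,
r_NH = 1.02 Å, Δσ = 172 ppm and θ = 17°.  For axially symmetric rotational
diffusion (D_∥, D_⊥, axis orientation α, β) the Woessner spectral density

    J(ω) = (2/5) Σ_{k=0..2} A_k(φ) τ_k / (1 + (ω τ_k)²),
    1/τ_k = 6D_⊥ + k²(D_∥ − D_⊥)

depends on the angle φ between each N–H vector and the symmetry axis, so
experimental R2/R1 ratios over many residues determine the tensor by
weighted least squares.  Supporting relations: the effective correlation
time τC = 1/(2 tr **D**); the large-molecule ratio
R2/R1 = (2/3)(ωN τC)² + 7/6; the TRACT conversion
τC = 5η_xy/(8S²pδ_N(3cos²θ−1)); and the exchange estimate
Rex = R2 − [(3d²+4c²)/(2√3 c d (3cos²θ−1))] η_xy, flagged significant at
Rex/σ_Rex > 5.  Tensor uncertainties come from delete-d resampling
(d = 20 %, 100 refits, SD scaled by √(n/d)).

## Worked example

Run the bundled synthetic pipeline end to end (the generator's defaults
emulate the study conditions: a ~26.5 ns two-domain monomer, 116 selected
amide vectors, 900 MHz):

    cat > config.toml <<'EOF'
    seed = 7
    output_dir = "out"

    [field]
    mhz = 900.0

    [simulate]
    n_vectors = 40

    [simulate.rex_injection]
    5 = 8.0

    [pca]
    alignment_stretches = [[1, 30]]
    analysis_stretches = [[1, 60]]
    EOF
    spinrelax --config config.toml all

which prints (abridged):

    {
      "full": {
        "tauC_ns": 26.54783574571261,
        "zeta": 1.3762707545989787
      }
    }
    1 residues with significant exchange (Rex/sigma > 5)
    {
      "explained_variance_pct": [99.77, 0.11, 0.04, 0.0, 0.0]
    }

Reading: the tensor fitted from the simulated decays recovers the
generating truth (τC = 26.5 ns, anisotropy ζ = D_∥/D_⊥ = 1.375) within the
simulated noise; the one residue carrying an injected 8 s⁻¹ exchange
contribution is the only one flagged; and the toy hinge ensemble is
dominated by a single PCA mode (the hinge), as constructed.  Per-stage
outputs (rate tables, tensor report with resampled uncertainties and the
selection audit, Rex profile, PCA report) and run manifests land in
`out/`.

The same stages run on real data by pointing the config at measured decay
tables (TSV: residue, delay_s, volume, sigma), a PDB structure for the
N–H vectors and B-factors, and a multi-model PDB ensemble.

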