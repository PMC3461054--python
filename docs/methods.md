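# Methods

## Two-state thermal unfolding

The melt observable is the mean residue molar ellipticity at 222 nm, Y₀(T).
Under an apparent two-state equilibrium N ⇌ U with linear instrument
baselines,

    Y₀(T) = (1 − f_U)·(y_N + m_N T) + f_U·(y_U + m_U T),
    K(T)  = f_U/(1 − f_U),
    ΔG(T) = −R T ln K,          R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹,

and the stability curve is the Gibbs-Helmholtz form

    ΔG(T) = ΔH_m (1 − T/T_m) + ΔC_p [(T − T_m) − T ln(T/T_m)].

ΔG(T_m) = 0 identically; for ΔC_p > 0 the curve is strictly concave with
its maximum at T_s = T_m exp(−ΔH_m/(ΔC_p T_m)); for ΔC_p = 0 it degenerates
to the van't Hoff line and T_s is undefined (reported as absent).
Reversibility is assumed; no three-state or dissociation-coupled variant is
offered. Temperatures are accepted in °C or K and converted to K.

### Fitting strategy

The fit runs in two stages.

**Staged pipeline** (also exposed as individual operations): ordinary least
squares baselines inside a native and an unfolded temperature window;
f_U(T) by baseline interpolation, clipped to [10⁻⁴, 1−10⁻⁴] with clipped
points excluded downstream; ΔG(T) restricted to the transition window
(default 288–334 K); nonlinear least squares on the Gibbs-Helmholtz form
with deterministic starts (T_m from the f_U = ½ crossing, ΔH_m from the
van't Hoff slope over the central transition, ΔC_p = 0.5 kJ/mol/K) and
ΔC_p constrained ≥ 0.

**Profiled refinement** (the default result). A marginally stable protein
is already a few percent unfolded at the coldest accessible temperature, so
window-only baselines are biased and their long extrapolation to T_m is
noisy. The refinement therefore treats the baselines as nuisance
parameters: for a candidate (T_m, ΔH_m, ΔC_p) the unfolded fraction is
known, the model is linear in the four baseline coefficients, and those are
solved by linear least squares on the baseline-window points; the
whole-curve residual, scaled by a data-driven noise floor (MAD of second
differences, which estimates white noise robustly against the transition's
curvature), drives a bounded least-squares fit of the three thermodynamic
parameters. The truth is an exact fixed point of this construction, so
noise-free synthetic curves are recovered to machine precision.

ΔC_p is the weak spot of any single-curve analysis: it enters only through
the gentle curvature of ΔG across the transition, and a Fisher-information
analysis of the synthetic study conditions below gives a Cramér-Rao bound
of σ(ΔC_p) ≈ 2.6 kJ/mol/K with free baselines (≈ 0.2 even with baselines
known exactly) — i.e. it is essentially unidentifiable, and T_s, which
depends exponentially on 1/ΔC_p, inherits that fragility. The refinement
therefore applies a weakly informative Gaussian prior ΔC_p ~ (0.5 ± 0.3)
kJ/mol/K, appended as one residual row, centred on the same physically
plausible value used to initialize the staged fit and wide enough to span
0–1.1 at two standard deviations. Because the data residuals are scaled by
the estimated noise floor, clean data override the prior automatically;
`dcp_prior=None` gives the unpenalized maximum-likelihood fit. Reported
uncertainties come from the (penalized) Jacobian at the optimum, so they
describe the regularized estimator, not the unidentifiable ML problem.

**Window defaults.** Native = the lowest 15 K of the data; unfolded = all
data above the transition window's upper edge (falling back to the top
15 K when that leaves fewer than three points). Wider windows than the
narrowest conventional choice are deliberate: with no native plateau, short
windows leave both the baseline slope and ΔC_p poorly determined. All
windows are configurable.

## CD spectrum metrics

Raw ellipticity θ (mdeg) is normalized per residue, per mol/L, per cm:
[Θ] = θ/(10·C·l·N). The 222/208 index uses linear interpolation on the
wavelength grid; classification uses the literature anchors 0.83
(single helix) and 1.03 (coiled coil) with a dead band — ≥ 0.98
coiled-coil-like, ≤ 0.88 helix-like, otherwise intermediate — because the
underlying assignment is qualitative. Helix content comes either from the
chain-length-corrected limiting value −40000·(1 − 4.6/n) (clipped to
[0, 1]; the effective n, e.g. with or without purification tags, is the
caller's responsibility) or from non-negative least squares against
reference basis spectra with coefficients normalized to sum to one. The
shipped basis is synthetic — Gaussian bands at the canonical helix
(192/208/222 nm), sheet (195/218 nm) and coil (198 nm) band positions with
literature-scale amplitudes — adequate for recovery testing and rough
estimates; quantitative deconvolution should supply a measured basis.

## Heptad register analysis

Registers are the cyclic labels a–g; blocks are user-supplied
(start, end, phase) intervals in 1-based inclusive full-protein numbering.
The scanner scores each sliding window (default 21 residues, minimum two
heptads) for all seven phase offsets as mean Kyte-Doolittle hydropathy at
a/d minus the mean elsewhere, residues take the phase voted by their
covering windows, and ties break deterministically to the lowest offset
with a low-confidence flag. This is an intentionally lightweight stand-in
for probabilistic coiled-coil predictors and is labelled as such in
reports. Atypicality counts residues from the charged set {D, E, K, R}
(His excluded by default, configurable) at a/d positions. Shipped segment
schemes carry only the published stalk boundaries; unpublished boundaries
are left to user configuration.

## Ensemble metrics

Multi-model PDB files are read via gemmi; models must share one atom
table; waters are dropped by default. Superposition is the closed-form
Kabsch solution (SVD with a determinant guard, so reflections are never
returned). RMSF superposes all frames onto the ensemble mean, recomputes
the mean once, and reports per-residue √⟨|x − x̄|²⟩; a planted isotropic
displacement σ appears as RMSF ≈ σ√3 minus the ~6/(3N) variance fraction
absorbed by superposition. Rg is mass-weighted. SASA is Shrake-Rupley with
a golden-spiral point lattice (default 960 points), probe 1.4 Å and Bondi
radii (unknown elements 1.5 Å with a warning); the partition assigns whole
residues to the hydrophobic class {A, V, L, I, M, F, W, P, G} and sums
exactly to the total by construction. Salt bridges pair acidic side-chain
oxygens (Asp OD1/OD2, Glu OE1/OE2, optionally the C-terminal OXT) with
basic nitrogens (Lys NZ, Arg NE/NH1/NH2, optionally the N-terminal amine)
at ≤ 4.0 Å minimum inter-group distance, deduplicated per residue pair;
hydrophobic contacts use side-chain heavy atoms at ≤ 5.0 Å, interchain
only by default. Both cutoffs are conventions, configurable and recorded
in reports. Helicity is geometric: residue i passes when d(i,i+3) ∈
[4.7, 5.7] Å and d(i,i+4) ∈ [5.8, 6.7] Å, runs of ≥ 4 passing residues
mark i…i+4 helical, chains shorter than 5 residues are excluded; this
needs no hydrogens or carbonyl oxygens, unlike hydrogen-bond-based
assignments. Reports are per-frame tables with a trailing-window mean row;
coordinates are Å internally, Rg and SASA print in nm/nm² for comparison
with the molecular-dynamics literature.

## Synthetic data: what it emulates and what it does not

The melt generator evaluates the exact forward model on a 278–363 K grid at
0.5 K pitch (coarser than a real instrument's 0.1 K, by choice of problem
size) with additive homoscedastic Gaussian noise — no heteroscedastic
photomultiplier noise, drift, or aggregation artifacts, so passing recovery
tests demonstrates correctness of the inference, not robustness to every
instrument pathology. Default thermodynamic parameters are the published
values for the His-KLP64D/68D-S heterodimer (T_m = 297.6 K, ΔH_m = 102.1
kJ/mol, ΔC_p = 0.5624 kJ/mol/K as implied by its T_s), with baseline
intercepts/slopes of −16000/+10 (native) and −3000/+2 (unfolded) per K
relative to the ramp start — representative magnitudes for per-residue
ellipticity at 222 nm. Coordinate generators produce Cα traces only
(ideal helix: rise 1.5 Å, twist 100°, radius 2.3 Å; coiled coil: minor
helices with 3.5 residues/turn wound on a superhelix of radius 4.9 Å and
pitch 140 Å, chains 180° apart); side chains exist only in the small
geometric templates used to build salt-bridge/contact fixtures and are not
stereochemically refined. The fluctuation generator adds isotropic
per-residue Gaussian displacements and optional global rigid motions; it
has no covariance structure between residues, so it validates estimators,
not dynamics.

## Numerical choices and limitations

- f_U clipping ε = 10⁻⁴; clipped points are excluded from the free-energy
  fit and counted in the report.
- Baselines that cross inside the data range abort the staged pipeline
  (degenerate geometry); the refinement can still proceed from a coarse
  sigmoid initialization when asked for.
- The Gibbs-Helmholtz fit requires ≥ 6 stability points spanning the zero
  crossing; bounds are T_m within the data range ± 50 K, ΔH_m ∈ (0, 10⁴],
  ΔC_p ∈ [0, 50].
- Determinism: all generators take integer seeds (numpy `default_rng`);
  identical inputs and seeds produce byte-identical reports and PDB files.
- Known limitations: single-wavelength analysis only (no global
  multi-wavelength fit); ΔC_p and hence T_s are prior-dominated at
  realistic single-curve noise (see above) and should be treated as
  order-of-magnitude unless multiple curves or calorimetry constrain them;
  the register scanner is hydropathy-based and will mis-phase
  low-complexity or strongly amphipathic non-coil sequences; SASA ignores
  hydrogens (heavy-atom radii only); helicity is a geometric proxy, not a
  hydrogen-bond assignment.
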