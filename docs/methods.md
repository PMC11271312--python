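# Methods

This note records the models behind each stage, the defaults and why they
were chosen, the numerical strategy, and what the synthetic-data generators
do and do not emulate.

## Analyte model

An analogue is a pair of chains (A, B) with 1-based per-chain numbering and
an edit list applied in the order **substitutions → truncations →
modifications**, so every position in a definition refers to native
numbering (A14E means residue 14 of the native A-chain even when desB30 is
also present).  The native disulphide topology (A6–A11, A7–B7, A20–B19) is
attached and re-validated after editing.  Acyl side chains are
*configuration data*: each block stores the net elemental addition to the
peptide with all condensation waters already removed, together with its free
building-block breakdown (C20/C18 fatty diacid: C20H38O4 / C18H34O4; γGlu:
C5H9NO4; OEG, i.e. 8-amino-3,6-dioxaoctanoic acid, also written "Ado":
C6H13NO4; five condensations in total for diacid–γGlu–2×OEG–LysNε).  A test
re-derives every block from its components, so the table cannot silently
drift from the chemistry.  "OEG" and "Ado" name the same block.

## Mass engine

Peptide compositions are assembled residue-by-residue (residue = amino acid
minus water) plus one water per chain; each disulphide bond removes two
hydrogens.  Monoisotopic isotope masses are package constants at 1e-7 Da
precision (H 1.0078250, C 12, N 14.0030740, O 15.9949146, S 31.9720707).
Average masses are deliberately not implemented — deconvoluted
high-resolution spectra are interpreted in monoisotopic space.

Metabolite enumeration returns, for a two-chain parent:

* the free B-chain with its single intrachain disulphide, retaining any
  acyl modification;
* all complete pairings of the A-chain's four cysteines into two intrachain
  disulphides — exactly three connectivities, which share one elemental
  composition and hence one mass (mass spectrometry cannot distinguish
  them; chromatography can);
* the B-chain dimer joined by two interchain disulphides.  Parallel and
  antiparallel pairings are mass-degenerate, so a single species represents
  both;
* C-terminal proteolytic fragments of the B-chain for each supplied
  cleavage site (defaults: after B23 and after B28, yielding the acylated
  B24–29 and B29 species for a desB30 parent).  The "B29" metabolite is
  modelled as the free, water-terminated lysine residue carrying the full
  acyl side chain; its exact covalent termini are a modelling choice, kept
  in config so it can be revised against reference standards.

Mass matching uses a signed ppm error, (m_obs − m_ref)/m_ref × 1e6, and a
**strict** `< tolerance` comparison (default 10 ppm): a mass exactly at the
boundary is rejected.  All acceptable species are returned sorted by |ppm|;
observed masses with no hit are reported as unmatched rather than dropped.

## Redox titration

Conditions mix varied GSH (0–25 mM) against fixed 1 mM GSSG at 310.15 K.
The potential axis is E = E°′ − (RT/2F)·ln([GSH]²/[GSSG]) with
concentrations in mol/L; RT/2F = 13.363 mV at 310.15 K.  E°′ defaults to
−240 mV, the conventional GSSG/2GSH standard potential at pH 7 and 25 °C; no
pH correction is applied, and the constant is exposed as configuration.
Consequently the axis (and any fitted E50) is meaningful *relative to this
convention*; rankings and shifts between analytes are unaffected by the
choice.  The 0 mM GSH control has no defined potential and is used solely
for normalisation (control → exactly 100%).

The stability fit is the constrained sigmoid y(E) = 100 / (1 + 10^(h·(E50 −
E))) with Top = 100, Bottom = Baseline = 0 and h > 0 (bounded least
squares).  Sign convention: more negative potential (more reducing) → more
degradation, so a more negative fitted E50 means a more stable analyte.
Initialisation: E50 at the well nearest 50% intact, h₀ = 0.05 /mV.
Normalised values above 100 are *not* clipped — the asymptotes are fixed,
not fitted, so symmetric noise around the plateau does not bias E50.  If
every well stays above 90% intact the transition was not reached and the
fit is flagged "E50 below scanned range" instead of returning a number.

## Chemical denaturation

The two-state linear extrapolation model: ΔG(D) = m·(Cm − D), unfolded
fraction f(D) = 1/(1 + exp(ΔG/RT)), observed signal per wavelength
Y = (1 − f)(Y_N + s_N·D) + f(Y_U + s_U·D).  RT uses 298.15 K (the
measurement temperature) giving RT = 2.479 kJ/mol; m is in kJ·mol⁻¹·M⁻¹.
The global fit shares (Cm, m) across wavelengths with four baseline
parameters each (2 + 4·n_λ parameters total; 86 for the standard 21-λ
window against 462 data points).

Numerically the baselines are **profiled out** (variable projection): for
fixed (Cm, m) the model is linear in the baselines and one shared design
matrix [(1−f), (1−f)D, f, fD] solves all wavelengths by linear least
squares, so the nonlinear search runs over (Cm, m) only.  This reaches the
same optimum as the full joint fit — a test verifies the single-wavelength
case coincides with an independently coded 6-parameter curve fit — while
being fast and insensitive to baseline start values.  Cm is initialised at
the denaturant of steepest mean signal change, m at 4 kJ·mol⁻¹·M⁻¹.  A fit
whose unfolded fraction never crosses the 0.2–0.8 band is flagged
"transition not bracketed".

Supporting bench math: ε₂₇₆ = 6.20×10³ M⁻¹cm⁻¹ for four tyrosines, scaled
exactly proportionally for fewer (equal-contribution assumption: 4.65×10³
for three, 3.10×10³ for two); Beer–Lambert concentration A/(ε·l); and the
refractometric GuHCl concentration C = 57.147·ΔN + 38.68·ΔN² − 91.60·ΔN³,
which is monotone over the working range ΔN ∈ [0, 0.15] and evaluates to
6.010 M at ΔN = 0.1.

## Structure analysis

Files are parsed with gemmi; alternate locations are resolved to the
highest-occupancy conformer, heteroatoms/waters kept but flagged.  SASA is
an in-package Shrake–Rupley implementation: deterministic Fibonacci-spiral
test points (default 960/atom), probe 1.4 Å, Bondi van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å), neighbours via a k-d tree.  An
isolated atom reproduces 4π(r+r_p)² exactly; totals are rotation-invariant
to well under 1% at the default sampling (≈0.4% on a compact helix), and a
test cross-checks per-atom values against biotite's independent
implementation fed the same radii.

Relative disulphide exposure needs a reference state, which crystallographic
papers rarely define.  Here: per bond, the summed SASA of the two Sγ atoms
in the full model is divided by the same sum recomputed on the isolated
cystine fragment (the bonded pair's Cβ/Sγ atoms at in-situ coordinates).  A
surface bond approaches 1, a core-buried bond 0; the readout is a ratio, so
it is insensitive to the sampling density used for both evaluations.

B-factor reports give the raw mean over the B-helix (B9–19, all non-H
atoms) — the conventional normalisation reference — and loop (default
B20–23) means over both all non-H and backbone (N, CA, C, O) atom classes,
plus the loop/helix ratios.  Published "normalised temperature factor"
columns multiply such ratios by an external scale constant that is not
derivable from the structures themselves; the report therefore carries the
ratio and applies a scale only when the user supplies one.  Multi-copy
crystals are handled by per-accession chain maps (one insulin A/B → chain
label mapping per molecule in the asymmetric unit), shipped as editable
config for 8RRP, 6S34 and 6S4I.

Superposition is the Kabsch SVD solution with the determinant correction
enforcing a proper rotation; centred point sets of rank < 2 (collinear) are
rejected as degenerate.  A test checks the result against a brute-force
minimisation over rotations parameterised by random unit quaternions with
Nelder–Mead polishing, to 1e-3 Å.  Contact distances are minimum pairwise
Euclidean distances between named atom groups (e.g. Arg guanidinium N vs.
Glu carboxylate O).

## Plasma stability and NCA

Week-long steady-state incubations lose intact analyte approximately
linearly, so the default disappearance model regresses %-remaining on time
and reports the time for the *fitted line* to fall from 100 to 50 (50/|b|),
which is robust to an intercept slightly off 100.  The log-linear
alternative reports ln2/|slope|.  A slope ≥ 0 (within float tolerance of a
constant course) yields no half-life but a "stable within experiment" flag.

NCA uses the linear trapezoid throughout — appropriate for the sparse,
endpoint-rich sampling grids involved — with AUC over the 168-h dosing
interval (interpolating the boundary when sampling extends past it) and to
the last quantifiable point; there is deliberately no extrapolation to
infinity.  λz comes from log-linear regression over a user-chosen terminal
window (≥ 2 quantified points, else flagged), t½ = ln2/λz.  Below-LLOQ
values are excluded, never zero-imputed; masking a tail can therefore only
decrease AUC_last.  Metabolite exposure is 100·AUC_last(met)/AUC_last(parent),
and percentages of the summed AUC across components are available for
conserved systems.  Default LLOQs follow the assays modelled: 0.2 nM for
in-vivo plasma; 10 000 / 2000 / 1000 / 1000 pmol/L for parent, B-chain,
B24–29 and B29 in human serum.

## Synthetic data

All generators are pure functions of (parameters, config): a config carries
the integer seed, the noise level as a fraction of the signal's dynamic
range (default 2%, consistent with duplicate-assay scatter), and grid
definitions.  Independent seeded streams per generator keep outputs
bit-identical run to run.

* **Redox plate** — 12 two-fold GSH dilutions from 25 mM plus the 0 mM
  control at fixed 1 mM GSSG (the assay states the range, not the ladder;
  two-fold dilution is the natural plate design).  % intact from the
  constrained sigmoid plus noise; the control itself is noiseless at 100.
* **CD unfolding** — 21 wavelengths (218–228 nm at 2 pt/nm) × 22 GuHCl
  points (0–8.3 M); per-wavelength baselines drawn once per seed (folded
  ellipticity −12…−8, unfolded −4…−2, gentle slopes) emulate the
  absorbance-normalised far-UV signal shape; Gaussian noise at 2% of the
  matrix range.
* **Plasma time course** — first-order parent splitting feeding the free
  B-chain (dP/dt = −k_s·P; dB/dt = k_s·P − k_l·B) in closed form on the
  incubation grid (0.25–168 h), in % of initial parent, so P + B is
  conserved exactly when chain loss is off.
* **PK profiles** — one-compartment parent (rate k_elim + k_split) with the
  Bateman metabolite curve, dense 0–240 h grid, multiplicative noise, LLOQ
  censoring to NaN.
* **Toy structures** — an ideal poly-Ala α-helix built by internal-coordinate
  (NeRF) placement at φ = −57°, ψ = −47° with user-assigned per-residue B
  values; and a two-chain assembly with one solvent-facing cystine on a
  platform and one cystine enclosed in a carbon shell dense enough to
  exclude the probe (guaranteeing relative exposures > 0.4 and < 0.05
  respectively).

What the generators do **not** emulate: chromatographic peak integration,
instrument drift or correlated noise, three-state unfolding or dimer
dissociation, inter-animal variability, enzymatic (Michaelis–Menten)
saturation, or crystallographic data quality.  Passing recovery tests on
these synthetic inputs demonstrates the estimators are correct and
well-conditioned under the assays' nominal designs — not that real data
meet those assumptions.

## Problem sizes and tolerances

Recovery suites use 50–100 seeded replicates of the standard grids (13–22
redox wells; 21×22 CD matrices), which keeps the full test run within a few
tens of seconds on one CPU.  Noiseless round trips are asserted to
SSE < 1e-10; stochastic recoveries at 2% noise to the widths the designs
support (median |ΔE50| < 2 mV; median |ΔCm| < 0.05 M).  Deposited-structure
analyses (8RRP/6S34/6S4I B-factors, 0.4 Å Cα RMSD, 2.8 Å salt-bridge
distance, disulphide-exposure ordering) require the PDB files, fetched into
`~/.cache/chainsplit/pdb` on first use; without network access or pre-placed
files those specific checks fail with an explanatory error while everything
else runs offline.

## Known limitations

* Absolute E50 values depend on the E°′ convention and any pH correction;
  only the axis construction, rankings and shifts are convention-free.
* The m-value from the global CD fit is reported but more weakly determined
  than Cm; no three-state model is offered.
* Disulphide-exposure percentages depend on the declared reference state
  and radii; comparisons should use identical settings.
* The B29 metabolite's covalent termini are a modelling convention (config),
  pending reference-standard confirmation.
* NCA performs no infinity extrapolation and no dose normalisation across
  species.
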