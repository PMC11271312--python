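# chainsplit

Quantitative analysis of insulin **chain-splitting** — the degradation of
insulin analogues by thiol–disulphide exchange, in which attack of a free
thiol (e.g. glutathione) on one of insulin's disulphide bonds ultimately
separates the molecule into its A-chain (two intrachain disulphides) and
B-chain (one intrachain disulphide), abolishing receptor binding.  For
long-acting analogues such as insulin icodec, whose circulating depot is
exposed to plasma thiols for days, this pathway is a clinically relevant
clearance mechanism, and resistance to it is an engineering goal.

The package is aimed at protein-engineering and DMPK scientists who need the
quantitative layer of such a stability programme: it turns raw assay tables
(plate CSVs, CD matrices, concentration–time profiles, PDB/mmCIF models)
into the standard readouts, and ships seeded simulators that emulate each
assay so every stage is testable offline.

## What it computes

**Redox stability (`chainsplit.redox`).**  The glutathione titration axis via
the Nernst equation, E = E°′ − (RT/2F)·ln([GSH]²/[GSSG]), and the
constrained absolute-IC50 sigmoid y(E) = 100 / (1 + 10^(h·(E50 − E)))
(Top = 100, Bottom = Baseline = 0) whose midpoint **E50** — the potential at
which half the analyte survives a fixed incubation — is the stability
readout.

**Thermodynamic stability (`chainsplit.denaturation`).**  Two-state GuHCl
unfolding under the linear extrapolation model, ΔG(D) = m·(Cm − D), with
per-wavelength linear baselines and a global multi-wavelength least-squares
fit sharing (Cm, m); plus the tyrosine ε₂₇₆ ladder (6.20×10³ M⁻¹cm⁻¹ for
four tyrosines, proportional below) and the refractometric GuHCl
concentration polynomial.

**Masses and metabolites (`chainsplit.analyte`, `chainsplit.chem_mass`).**
Analogues defined as edits on human insulin (substitutions such as A14E,
truncations such as desB30, acyl blocks such as the C20
diacid–γGlu–2×OEG side chain on Lys B29); monoisotopic masses from elemental
compositions (−2 H per disulphide); enumeration of chain-splitting products
(free B-chain, the three A-chain disulphide isomers, the B-chain dimer) and
proteolytic B-chain fragments; matching of observed deconvoluted masses at a
strict <10 ppm tolerance.

**Structure (`chainsplit.structure`).**  Shrake–Rupley SASA and relative
disulphide sulphur exposure against an isolated-cystine reference,
B-factor reports normalised to the B-helix (B9–19) mean, Kabsch Cα
superposition RMSD, and minimum contact distances.

**Plasma stability and PK (`chainsplit.pk`).**  Linear-percent and
log-linear disappearance fits with half-lives (or a "stable within
experiment" flag), and non-compartmental analysis: linear trapezoidal
AUC₀₋₁₆₈ₕ and AUC_last, terminal λz and t½ = ln2/λz, and metabolite exposure
as % of the parent, with below-LLOQ values excluded.

**Simulators (`chainsplit.synthdata`).**  Seeded, bit-reproducible
generators for every input above, including toy crystal structures with
assigned B-factors and a buried-vs-exposed disulphide pair.

## Worked example

```python
from chainsplit.analyte import get_analogue
from chainsplit.chem_mass import enumerate_metabolites, match_masses, parent_species
from chainsplit.redox import fit_redox_stability
from chainsplit.synthdata import SimulationConfig, simulate_redox_plate

icodec = get_analogue("icodec")
print(parent_species(icodec).composition.formula())   # C280H433N71O86S6

for sp in enumerate_metabolites(icodec):
    print(f"{sp.name:20s} {sp.monoisotopic_mass:10.4f}")
# B-chain               4014.0536   (acylated, S-S B7-B19)
# A-chain (6-7,11-20)   2343.9480   \
# A-chain (6-11,7-20)   2343.9480    > one mass, three connectivities
# A-chain (6-20,7-11)   2343.9480   /
# 2B dimer              8028.1072
# B24-B29               1516.8429   (acylated proteolytic fragment)
# B29                    871.5518   (acylated Lys B29)

[hit] = match_masses([4014.06], enumerate_metabolites(icodec))
print(hit.matches[0][0].name, round(hit.matches[0][1], 1), "ppm")
# B-chain 1.6 ppm

plate = simulate_redox_plate(e50_mV=-160.0, hill=0.05,
                             config=SimulationConfig(seed=1, noise_sd=0.02))
fit = fit_redox_stability(plate)
print(round(fit.e50_mV, 1), round(fit.hill_slope, 4))
# -160.4 0.0493
```

The three identical A-chain masses show why the three chromatographic
A-chain isoforms cannot be distinguished by mass alone, and the recovered
E50 of −160.4 mV (generated at −160 mV with 2% noise) illustrates the
precision of the constrained sigmoid readout.

A command-line layer mirrors the library:

```bash
chainsplit simulate redox --seed 1 --out-dir scratch/
chainsplit redox-fit scratch/redox_plate.csv
chainsplit mass-match --analyte icodec --observed observed_masses.csv --ppm 10
chainsplit denat-fit cd_matrix.csv
chainsplit structure-report model.pdb --accession 8RRP
chainsplit pk-nca profiles.csv --parent icodec --window 168 516
```

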