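# apace-pdft

Automated multiconfigurational reaction energetics for small organic
systems: approximate-pair-coefficient (APC) active-space selection,
CASSCF, and multiconfiguration pair-density functional theory (MC-PDFT)
with the translated-PBE on-top functional — plus the diagnostics needed to
tell when a single-reference treatment would have been enough.

## The problem

Transition states and stretched bonds are often *multiconfigurational*: no
single determinant describes them well, so standard DFT and coupled-cluster
results degrade there. CASSCF-type methods fix this by treating all
configurations of A electrons in B active orbitals,

```
|Ψ⟩ = Σ_{n1..nL} C_{n1..nL} |n1 n2 … nL⟩ ,
```

but choosing the active space consistently along a reaction path is the
classic obstacle: an inconsistent choice produces an *active-space
inconsistency error* (ASIE) in ΔE and barrier heights. This package
automates the whole chain and quantifies ASIE as the deviation of each
multireference method from its single-reference limit (SRL).

**Active-space selection (APC).** Every doubly-occupied/virtual pair (i, a)
of the Hartree–Fock solution gets an approximate pair coefficient from the
2×2 CI problem of the paired double excitation i² → a², built only from
Fock and exchange matrix diagonals:

```
A_ia = (Δ_ia − sqrt(Δ_ia² + 4 K_aa²)) / (2 K_aa) ,   Δ_ia = 2 (F_aa − F_ii).
```

Orbital entropies condense these interactions (intermediate normalization):
with p = ΣA²/(1+ΣA²) summed over an orbital's partners,
S = −p ln p − (1−p) ln(1−p). Singly occupied orbitals are forced to the top
of the ranking; the N highest-entropy virtuals (default N = 2) are
successively removed from the sums and forced to the top as well, which
counters the scheme's bias toward doubly occupied orbitals. An APC(A, B)
space is then the A/2 best doubly occupied plus B − A/2 best virtual
orbitals — the same (A, B) for every geometry of a reaction.

**Energy (MC-PDFT / tPBE).** From the CASSCF density ρ and on-top pair
density Π (the probability of two electrons at the same point, contracted
from the 2-RDM):

```
E = V_nn + Σ_pq h_pq D_pq + ½ J[ρ] + E_ot[ρ, Π] ,
```

where E_ot is the PBE functional evaluated on *translated* effective spin
densities: R = Π/(ρ/2)², ρ̃↑,↓ = (ρ/2)(1 ± √(1−R)) for R ≤ 1 and ρ/2
otherwise. Replacing the CAS densities with the determinant's own
(Π = ρ↑ρ↓) gives the single-reference limit **HF-PBE** (density-corrected
PBE) through the identical code path.

**Diagnostics.** Multireference character is scored by the M-diagnostic of
the natural occupations, M = ½(2 − n_HDOMO + n_LUMO + Σ|n_SOMO − 1|), with
M < 0.05 low, 0.05–0.1 moderate, > 0.1 high, and by the leading CI weight
C0². Deviations from the SRL (tPBE↔HF-PBE, CASSCF↔HF; NEVPT2↔MP2 for
imported energies) are aggregated as mean absolute deviations stratified by
M category.

The package contains its own compact electronic-structure engine
(McMurchie–Davidson Gaussian integrals, RHF/ROHF, determinant full CI with
orbital-optimized CASSCF, Becke quadrature grids and a spin-polarized PBE
kernel) sized for small CHON/Li systems: STO-3G is shipped for H–Ne and
cc-pVDZ for hydrogen.

## Worked example

Three XYZ files describe a reaction triple (here: H2 at 0.74 Å as the
"reactant", stretched to 1.5 Å at the "transition state" and to 2.5 Å as
the "product" — a bond homolysis in miniature):

```bash
apace-pdft run --reactant reactant.xyz --ts ts.xyz --product product.xyz \
    --basis cc-pvdz --active 2 2 --grid-level 1 --out h2_report.json
```

prints

```
casscf    dE =     83.03  Ea_fwd =     49.63  Ea_rev =    -33.40  kcal/mol
hf        dE =    165.27  Ea_fwd =     79.38  Ea_rev =    -85.88  kcal/mol
hf_pbe    dE =    130.89  Ea_fwd =     66.02  Ea_rev =    -64.87  kcal/mol
tpbe      dE =    101.10  Ea_fwd =     60.32  Ea_rev =    -40.78  kcal/mol
```

and the JSON report carries the per-state diagnostics:

```
reactant  M = 0.007  low   C0² = 0.996
ts        M = 0.190  high  C0² = 0.905
product   M = 0.701  high  C0² = 0.649
```

Read: near equilibrium the wavefunction is single-reference (M ≈ 0) and
tPBE sits close to its single-reference limit HF-PBE; as the bond breaks, M
climbs toward 1 and the restricted single-reference energies (hf, hf_pbe)
overshoot — the 165 kcal/mol RHF "reaction energy" is the familiar
restricted-dissociation failure, while CASSCF/tPBE stay physical.

`apace-pdft state geometry.xyz` runs a single geometry;
`apace-pdft aggregate reports/*.json --out mad.csv` produces the
category-stratified MAD summary. All flags mirror a YAML config file
(`--config`), and an external table of reference energies
(`label,method,energy_hartree`) can be attached with `--refs`.

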