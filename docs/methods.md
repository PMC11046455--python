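# Methods

This note records the models, numerical choices and limitations behind
`apace-pdft`. Internals are in hartree and bohr; reports are in kcal/mol
(1 hartree = 627.509 kcal/mol) and Å.

## Mean field

Closed shells use RHF; open shells use ROHF (Roothaan single effective
Fock, fa/fb-averaged diagonal blocks, fb closed–open and fa open–virtual
couplings) so that every orbital has an integer occupation in {0, 1, 2} —
the selection scheme needs a categorical doubly-occupied / singly-occupied
/ virtual partition, which an unrestricted mean field would not provide.
Convergence: energy 1e-9 hartree and max |[F, P]| 1e-7, DIIS (8 vectors),
core-Hamiltonian initial guess, deterministic MO phase fixing. If DIIS
stalls — which happens at orbital degeneracies such as homolytic
dissociation limits — the solve is retried with fixed virtual level shifts
(0.25, then 1.0) and, if a converged state violates aufbau ordering, it is
restarted from aufbau-reordered orbitals up to three times. A stationary
non-aufbau solution is accepted as a last resort: at dissociation any
restricted determinant is qualitatively wrong, and the selection layer is
designed to recover from it (see "inverted pairs" below).

The exchange diagonal K_pp consumed by the selection is that of the
exchange matrix of the **total** (alpha + beta) density, evaluated in the
converged MO basis — the same basis as the Fock diagonal.

## Pair coefficients, entropies, selection

The pair coefficient of a doubly-occupied/virtual pair is the ground-state
mixing coefficient of the 2×2 CI problem between the reference and the
paired double excitation, with the excitation gap estimated as
Δ = 2(F_aa − F_ii) and the coupling by the exchange diagonal K_aa:
A_ia = (Δ − sqrt(Δ² + 4K_aa²))/(2K_aa). At K_aa = 0 the expression is
singular; the Δ > 0 limit (A = 0) is used and a diagnostic naming the pair
is emitted when the gap is nonpositive.

Orbital entropies use intermediate normalization: the excitation weight
touching orbital p is p_exc = ΣA²/(1 + ΣA²) (sum over its partners), and
S_p is the two-state entropy of that weight. Interactions with singly
occupied orbitals are never computed; SOMOs are an ordered forced-top
class, not a numeric sentinel — this avoids floating-point comparisons
against infinities.

**Virtual removal.** The highest-entropy virtual is removed from the sums
and entropies are recomputed, N times (default N = 2); removed virtuals
join the forced-top class below the SOMOs. Among removed virtuals the
*first* removal ranks highest: it was the globally strongest correlator,
and with a single virtual quota slot (APC(2,2)) any other order can drop
the essential antibonding partner — twisted ethylene loses its π* orbital
and all static correlation with it. If a molecule has fewer virtuals than
N, the removal count is capped at the virtual count.

**Inverted pairs.** A pair with Δ ≤ 0 (possible when the mean field
converged to a degenerate or hole state) has a divergent pair coefficient
that the entropy map sends to zero — precisely the pair that must be in the
active space. Members of such pairs are forced to the top of their
occupation classes (below SOMOs) and excluded from the entropy sums. This
is a robustness extension for degenerate dissociation limits; for a healthy
aufbau mean field it never triggers.

**Quota.** APC(A, B) takes the A/2 highest-ranked doubly occupied and
B − A/2 highest-ranked virtual orbitals; open shells first take all S
SOMOs, then (A−S)/2 doubly occupied and B − S − (A−S)/2 virtuals. Ties are
broken by smaller |F_pp − F_HOMO| (prefer frontier orbitals), then lower
index. Core orbitals are candidates like any others; their entropies are
negligible so they self-select out. The selection trace (orbital,
occupation, entropy, forced, selected) is embedded in every report.

## CASSCF

Full CI in the active space over (alpha-string, beta-string) determinants;
spin purity at fixed Sz is enforced by diagonalizing H + λ(S² − S(S+1))
with λ = 0.5 hartree (H and S² commute, so this only reorders roots, it
cannot bias the energy of the selected one). Dense diagonalization up to
600 determinants, Lanczos above. Orbital optimization minimizes the CASCI
energy over core–active, core–virtual and active–virtual rotations,
parametrized as U = exp(κ); gradients are exact (generalized Fock,
chain-ruled through the matrix exponential with its Fréchet derivative) and
the surface is minimized with L-BFGS to max-gradient 1e-6. The initial
orbitals are exactly the APC-selected mean-field orbitals, reordered into
[core | active | virtual]; no frozen core. Convergence failures flag the
result; downstream energies then require an explicit override and the state
is reported as unreliable rather than silently dropped.

Natural occupations are the eigenvalues of the active 1-RDM; the 2-RDM is
stored in chemist order with E_2e = ½ ΣΓ_pqrs(pq|rs).

A first-order optimizer inherits CASSCF's well-known local-minimum
behavior: if the selected active orbital is qualitatively wrong (e.g. a
tight virtual instead of σ* for H2/cc-pVDZ near equilibrium, where the
diagonal-only coupling estimate K_aa outweighs the small gap difference),
the optimizer stays in the corresponding basin rather than tunneling to the
global minimum. This is the active-space inconsistency phenomenon the
package exists to quantify, not an error state; the deviation-from-SRL
machinery makes it visible.

## Grids and the PBE kernel

Becke atomic partitioning (thrice-iterated smoothing polynomial, no
atomic-size adjustment), Gauss–Chebyshev radial points mapped by
r = (1+x)/(1−x) bohr, and a Gauss–Legendre × uniform-φ angular product
grid. Levels 0–4 map to (radial, θ) counts (35,10) … (140,30); the default
level 2 (75, 18) integrates the mean-field density to ~1e-9 relative for
the shipped systems, comfortably inside the 1e-6 contract. AO values and
gradients are tabulated once per grid.

Exchange-correlation is spin-polarized PBE: exchange through the exact
spin-scaling relation with enhancement factor κ = 0.804,
μ = 0.2195149727645171; correlation is the PW92 local part (standard
parameter sets for ε_c(rs,0), ε_c(rs,1), −α_c) plus the PBE H gradient
correction (β = 0.06672455060314922, γ = (1−ln2)/π²). The kernel is a pure
function of the spin densities and gradients; negative input densities
raise (they indicate an upstream translation bug). Points with total
density below 1e-12 a.u. contribute zero.

## MC-PDFT

ρ and Π on the grid follow the CAS block structure: the inactive space
contributes as a closed-shell determinant, Π = ρ_c²/4 + ρ_c ρ_a/2 + Π_act,
with Π_act contracted from the active 2-RDM. The translation is the
original "t" scheme: R = Π/(ρ/2)², effective spin densities
(ρ/2)(1 ± √(1−R)) for R ≤ 1, clamped to the unpolarized point for R > 1,
and gradients carried by the same pointwise factors (∇Π is not used).
E = V_nn + h·D + ½J + E_ot; the CASSCF energy itself never enters. HF-PBE
feeds the determinant's densities (Π = ρ↑ρ↓) through the identical path; a
separate direct-PBE route (no translation, no Π) exists so the
single-reference-limit identity is a genuine two-path check rather than a
tautology. Grid-point batching (40k points) bounds memory for larger
active spaces.

## Diagnostics and aggregation

M-diagnostic roles are assigned from the *reference* occupation pattern
recorded in the active space's provenance tags: sort natural occupations
descending; the least-occupied of the first n_docc is the HDOMO, the
most-occupied of the virtual block is the LUMO, SOMO occupations sit in
between. An active space with no virtual-role orbital (e.g. a lone H atom
in APC(1,1)) has no defined M; the pipeline records the energies and notes
the missing diagnostic instead of failing. Boundary values M = 0.05 and
M = 0.1 classify into the lower category (the defining inequalities are
strict; at float resolution the choice is immaterial).

Two-state quantities are stratified by the larger of their endpoint M
values (ΔE by max of reactant/product, barriers by max of the two states
they connect): a quantity is as multireference as its most multireference
endpoint. MADs are reported per (method pair, quantity, category) with
counts; empty categories are absent, not zero.

## Pipeline conventions

Reaction triples are all-atom "preassociated" geometries sharing one
element multiset, charge and multiplicity; geometries are inputs and are
never re-optimized. All three states use the same (A, B) size but
independently selected orbitals — size consistency of the active space is
enforced, orbital identity deliberately is not. Imported reference
energies (e.g. CCSD(T), NEVPT2, MP2) join the comparison tables by state
label but are never computed; NEVPT2↔MP2 deviations appear only when both
are imported. Reports are JSON at full precision with the resolved config
and per-state selection traces embedded, plus a 2-decimal CSV summary;
repeated runs produce byte-identical reports.

## What the built-in systems do and do not show

The test systems (H2 stretching, linear H4, twisted ethylene,
trimethylamine) are desk-scale analogs of the correlation regimes a
reaction benchmark contains: smooth single- to multireference crossover,
polyradical character, a strongly multireference closed-shell "transition
structure", and an ordinary single-reference organic molecule. Passing
tests on them demonstrates the correctness of the selection algebra, the
translation identities, the dissociation limits and the bookkeeping — not
quantitative accuracy for general organic reactions, which depends on
basis sets (the shipped library is STO-3G for H–Ne plus cc-pVDZ for
hydrogen) and on active-space sizes larger than these molecules need. The
acceptance script's small reaction set reproduces the qualitative ordering
expected of the method — tPBE tracks its single-reference limit far more
closely than CASSCF tracks HF in low-M cases, and both deviate strongly in
high-M cases — on a handful of reactions, not at benchmark scale.

## Known limitations

* Determinant CI is dense/Lanczos without direct-CI acceleration; active
  spaces beyond ~(8,8) singlets are impractical.
* The orbital optimizer is first-order (exact gradient, approximate
  curvature); no stability analysis is performed after convergence.
* Cartesian d shells are supported by the integral code but no shipped
  basis uses them; heavier-element chemistry is limited to STO-3G quality.
* ROHF uses one fixed effective-Fock coupling scheme; no second-order SCF.
* No analytic nuclear gradients anywhere — geometries are strictly inputs.
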