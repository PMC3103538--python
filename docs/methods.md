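# Methods

## Scope and model

`multipk` predicts pK₁/₂ values of protein ionisable groups from continuum
electrostatics evaluated on conformer ensembles. It consumes pre-generated
conformers (PDB files, multi-model files treated as ensembles); it does not
run molecular dynamics. Three protonation regimes tag the ensembles: allC
(all ionisable groups charged, tyrosine neutral), glu0 (glutamates neutral,
rest charged) and lys0 (lysines neutral, rest charged).

### Microstates and state energy

Each titratable site carries a catalogue of microstates: protonation state
plus hydrogen placement. Defaults: two charge-distinct states for
carboxyls, amino groups, hydroxyls and termini; three for imidazoles (Nδ-H
and Nε-H neutral tautomers plus the doubly protonated form); an optional
three-state carboxyl mode resolves the proton on either oxygen. Because a
site with g degenerate microscopic states on one side of a protonation
equilibrium has its macroscopic midpoint shifted by log₁₀ g, the
microscopic standard pK values are degeneracy-corrected (imidazole:
pK_micro = pK_mod + log₁₀ 2; three-state carboxyl: pK_mod − log₁₀ 2) so an
isolated site always titrates at pK_mod. Model pK values: Glu 4.4, Asp
4.0, Lys 10.4, Tyr 9.6, His 6.4, N-terminus 7.5, C-terminus 3.8, Arg 12.5.
Arginine is detected but excluded from titration by default (guanidine
stays protonated across the usual range); `include_arg=True` overrides.

The reference state of the system is **all sites neutral**. State energies
are

ΔE(x) = Σᵢ [Δnᵢ·ln10·kT·(pH − pK_int,i) + gᵢ] + Σᵢ<ⱼ W(i,xᵢ; j,xⱼ),

singleton terms per site, pairwise couplings counted once. Tautomers of
the reference charge state enter through the pH-independent offset gᵢ.

### Electrostatic terms

All energies are computed from the charge difference Δq between a
microstate and the site's reference microstate, placed on the heavy atoms
of the functional group. Input snapshots therefore never need hydrogens;
the "multiple hydrogen location" physics lives in the per-microstate charge
sets. For each non-reference microstate the package runs four focused
finite-difference LPB solves: heterogeneous and homogeneous-reference
(uniform protein dielectric) solves of Δq in the whole protein and in the
model compound — the site's side-chain (or terminal) fragment excised with
its own charges, same conformation, alone in solvent. Then

* ΔpK_Born: difference of reaction-field self-energies ½ΣΔq(φ_het − φ_hom)
  between protein and model compound, divided by −Δn·ln10·kT. Conformation-
  matched model compounds cancel geometry artefacts; with identical fine
  grids around the sources the grid self-energy cancels exactly.
* ΔpK_perm: interaction of Δq's screened potential with all non-titratable
  partial charges, including the dielectric correction for the fragment's
  own background charges (protein minus model-compound potential).
* ΔpK_ref: interaction with the other titratable sites' reference charge
  distributions (zero when all reference forms are neutral in net charge
  but nonzero in general through their partial charges).
* W(i,xᵢ; j,xⱼ): Σ over site j's Δq atoms of Δq·φ from site i's protein
  solve; the two one-sided estimates are averaged and their maximum
  discrepancy recorded (`SiteEnergyTable.asymmetry`).

The sign convention −ΔG/(Δn·ln10·kT) makes every correction additive,
pK_int = pK_mod + ΔpK_Born + ΔpK_perm + ΔpK_ref, raising acid pK values
and lowering basic ones for destabilising environments.

### The solver

The linearised Poisson–Boltzmann equation ∇·(ε∇φ) − ε_s κ² φ = −4πCρ is
discretised on regular grids with a 7-point stencil. Dielectric values
live on edge midpoints as the harmonic mean of four sample points along the
edge (series combination across the boundary), which restores smooth
first-order convergence of Born-type energies; the binary midpoint rule
oscillates with boundary/grid alignment. The molecular volume is the union
of atom spheres inflated by the 1.4 Å solvent probe (an
accessible-volume approximation; the re-entrant correction of a true
molecular surface is deliberately omitted and flagged as an approximation).
Ions are excluded within probe + 2.0 Å of any atom; outside, the screening
coefficient is ε_s κ² with κ the Debye constant for the configured ionic
strength. Charges spread trilinearly; boundary potentials are analytic
Debye–Hückel sums over the source charges. The symmetric positive-definite
system is solved by Jacobi-preconditioned conjugate gradients (relative
tolerance 1e-8); non-convergence raises with the residual attached.

Two-stage focusing: a coarse solve (default 1.0 Å spacing, 8 Å padding)
over the whole system supplies Dirichlet values for a fine grid (default
0.4 Å, 6 Å margin) around the source charges. The fine-grid geometry
depends only on the sources, so matched solves share their discretisation.
All grids are centred on the bounding-box centre of what they cover; a
consequence worth noting is that a mirror-symmetric dimer sees an exactly
mirror-symmetric discretisation, making the ΔpK = 0 symmetry check hold to
solver tolerance rather than to grid-placement luck, and whole-system
translations leave energies bit-identical. `origin_shift` in `PBConfig`
deliberately breaks the centring to probe discretisation sensitivity.

Accuracy at defaults, against closed forms: Born ion (2 Å sphere, 4/78)
2.0% at 1.0 Å spacing, 1.2% at 0.5 Å, 0.02% at 0.25 Å; off-centre charge
(Kirkwood series) 0.3% at 0.3 Å; two-charge Coulomb in uniform water 0.6%
at 0.4 Å.

### Titration

`populations_exact` enumerates the state space (default cap 2²⁰ states,
chunked, with per-pH max-subtraction for overflow safety).
`populations_mc` runs one Metropolis chain per pH point, vectorised across
the grid: per sweep one single-site flip proposal per site (uniform over
the site's *other* microstates) plus paired flips for site pairs whose
|W| exceeds 2 pK-unit equivalents. Defaults: 10⁴ sweeps after 10³ burn-in,
fixed seed, bitwise reproducible. Errors are batch-means standard errors
reported conservatively — the upper 95% confidence bound of the
16-batch estimate, floored at one part per effective sample
(sweeps × acceptance rate) for microstates never or always observed. The
conservative choice is deliberate: a naive small-batch estimate
underestimates its own noise, and downstream 3σ consistency checks across
hundreds of grid points would then flag false alarms.

### Ensemble averaging, regime weights, pK₁/₂

Per-site protonated-fraction curves are arithmetically averaged over the
snapshots of each regime. The regime weights are built from the calculated
ionisation of the groups that define each regime: W_glu0 = 1 − ⟨θ_carb⟩
from the glu0 set, W_lys0 = ⟨θ_amino⟩ from the lys0 set, W_allC as the
complement, clamped at zero and renormalised (logged) if the flanking
transitions overlap. ⟨·⟩ is the arithmetic mean over sites, each site's θ
snapshot-averaged first (order is immaterial by linearity, but averaging
precedes weighting). By default the θ̄ means run over the *side-chain*
classes only (Glu+Asp carboxyls; Lys aminos): the regime protocols keep
the chain termini charged, so termini do not define regime populations —
on small peptides their strongly shifted pK values would otherwise
contaminate the weights. `weight_sites` switches to "with-termini" or
"glu-only".

pK₁/₂ is the linear-interpolated 0.5-crossing of the combined
protonated-fraction curve; multiple crossings return the one nearest the
model pK and set a multimodality flag, no crossing sets an out-of-range
flag instead of erroring. Chain-averaged values are arithmetic means over
chains; ΔpK = pK(chain A) − pK(chain B) for homologous pairs.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| eps_protein / eps_solvent | 4 / 78 | relative dielectrics |
| ionic_strength | 0.14 mol/L | 1:1 electrolyte, Debye screening |
| temperature | 298 K | enters kT and κ |
| probe_radius / ion_exclusion | 1.4 / 2.0 Å | surface and Stern layer |
| grid_spacing_coarse / fine | 1.0 / 0.4 Å | focusing stages |
| grid_padding / focus_margin | 8 / 6 Å | box construction |
| pH grid | 0–14, step 0.1 | titration range |
| MC sweeps / burn-in / seed | 10⁴ / 10³ / 1 | sampler defaults |
| state cap | 2²⁰ | exact-enumeration limit |

## Parameter table

The shipped charge/radius table (`data/charges_radii.tsv`) is the package's
own heavy-atom set: hydrogens are folded into their heavy atoms, each
(residue, variant) block sums exactly to the variant's formal charge, and
cavity radii are element-typed (N 1.55, O 1.50, S 1.85, carbonyl/aromatic C
1.70, aliphatic united C 2.00 Å). It is deliberately simple and
self-contained rather than a copy of any published force field; users can
supply their own table in the same four-column format.

## Synthetic data

The fixture generator builds toy peptides: extended backbones (3.8 Å
residue spacing, carbonyl pointing away from the side chain), side chains
alternating above/below the chain, functional-group tips at controlled
distances. A "salt bridge" is a charged pair at 2.8–3.0 Å donor–acceptor
distance. Regime ensembles are jittered copies (Gaussian σ, default
0.3 Å); in the glu0/lys0 ensembles the bridge-partner chain is moved 5 Å
away, emulating bridge loss when one partner is neutralised. Mirrored
dimers mirror chain A's jitter onto chain B exactly. Defaults mirror a
50 ps/14 ns sampling cadence (280 snapshots); tests and the acceptance
script use 2–3 snapshots and 0.25 pH steps to keep each pipeline run in
seconds-to-a-minute on one CPU.

What the toys do **not** emulate: real secondary structure, packing and
burial, thermalised (Boltzmann-weighted) conformer distributions,
counterions, or any force-field energetics. Passing tests therefore
demonstrate the correctness of the electrostatics, the statistical
mechanics and the combination logic — not prediction accuracy on real
proteins, which the bundled benchmark table addresses separately.

## Numerical choices and degenerate inputs

* CG tolerance 1e-8 relative; Jacobi preconditioning; SPD by construction.
* Population normalisation is exact to 1e-9 in enumeration; Monte Carlo
  populations are counts and normalise by construction.
* pK₁/₂ interpolation error on a 0.1 grid is < 0.005 for logistic curves.
* Zero-charge systems give identically zero potentials (empty boundary
  sums), not noise.
* Curves flat at 0.5, multiple 0.5-crossings and out-of-range midpoints
  are flagged, never silently resolved.
* Snapshot ensembles must share residue topology; sites are detected once
  and indexed by (chain, residue, terminus flag).

## Known limitations

* The accessible-volume surface overestimates the low-dielectric region in
  crevices (no re-entrant correction).
* W couplings use the linear-response shortcut Σ q·φ with no
  self-consistency iteration.
* The pH-dependent regime weights are a heuristic interpolation between
  regimes, not a rigorous thermodynamic linkage of conformational and
  protonation free energies; the construction is the minimal one satisfying
  the stated limits and Σ W_S = 1.
* Proline N-termini and disulfide-bonded cysteines are not special-cased.
* Monte Carlo standard errors are deliberately conservative (see above);
  users wanting tight error bars should raise the sweep count rather than
  trust the bound.
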