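# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and
the known limitations.

## Interface detection and contact classification

The interface criterion is the **minimum heavy-atom/heavy-atom
distance** between two residues, cutoff 6.0 Å by default. Hydrogens are
excluded so the residue set does not depend on whether a structure
carries hydrogens. One contact is emitted per residue pair with the
minimum distance attained; the result is provably identical to an
all-pairs O(N²) scan (tested against one) and symmetric under swapping
the two chain sets.

Contact classes are assigned by the first matching rule in fixed order:

| rule | criterion | default |
| --- | --- | --- |
| salt bridge | opposite formal-charge side-chain N/O pair | ≤ 4.0 Å |
| hydrogen bond | donor–acceptor heavy pair; with hydrogens present additionally D–H···A ≥ 150° | ≤ 3.5 Å |
| cation-π | Lys NZ / Arg CZ to Phe/Tyr/Trp ring centroid, within 45° of the ring normal | ≤ 6.0 Å |
| hydrophobic | apolar side-chain carbon pair | ≤ 4.5 Å |

These are standard literature thresholds; all are config-overridable
(`ContactCriteria`). Residues with missing side-chain atoms are
classified from the atoms present, with a logged warning. Ordering makes
classification deterministic: a pair that satisfies both the salt-bridge
and hydrogen-bond geometry is a salt bridge.

PDB reading and writing are delegated to biotite behind the module
surface; a fixed-width pre-validation pass reports malformed records
with their line number. Alternate locations resolve to the
highest-occupancy conformer. Duplicate atoms at identical coordinates
are rejected at parse time. Multi-MODEL files represent ensembles.

Superposition is least-squares rigid (Kabsch, proper rotation enforced),
pairing atoms by (chain, residue, atom name) with an explicit
`pair_by_index` escape hatch when residue identities differ (e.g.
mutant-vs-wild-type backbones). RMSD is invariant under rigid motion of
the mobile structure to < 1e-6 Å (property-tested), which is the
machinery behind Cα-RMSD claims of backbone preservation.

## Design rules

Per classified contact, the A-side (receptor) residue receives proposals
from whichever rules the partner residue activates:

* **hydrophobic** (partner apolar): candidates {W, F, L, I, Y} with
  side-chain volume strictly greater than the wild type's, ranked by
  Kyte–Doolittle hydropathy (most hydrophobic first). "Larger" is
  side-chain volume on the Zamyatnin scale (residue volume minus
  glycine).
* **charge** (partner carries a formal charge): the opposite-charge pair
  — E then D against a cation, K then R against an anion.
* **hydrogen bond** (partner polar or charged): polar candidates
  {N, Q, E, K} whose **side-chain reach** — the maximum side-chain
  heavy-atom distance from CA in the extended template — is at least the
  wild type's minus 0.5 Å, ranked smallest volume first (most
  conservative substitution). Reach rather than volume is used because
  the operative geometric question is whether the donor/acceptor can
  span the gap to the partner: Gln reaches as far as the His imidazole
  despite a smaller volume, and it is exactly such substitutions
  (H→Q, V→N) that the published design set contains.

Proposals are a pure function of (contacts, property table,
max_per_site), ordered by position, rule, rank, and never include the
wild type or a smaller apolar residue under the hydrophobic rule. The
engine regenerates 22 of the 24 substitutions named in the source
analysis; the two exceptions, F63L (a *smaller* hydrophobic residue) and
A158F (a space-filling substitution argued to buttress a neighbouring
hydrogen bond), reflect manual designer judgment outside the three
rules and are documented as such in the variant fixture.

**Mutant builder.** Fixed backbone: N, CA, C, O and CB keep their input
coordinates bit-for-bit; the side chain beyond CB is grown from
internal-coordinate templates (NeRF placement) in each rotamer of an
embedded χ grid ({−60°, 60°, 180°} per variable χ, ≤ 9 combinations) and
the rotamer with the fewest heavy-atom clashes (< 2.5 Å) against the
rest of the structure wins, ties to the first enumerated. Glycine sites
get a CB constructed from backbone geometry (warned). This is a
deliberately simple stand-in for rotamer-library model building; it is
adequate here because the apo mutant structures of this system show the
backbone and Cβ positions unchanged.

## Energetics

Direct pairwise sums between two disjoint atom groups, no cutoff, no
periodicity, no reaction field:

* Coulomb: `E = f Σ q_i q_j / r_ij`, `f = 138.935485 kJ mol⁻¹ nm e⁻²`,
  coordinates converted Å → nm internally.
* Lennard-Jones 12-6 with Lorentz–Berthelot combination.
* Hydrogen bonds: D–A ≤ 0.35 nm and H-D-A ≤ 30° (the convention of the
  trajectory tool this readout mirrors); counted in both directions
  between the groups; a `distance_only` flag covers hydrogen-free
  topologies.

Ensemble quantities are uniform means over snapshots. The
mutant-minus-wild-type decomposition restricts group A to the mutated
residues (the corresponding wild-type residues on the wild-type side)
and group B to the whole target chain — computing whole-complex energies
would be noise-dominated, which is why the decomposition is restricted
to the mutated sites. Super-additivity is
`double − (single₁ + single₂)` per term.

**Parameters.** The embedded table is a reduced polar-hydrogen set: every
residue's charges sum exactly to its formal charge at pH 7 (validated),
apolar carbons are neutral, polar groups carry chemically signed
charges, LJ σ/ε are assigned per element, and water is three-site with
TIP3P charges. The table ships as data keyed by (residue, atom), is
exportable/replaceable as CSV, and is **not** a calibrated force field:
absolute energies from it are not comparable to published MD averages,
which depend on the force field, solvation and trajectory. Published
ΔCoulomb/ΔLJ/ΔHB tables are therefore treated as *inputs* to the
additivity statistic, while the energy kernels themselves are verified
against analytic limits (two unit charges at 1 nm; LJ zero at σ and
minimum −ε at 2^{1/6}σ) and against a naive double-loop oracle at 1e-9
relative tolerance.

## SPR kinetics

Closed-form 1:1 Langmuir forward model (association + dissociation,
continuous at the phase boundary), additive Gaussian noise with a fixed
seed. Fitting is global nonlinear least squares (lmfit/leastsq) sharing
(k_a, k_d, R_max) across concentrations, in log₁₀ space for the rates so
positivity and scaling are automatic; per-curve local fitting is
available behind a flag. Initial guesses are deterministic: k_d from a
log-linear regression of the dissociation tail of the largest-response
curve, k_a from the linearized observed rate k_obs ≈ k_a C + k_d across
curves. An ill-conditioned Fisher information (or a single
concentration) raises an identifiability warning; a flat curve is an
error.

Default protocol constants mirror the experiment: 90 s association,
1800 s dissociation, five concentrations geometrically spanning
4 nM – 2 µM, R_max = 100 RU, noise 2 RU. Under these conditions the fit
recovers generating rates to ~1e-13 relative error noiselessly and K_D
to well under 10 % at 2 RU noise — except for picomolar binders whose
dissociation (k_d ≈ 5e-7 s⁻¹) decays < 0.1 % within the 30-minute
window; their K_D is weakly identified from noisy data, a limitation the
underlying protocol shares.

Table arithmetic: `K_D = k_d/k_a`; `fold = K_D^{wt}/K_D^{mut}`; summary
counts exclude the wild-type row. The validator flags rows where the
stored K_D deviates from k_d/k_a by > 5 % and folds inconsistent with
the K_D ratio by > 10 % (absorbing printed rounding); on the published
single-mutant table it flags exactly one row (H159Q, 8.7 % off — most
plausibly a mean-of-ratios vs ratio-of-means artifact across
replicates), which is surfaced, not corrected.

## Synthetic data

* **Toy complexes** plant one residue pair per requested contact class
  with idealized geometry that satisfies exactly that class's rule
  (e.g. the Ser donor hydrogen is placed on the D→A axis; the Arg CZ
  sits on the ring normal), isolated by 14 Å spacing; spacer residues
  are glycines 25 Å from the partner chain. Unsatisfiable
  (class, distance) pairs are rejected.
* **The benchmark complex** reconstructs the decoy-receptor/MD2
  interface *topology*: 16 receptor residues (the 14 design sites plus
  the two pre-hydrogen-bonded positions 183/209) at author numbering,
  each placed within the 6 Å criterion of its mapped MD2 partner
  (Ile-66, Arg-68, Asp-99, Arg-106, Leu-108, Lys-109, Glu-111). Only
  identities, numbering and adjacency are taken from the published
  interface map; coordinates are synthetic. It exercises the scan,
  classification, design and mutant-building machinery; it does not
  reproduce crystal geometry.
* **Ensembles** are i.i.d. Gaussian positional perturbations
  (default σ = 0.3 Å per coordinate) of a reference structure — a
  stand-in for the fluctuations of an equilibrated trajectory window
  with no kinetics, no correlated motions and no solvent dielectric.
  The optional water shell is a 3.1 Å lattice within 6 Å of the
  interface, clash-culled at 2.6 Å, with fixed orientations: water
  *counts* and their exclusion by bulky substitutions are meaningful;
  water interaction energies are not physical solvation energies.
* **Sensorgram sets** use the experimental protocol defaults above.

Consequently, passing tests demonstrate correctness of the geometric
operators, energy kernels, statistics and fitting machinery — not that
the reduced parameter set reproduces MD-derived energy magnitudes, nor
that synthetic ensembles reproduce conformational sampling of real
trajectories.

## Numerical choices and degenerate inputs

Coordinates are Å at every module boundary, nm internally for energies;
energies are kJ/mol throughout. Zero interatomic distances are errors in
the energy kernels and at PDB parse time. Rotations are kept proper by
determinant correction. Classification tie-breaks are by rule order;
rotamer ties by enumeration order; altloc ties by letter order. The
pipeline is deterministic for a fixed config + seed (byte-identical CSV
outputs, tested), seeds all child generators from a single
`SeedSequence`, and stamps every output table with the config hash.

## Limitations

* The rule engine encodes the three published design classes; it does
  not score candidates energetically (no ΔΔG prediction) and cannot
  reproduce expression-driven triage of variants.
* The mutant builder is fixed-backbone with a coarse χ grid: adequate
  for rigid repeat-protein scaffolds, wrong wherever substitution
  perturbs the backbone.
* No cutoff/PME/solvation in the energy kernels: suitable for
  group–group decomposition re-runs at desk scale, not for simulating
  or scoring whole systems.
* Mass transport, drift, bulk refractive-index steps and bivalent
  binding are outside the 1:1 Langmuir model.
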