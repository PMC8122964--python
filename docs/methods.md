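# Methods

## Problem setting

A protein-structure refinement engine takes one predicted model and
searches its conformational neighborhood for structures that score better
under several energy functions at once. Because no single energy reliably
ranks near-native conformations for all proteins, the search is posed as a
multi-objective minimization of an energy vector F(C) = (f1, ..., fM),
M >= 2 (three by default), over backbone torsion space, and returns a set
of trade-off (Pareto) solutions rather than a single minimum.

## Conformation model

The optimization variable is the chain of backbone torsions
(phi_i, psi_i, omega_i), in degrees, wrapped to (-180, 180]. By convention
residue 1 has no phi and the last residue no psi/omega; those slots are
stored as NaN, never as 0. Cartesian coordinates for the backbone atoms N,
CA, C are regenerated from torsions by sequential atom placement: each new
atom is positioned from the previous three using a fixed bond length, a
fixed bond angle and the free torsion, with the canonical first frame (N1
at the origin, CA1 on +x, C1 in the xy-plane). Covalent geometry uses
standard values (N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A; N-CA-C 111.2
deg, CA-C-N 116.2 deg, C-N-CA 121.7 deg), configurable through
`GeometryParams`. The inverse direction measures standard dihedrals; the
round trip is exact to well below 1e-6 degrees. When an input PDB carries
non-ideal covalent geometry, the measured torsions are exact but the
regenerated Cartesians use ideal geometry; the resulting one-time RMSD
drift is reported at startup by the CLI.

Omega stays at its input value during sampling (peptide bonds remain near
trans); a flag enables omega perturbation. The optimizer itself moves flat
angle vectors through a `SearchSpace` abstraction — `TorsionSpace` with
circular arithmetic for proteins, `BoxSpace` (clipped [0,1]^n with
absorbing walls) for benchmark landscapes — so one engine serves both
domains.

## Decomposition and scalarization

Weight vectors come from the simplex-lattice design with H divisions:
every lambda has components in {0, 1/H, ..., 1} summing to 1, giving
N = C(H+M-1, M-1) subproblems (H=10, M=3 -> N=66). Subproblem i minimizes
the penalty-based boundary intersection (PBI) value

    g(F | lambda_i, z*) = d1 + theta * d2,

with d1 the distance travelled along the ray z* + t lambda_i (convergence)
and d2 the perpendicular deviation from the ray (direction error /
diversity). The ideal point z* is the running component-wise minimum of
all evaluated objective vectors. The penalty theta rises linearly from 5
to 20 over the run: small early values favor convergence, large late
values enforce direction diversity. Each subproblem exchanges information
with its neighborhood B(i), the T = 8 weight vectors closest in Euclidean
distance (self included; ties break to the lower index).

Zero components in lambda are kept as-is — PBI, unlike the Tchebycheff
form, is well defined with them.

### Objective normalization

By default PBI distances are computed on raw energies. This is correct
when the objectives share a scale, but when one objective spans an order
of magnitude more than the others (the surrogate compactness term spans
~600 units against ~30 for the other two), every weight ray effectively
collapses onto the large-scale objective and the decomposition
degenerates. `normalize_objectives` therefore rescales each objective to
(F - z*) / (nadir - z*) inside the scalarization, with the nadir estimated
per generation from the swarm's pbest set. The population estimate is
preferred over the archive because the archive retains extreme corner
solutions forever, which permanently inflates the span of an objective and
squashes it out of every subproblem. The option is off by default and on
in the refinement profile.

## Swarm dynamics

One particle per subproblem. Velocities follow the canonical update
v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x) with c1 = c2 = 2, inertia
w decaying linearly 1.3 -> 0.7, and angle differences taken as shortest
signed circular distances. r1, r2 are drawn once per particle per
generation and shared across angles by default; the refinement profile
draws them per angle, which explores better on the separable
torsion-restraint landscape. pbest and gbest replacements require strictly
smaller scalarized values, always recomputed from stored objective vectors
at the current z* and theta(t), so stored bests are re-judged consistently
as the ideal point drifts. Particles are processed in ascending index
order and gbest updates apply immediately within a generation. Every
evaluated solution is offered to an unbounded (optionally capacity-pruned)
Pareto archive with the usual semantics: rejected if dominated or a
duplicate, otherwise inserted after evicting everything it dominates.

Velocities are clamped per angle. The clamp matters more than it may
appear: for c1 = c2 = 2 the swarm is second-order (variance) divergent for
any inertia below roughly 0.78 — the critical mean attraction
phi* = 12(1 - w^2)/(7 - 5w) is about 1.75 at w = 0.7, below the actual
phi = 2 — so particle oscillation never contracts on its own and the clamp
sets the effective sampling step. The default clamp is 60 deg/generation.
An optional linear clamp schedule (`velocity_clamp_end`) anneals the step
over the run; this is what turns the late-phase sampler into a refiner.

### Refinement profile

`PSOConfig.refinement_profile(deviation_sigma)` encodes the package's
desk-scale defaults for surrogate-energy refinement, derived from the
analysis above rather than from the plain-algorithm defaults:

| parameter          | value                  | rationale                                   |
|--------------------|------------------------|---------------------------------------------|
| perturb_sigma      | deviation_sigma        | population brackets the input at its own deviation scale |
| velocity_clamp     | deviation_sigma / 3    | refinement is local search; steps must be smaller than the distance still to travel |
| velocity_clamp_end | 1 deg                  | final polish at degree resolution           |
| per_component_r    | on                     | separable restraint landscape               |
| normalize_objectives | on                   | surrogate scales are incommensurate         |
| archive_capacity   | 500                    | crowding-pruned; bounds run-end model set   |
| max_iter           | 1000                   | enough generations for the annealed clamp to reach the polish regime |

## Energies

The engine only requires the `EnergyModel` contract: a named,
deterministic, lower-is-better scalar of a conformation. Production force
fields are external programs; `ExternalScorerAdapter` documents the
shell-out contract (write PDB, invoke scorer, parse one float) and is
exercised with mocks. Three built-in surrogates make the pipeline testable
end to end:

* **clash**: soft-sphere repulsion sum max(0, r_min - d)^2 over backbone
  atom pairs more than 3 positions apart along the N-CA-C chain
  (r_min = 2.5 A);
* **compactness**: squared radius of gyration of the CA trace;
* **torsion preference**: per-residue harmonic restraint
  d^2 / (2 w^2) on the circular distance of (phi, psi) from a basin
  center, default the alpha-helical (-57, -47) with w = 30 deg. The
  quadratic form mirrors the torsion restraints used in refinement and
  keeps energy ordering consistent with overall closeness to the basin; a
  saturating form would rate a chain with a few wildly wrong angles above
  one with many slightly displaced angles.

Compactness conflicts with both other terms (collapse causes clashes and
bends ideal helices), so the three-objective front is non-degenerate.

Two benchmark landscapes with closed-form fronts validate the optimizer on
real vectors: `dtlz2` (front = unit-sphere octant) and `convex-plane`, a
unimodal landscape built here with front f1 + f2 + f3 = 1 via the simplex
parameterization (x0 x1, x0 (1 - x1), 1 - x0) scaled by 1 + g,
g = sum (x_i - 0.5)^2 over the remaining variables (7 variables total: 2
position + 5 distance).

## Model selection

Archived solutions are ranked by expected utility: U(C, w) = w . F(C)
averaged over S weights drawn uniformly from the simplex (flat Dirichlet;
S = 20,000 by default). All solutions share one weight sample (common
random numbers), so Monte-Carlo noise cancels between solutions and a
dominated solution can never outrank its dominator. Ranking ascends
(lower expected energy first); ties break by earlier discovery generation,
then archive position. The top five are written as Model_1..5.pdb. An
optional per-objective min-max rescale over the archive is available for
raw energies of very different scales, off by default. The ranking as
defined is a plain expected utility; knee solutions surface because
balanced objective vectors achieve low utility for most weight draws.

A consequence worth knowing: the knee of a front is not necessarily its
most native-like point. With the built-in surrogates the near-native
conformations occupy an extreme of the front (minimal torsion restraint,
maximal radius of gyration among low-clash structures), so the
expected-utility Model 1 is a balanced compromise that scores below the
best archive member on GDT-TS. Selecting the best model from a Pareto
front blindly — without a reference — is an open problem; the ranking
here is the quick utility-based heuristic, and the full archive is always
written alongside the ranked models.

## Evaluation metrics

RMSD uses the closed-form Kabsch superposition (SVD with reflection
guard). GDT-TS is approximated as the mean over cutoffs {1, 2, 4, 8} A of
the best fraction of CA atoms within the cutoff after heuristic
superposition search: seeds from the full chain plus length-4 and
length-8 contiguous windows (window starts strided by 3), each refined up
to 3 times on the atoms currently inside the cutoff, maximum taken. This
is a close lower bound, not the official exhaustive search; residue
pairing is positional (refinement setting, same sequence).

## Synthetic refinement cases

`make_native` builds deterministic natives from canonical torsions (helix
(-57, -47); extended (180, 180); mixed 8-residue blocks) with 2-degree
seeded jitter; `make_refinement_case` perturbs the native's phi/psi by
Gaussian noise of a chosen sigma to produce the starting model, writes
both PDBs and a JSON manifest of the starting RMSD/GDT-TS. The generator
emulates the geometry of a refinement target — a correct fold at a
controlled torsion deviation — but not real-data features: no side chains,
no experimental noise or missing atoms, no heterogeneous per-region model
quality, and a native that coincides with a surrogate-energy basin. Tests
passing on these fixtures demonstrate the optimizer and pipeline
machinery, not force-field quality on real proteins.

## Numerical choices

* Angles in degrees on (-180, 180]; wrapping passes in-range values
  through bit-exactly.
* Dihedrals via the atan2 formulation; collinear quadruples raise a
  degenerate-geometry error rather than returning an arbitrary value.
* Weight-lattice rows in lexicographic composition order; subproblem
  indices are reproducible across runs.
* One `numpy` Generator seeded from `rng_seed`, consumed in a fixed
  documented order (initial perturbations, initial velocities, then
  per-generation per-particle draws in index order); runs are bit-for-bit
  reproducible.
* Duplicate objective vectors: the archive keeps the first and rejects
  later copies.
* PBI with a zero-norm weight vector is rejected; theta must be >= 0.

## Known limitations

* Real force-field backends are specified as an adapter contract only;
  all quantitative results use the surrogate energies.
* The surrogate triple cannot sense global straightness: a gentle uniform
  bend is nearly free in the torsion restraint and actively rewarded by
  compactness, which is why the refinement profile restricts the search
  to the input's neighborhood instead of trusting the energies globally.
* The GDT-TS search is heuristic; scores can slightly undershoot the
  official algorithm.
* Single chain, backbone-only; no side chains, no cis-proline handling,
  no multi-chain complexes.
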