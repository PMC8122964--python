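# torsionswarm

Decomposition-based multi-objective particle swarm refinement of protein
backbone conformations.

## The problem

Predicted protein structures usually carry regions that deviate from the
native fold, and refinement — moving a predicted model closer to the
native — remains hard because no single energy function ranks near-native
conformations reliably for every protein. `torsionswarm` treats
refinement as a **multi-objective** minimization over backbone torsion
angles: a conformation C = (phi_1, psi_1, omega_1, ..., phi_L, psi_L) is
scored by an energy vector F(C) = (f_1(C), ..., f_M(C)) and the goal is
the Pareto set of trade-off conformations,

    minimize F(C)  subject to  C in Omega.

The multi-objective problem is decomposed into N scalar subproblems, one
per weight vector lambda_i of a simplex lattice with H divisions
(N = C(H+M-1, M-1); H = 10, M = 3 gives N = 66). Subproblem i minimizes
the penalty-based boundary intersection (PBI) scalarization

    g(C | lambda_i, z*) = d1 + theta * d2,

where d1 is the distance travelled from the ideal point z* along the ray
through lambda_i, d2 the perpendicular deviation from that ray, and theta
rises linearly from 5 to 20 over the run. Each subproblem is worked by
one particle of a swarm (velocity update with c1 = c2 = 2, inertia
1.3 -> 0.7, per-angle clamping); particles share information inside
neighborhoods of the T = 8 closest weight vectors, every evaluated
conformation updates z* and is offered to a Pareto archive, and at the
end the archived front is ranked by expected utility
E[w . F(C)] under S = 20,000 uniform-simplex weight samples; the top-k
models are written out.

Real force fields are attached through a thin adapter (write PDB, call
scorer, read one number). Three built-in surrogate energies — steric
clash, compactness (squared radius of gyration), and a harmonic torsion
restraint toward a basin — make the whole pipeline runnable and testable
without external software, and two benchmark landscapes with closed-form
Pareto fronts (`dtlz2`, `convex-plane`) validate the optimizer itself.
See `docs/methods.md` for the full model description and design
rationale.

## Who it is for

Researchers and students working on conformational sampling and
multi-objective optimization in structural bioinformatics who need a
transparent, fully inspectable refinement engine — for methods
experiments, teaching, or as a scaffold to plug real scoring functions
into.

## Worked example

Create a synthetic refinement case — a 30-residue helical native and a
starting model perturbed by 10-degree torsion noise — then refine it:

```bash
torsionswarm make-fixture --length 30 --motif helix \
    --deviation-sigma 10 --seed 0 --outdir case
torsionswarm refine --input case/initial.pdb --native case/native.pdb \
    --iterations 1000 --seed 0 --outdir out
torsionswarm evaluate --model out/Model_1.pdb --reference case/native.pdb
```

The fixture step prints the starting quality:

```
native:  case/native.pdb
initial: case/initial.pdb
initial RMSD 1.825 A, GDT-TS 81.67
```

meaning the perturbed model sits 1.8 A (CA RMSD) from the native with a
global distance test score of 81.67/100. The refine step logs
`66 particles / weight vectors, T=8, 1000 generations` and writes
`Model_1.pdb` ... `Model_5.pdb`, `archive.tsv` (the final Pareto front),
`ranking.tsv` (expected utilities and, when `--native` is given, RMSD and
GDT-TS per model) and `run_log.tsv` (per-generation ideal point, archive
size and mean scalarized value). On this case the best archived
conformation reaches GDT-TS 98.33 against the native — +16.7 over the
starting model — because the swarm's torsion-restraint subproblems polish
the perturbed angles back toward the helical basin.

Note what the two outputs mean: the archive holds the whole trade-off
front, while `Model_1..k` are its expected-utility knees — balanced
compromises between the three energies. With the built-in surrogates the
knee is a partly compacted structure rather than the near-native extreme
of the front, so `Model_1` scores well on all three energies but *below*
the best archive member on GDT-TS; blind selection of the best model from
a Pareto front is exactly the hard, open part of refinement, and the
surrogates make the gap visible. `--rescale-utility` ranks on min-max
rescaled energies instead of raw ones when the scales are incommensurate.

The same machinery is available as a library:

```python
import torsionswarm as ts

case = ts.make_refinement_case(L=30, deviation_sigma=10.0, seed=0,
                               outdir="case")
config = ts.PSOConfig.refinement_profile(deviation_sigma=10.0, rng_seed=0)
archive, log = ts.run(case.initial_chain, config, ts.surrogate_energies())
top5 = ts.rank_select(archive, ts.UtilityConfig(top_k=5))
```

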