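"""Decomposition-guided multi-objective particle swarm optimizer.

One particle per subproblem: particle i minimizes the PBI scalarization
g(F | lambda_i, z*) of the shared objective vector F. Velocities follow the
canonical PSO update

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    x <- x + v

with the inertia w decaying linearly over the run and gbest taken from the
best position ever seen by the particles of the neighborhood B(i) (judged
by each neighbor's own scalarization). Every evaluated solution updates the
ideal point z* and is offered to the Pareto archive.

The optimizer moves flat numpy vectors through a :class:`SearchSpace`;
:class:`TorsionSpace` supplies circular arithmetic over backbone torsions
and :class:`BoxSpace` a clipped box for benchmark landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import conformation as conf
from .archive import ArchiveEntry, ParetoArchive
from .decomposition import (
    build_neighborhoods,
    pbi_aggregate,
    penalty_schedule,
    simplex_lattice,
    update_ideal,
)
from .errors import InvalidArgumentError, ObjectiveEvaluationError
from .objectives import evaluate_all

__all__ = [
    "PSOConfig",
    "Particle",
    "SwarmState",
    "SearchSpace",
    "TorsionSpace",
    "BoxSpace",
    "init_swarm",
    "inertia",
    "update_velocity",
    "update_position",
    "step",
    "run",
    "write_run_log",
]


@dataclass(frozen=True)
class PSOConfig:
    """Hyperparameters of the optimizer.

    ``n_divisions`` (H) sets the weight lattice, hence the particle count
    N = C(H+M-1, M-1); defaults reproduce the standard configuration
    H=10 (N=66 for M=3), T=8, c1=c2=2, inertia 1.3 -> 0.7, penalty
    theta 5 -> 20, 3000 iterations.
    """

    n_divisions: int = 10
    max_iter: int = 3000
    neighborhood_size: int = 8
    inertia_start: float = 1.3
    inertia_end: float = 0.7
    c1: float = 2.0
    c2: float = 2.0
    perturb_sigma: float = 10.0
    velocity_clamp: float = 60.0
    velocity_clamp_end: float | None = None
    theta_min: float = 5.0
    theta_max: float = 20.0
    rng_seed: int = 0
    per_component_r: bool = False
    archive_capacity: int | None = None
    normalize_objectives: bool = False

    def clamp_at(self, t: int) -> float:
        """Velocity clamp at generation t.

        Constant by default; when ``velocity_clamp_end`` is set the clamp
        decays linearly over the run (annealed velocity clamping), so late
        generations sample at progressively finer resolution. With c1=c2=2
        the swarm oscillation does not contract on its own (see
        :meth:`refinement_profile`), making the clamp the effective step
        size — annealing it is what turns the sampler into a refiner.
        """
        if self.velocity_clamp_end is None or self.max_iter == 0:
            return self.velocity_clamp
        frac = min(t, self.max_iter) / self.max_iter
        return (self.velocity_clamp
                + (self.velocity_clamp_end - self.velocity_clamp) * frac)

    @classmethod
    def refinement_profile(cls, deviation_sigma: float = 10.0,
                           max_iter: int = 1000, rng_seed: int = 0,
                           **overrides) -> "PSOConfig":
        """Desk-scale profile for surrogate-energy refinement.

        Refinement is a local search: the input model already has the right
        fold, so the swarm samples its neighborhood rather than re-folding.
        The initial population spreads at the expected torsion deviation of
        the input from its target (bracketing the input), while the velocity
        clamp is sized to ~1/3 of that deviation and anneals to 1 degree:
        with c1 = c2 = 2 the swarm oscillation does not contract on its own
        for any inertia below ~0.78, so the clamp is the effective sampling
        step, and descending a basin requires steps smaller than the
        distance still to travel. Per-angle stochastic coefficients suit
        the separable torsion-restraint landscape; min-max objective
        normalization keeps the decomposition spread when the energies have
        incommensurate raw scales; the archive is capped (crowding-pruned)
        to keep the run-end model set at a tractable size.
        """
        defaults = dict(
            perturb_sigma=deviation_sigma,
            velocity_clamp=max(1.0, deviation_sigma / 3.0),
            velocity_clamp_end=1.0,
            per_component_r=True,
            normalize_objectives=True,
            archive_capacity=500,
            max_iter=max_iter,
            rng_seed=rng_seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def __post_init__(self):
        if self.max_iter < 0:
            raise InvalidArgumentError("max_iter must be >= 0")
        if self.c1 < 0 or self.c2 < 0:
            raise InvalidArgumentError("c1, c2 must be >= 0")
        if self.neighborhood_size < 1:
            raise InvalidArgumentError("neighborhood_size must be >= 1")
        if self.perturb_sigma < 0:
            raise InvalidArgumentError("perturb_sigma must be >= 0")
        if self.velocity_clamp <= 0:
            raise InvalidArgumentError("velocity_clamp must be > 0")


class SearchSpace:
    """Topology of the decision space the swarm moves in."""

    dim: int

    def decode(self, position: np.ndarray):
        """Map a flat position vector to the object energy models evaluate."""
        raise NotImplementedError

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """a - b respecting the space's topology."""
        raise NotImplementedError

    def move(self, position: np.ndarray, velocity: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def adjust_velocity_at_boundary(self, position: np.ndarray,
                                    velocity: np.ndarray) -> np.ndarray:
        """Post-move velocity correction (identity unless the space has
        walls)."""
        return velocity

    def perturb(self, position: np.ndarray, sigma: float,
                rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


class TorsionSpace(SearchSpace):
    """Backbone torsion space: angles in degrees on the circle.

    Positions are the defined phi/psi angles of a template chain (omega is
    frozen near trans unless ``include_omega``); displacements use the
    shortest signed angular difference and moves wrap into (-180, 180].
    """

    def __init__(self, template: conf.TorsionChain, include_omega: bool = False):
        self.template = template
        self.include_omega = include_omega
        self.dim = template.to_vector(include_omega).shape[0]

    def encode(self, chain: conf.TorsionChain) -> np.ndarray:
        return chain.to_vector(self.include_omega)

    def decode(self, position: np.ndarray) -> conf.TorsionChain:
        return self.template.with_vector(position, self.include_omega)

    def displacement(self, a, b):
        return conf.angular_difference(a, b)

    def move(self, position, velocity):
        return conf.wrap_angle(position + velocity)

    def perturb(self, position, sigma, rng):
        return conf.wrap_angle(position + rng.normal(0.0, sigma, self.dim))


class BoxSpace(SearchSpace):
    """Euclidean box [lower, upper]^dim with clipping at the walls."""

    def __init__(self, dim: int, lower: float = 0.0, upper: float = 1.0):
        if upper <= lower:
            raise InvalidArgumentError("upper must exceed lower")
        self.dim = dim
        self.lower = lower
        self.upper = upper

    def decode(self, position):
        return position

    def displacement(self, a, b):
        return np.asarray(a, dtype=float) - np.asarray(b, dtype=float)

    def move(self, position, velocity):
        return np.clip(position + velocity, self.lower, self.upper)

    def adjust_velocity_at_boundary(self, position, velocity):
        # absorbing walls: a particle clipped at a wall loses the velocity
        # component that points out of the box
        out_low = (position <= self.lower) & (velocity < 0)
        out_high = (position >= self.upper) & (velocity > 0)
        return np.where(out_low | out_high, 0.0, velocity)

    def perturb(self, position, sigma, rng):
        return np.clip(position + rng.normal(0.0, sigma, self.dim),
                       self.lower, self.upper)


@dataclass
class Particle:
    """One particle: position/velocity vectors plus its personal best."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_objectives: np.ndarray
    subproblem_index: int


@dataclass
class SwarmState:
    """Full optimizer state after generation ``t``."""

    particles: list[Particle]
    weights: np.ndarray
    neighborhoods: np.ndarray
    gbest_positions: np.ndarray
    gbest_objectives: np.ndarray
    ideal: np.ndarray
    archive: ParetoArchive
    t: int
    rng: np.random.Generator
    space: SearchSpace
    log: list[dict] = field(default_factory=list)


def inertia(t: int, config: PSOConfig) -> float:
    """Linearly decaying inertia weight (affine from start to end)."""
    if config.max_iter == 0:
        return config.inertia_start
    if not (0 <= t <= config.max_iter):
        raise InvalidArgumentError(f"t={t} outside [0, {config.max_iter}]")
    frac = t / config.max_iter
    return config.inertia_start + (config.inertia_end - config.inertia_start) * frac


def update_velocity(particle: Particle, gbest_position: np.ndarray, w: float,
                    c1: float, c2: float, r1, r2, space: SearchSpace,
                    velocity_clamp: float) -> np.ndarray:
    """Canonical velocity update with topology-aware differences and clamp."""
    cognitive = space.displacement(particle.pbest_position, particle.position)
    social = space.displacement(gbest_position, particle.position)
    v = w * particle.velocity + c1 * r1 * cognitive + c2 * r2 * social
    return np.clip(v, -velocity_clamp, velocity_clamp)


def update_position(particle: Particle, velocity: np.ndarray,
                    space: SearchSpace) -> np.ndarray:
    """Move the particle: position + velocity, wrapped/clipped by the space."""
    return space.move(particle.position, velocity)


def _evaluate(models, space: SearchSpace, position: np.ndarray,
              particle_index: int | None = None) -> np.ndarray:
    try:
        return evaluate_all(models, space.decode(position)).values
    except ObjectiveEvaluationError as exc:
        raise ObjectiveEvaluationError(exc.model_name, exc.value,
                                       particle_index) from exc


def init_swarm(initial_model, config: PSOConfig, models,
               weights: np.ndarray | None = None,
               space: SearchSpace | None = None) -> SwarmState:
    """Build the initial swarm around one starting model.

    Particle 0 is the unperturbed start; the remaining N-1 particles are
    Gaussian torsion perturbations of it (std ``perturb_sigma``). Initial
    velocities are uniform in +/- velocity_clamp; pbest and gbest start at
    the particles' own positions; the ideal point is the component-wise
    minimum of the initial objective vectors, and every non-dominated
    initial particle enters the archive.
    """
    if space is None:
        if not isinstance(initial_model, conf.TorsionChain):
            raise InvalidArgumentError(
                "provide a TorsionChain or an explicit SearchSpace"
            )
        space = TorsionSpace(initial_model)
    M = len(models)
    if weights is None:
        weights = simplex_lattice(config.n_divisions, M)
    weights = np.asarray(weights, dtype=float)
    N = weights.shape[0]
    if N < 1:
        raise InvalidArgumentError("need at least one weight vector")
    neighborhoods = build_neighborhoods(weights,
                                        min(config.neighborhood_size, N))
    rng = np.random.default_rng(config.rng_seed)
    x0 = (space.encode(initial_model)
          if isinstance(space, TorsionSpace) else np.asarray(initial_model,
                                                             dtype=float))
    positions = [x0.copy()]
    for _ in range(N - 1):
        positions.append(space.perturb(x0, config.perturb_sigma, rng))
    velocities = rng.uniform(-config.velocity_clamp, config.velocity_clamp,
                             (N, space.dim))
    objectives = np.stack([
        _evaluate(models, space, positions[i], i) for i in range(N)
    ])
    ideal = objectives.min(axis=0)
    particles = [
        Particle(position=positions[i], velocity=velocities[i],
                 pbest_position=positions[i].copy(),
                 pbest_objectives=objectives[i].copy(), subproblem_index=i)
        for i in range(N)
    ]
    archive = ParetoArchive(capacity=config.archive_capacity)
    for i in range(N):
        archive.offer(ArchiveEntry(conformation=space.decode(positions[i]),
                                   objectives=objectives[i],
                                   generation_found=0))
    state = SwarmState(
        particles=particles, weights=weights, neighborhoods=neighborhoods,
        gbest_positions=np.stack(positions).copy(),
        gbest_objectives=objectives.copy(), ideal=ideal,
        archive=archive, t=0, rng=rng, space=space,
    )
    _log_generation(state, config, models)
    return state


def _g_rows(F_rows: np.ndarray, unit_lams: np.ndarray, z: np.ndarray,
            theta: float, span: np.ndarray | None = None) -> np.ndarray:
    """PBI g-values for paired rows of objectives and *unit* weight vectors.

    Vectorized equivalent of :func:`torsionswarm.decomposition.pbi_aggregate`
    on the optimizer's hot path (equality is covered by a unit test).
    ``span`` carries the (nadir - ideal) scales when min-max normalization
    is enabled.
    """
    diff = F_rows - z
    if span is not None:
        diff = diff / span
    d1 = np.abs(np.einsum("ij,ij->i", diff, unit_lams))
    resid = diff - d1[:, None] * unit_lams
    d2 = np.sqrt(np.einsum("ij,ij->i", resid, resid))
    return d1 + theta * d2


def _objective_span(state: "SwarmState") -> np.ndarray | None:
    """Current (nadir - ideal) scales for min-max normalization.

    The nadir is estimated from the swarm's pbest set (the current
    population of per-subproblem incumbents). The archive front would also
    work but retains extreme corner solutions forever, which inflates the
    span of an objective and squashes it out of every scalarization; the
    population estimate tightens as the swarm converges.
    """
    F = np.stack([p.pbest_objectives for p in state.particles])
    return np.maximum(F.max(axis=0) - state.ideal, 1e-12)


def _log_generation(state: SwarmState, config: PSOConfig, models) -> None:
    theta = penalty_schedule(min(state.t, max(config.max_iter, 1)),
                             max(config.max_iter, 1),
                             config.theta_min, config.theta_max)
    span = _objective_span(state) if config.normalize_objectives else None
    unit = state.weights / np.linalg.norm(state.weights, axis=1, keepdims=True)
    gs = _g_rows(np.stack([p.pbest_objectives for p in state.particles]),
                 unit, state.ideal, theta, span)
    state.log.append({
        "generation": state.t,
        **{f"z{k + 1}": float(v) for k, v in enumerate(state.ideal)},
        "archive_size": len(state.archive),
        "mean_g": float(np.mean(gs)),
    })


def step(state: SwarmState, config: PSOConfig, models) -> SwarmState:
    """Advance the swarm by one generation (in place; returns the state).

    Particles are processed in ascending index order; gbest updates take
    effect immediately, so later particles in the same generation see them.
    pbest and gbest replacements require strictly smaller scalarized values,
    evaluated at the current ideal point and the current penalty theta(t).
    """
    theta = penalty_schedule(min(state.t, config.max_iter), config.max_iter,
                             config.theta_min, config.theta_max)
    w = inertia(min(state.t, config.max_iter), config)
    space = state.space
    rng = state.rng
    unit_weights = state.weights / np.linalg.norm(state.weights, axis=1,
                                                  keepdims=True)
    span = _objective_span(state) if config.normalize_objectives else None
    clamp = config.clamp_at(state.t)
    for i, particle in enumerate(state.particles):
        if config.per_component_r:
            r1 = rng.random(space.dim)
            r2 = rng.random(space.dim)
        else:
            r1 = rng.random()
            r2 = rng.random()
        v = update_velocity(particle, state.gbest_positions[i], w, config.c1,
                            config.c2, r1, r2, space, clamp)
        particle.position = update_position(particle, v, space)
        particle.velocity = space.adjust_velocity_at_boundary(
            particle.position, v)
        F = _evaluate(models, space, particle.position, i)
        state.ideal = update_ideal(state.ideal, F)
        u_i = unit_weights[i : i + 1]
        g_pair = _g_rows(np.stack([F, particle.pbest_objectives]),
                         np.vstack([u_i, u_i]), state.ideal, theta, span)
        if g_pair[0] < g_pair[1]:
            particle.pbest_position = particle.position.copy()
            particle.pbest_objectives = F.copy()
        B = state.neighborhoods[i]
        uB = unit_weights[B]
        g_new = _g_rows(np.broadcast_to(F, (B.shape[0], F.shape[0])), uB,
                        state.ideal, theta, span)
        g_old = _g_rows(state.gbest_objectives[B], uB, state.ideal, theta,
                        span)
        for j in B[g_new < g_old]:
            state.gbest_positions[j] = particle.position.copy()
            state.gbest_objectives[j] = F.copy()
        state.archive.offer(ArchiveEntry(
            conformation=space.decode(particle.position), objectives=F,
            generation_found=state.t + 1,
        ))
    state.t += 1
    _log_generation(state, config, models)
    return state


def run(initial_model, config: PSOConfig, models,
        weights: np.ndarray | None = None,
        space: SearchSpace | None = None) -> tuple[ParetoArchive, list[dict]]:
    """Full optimization: init_swarm plus ``max_iter`` generations.

    Returns the final Pareto archive and the per-generation log (ideal
    point, archive size, mean scalarized value).
    """
    state = init_swarm(initial_model, config, models, weights, space)
    for _ in range(config.max_iter):
        step(state, config, models)
    return state.archive, state.log


def write_run_log(log: list[dict], path) -> None:
    """Serialize the per-generation log as TSV."""
    if not log:
        return
    cols = list(log[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in log:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
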