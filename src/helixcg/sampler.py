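"""Metropolis-Hastings sampling of coarse-grain models.

Each step redraws the placement parameters of one uniformly chosen
element (the fragment-replacement proposal is symmetric, so the
acceptance probability is min(1, exp(-dE)) with kT = 1 -- energies are
already log density ratios).  The secondary structure never changes.
Every tenth step the current structure's measure values are appended to
the reference distributions, adapting the reference-ratio energies
toward the sampled ensemble.  Feasible (clash- and closure-free)
structures are recorded; the Jensen-Shannon divergence between sampled
and target measure values serves as a convergence diagnostic: when it
levels off, the target distribution has been adequately sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyFunction, GaussianKDE, scott_bandwidth
from .model_builder import (
    CoarseGrainModel,
    build_model,
    resample_element,
    _sampleable_elements,
)
from .proposal_stats import StatsTable
from .ss_graph import SkeletonGraph

__all__ = [
    "SamplerState",
    "TrajectoryRecord",
    "SimulationResult",
    "mh_step",
    "run_simulation",
    "js_divergence",
    "js_series",
]


@dataclass
class SamplerState:
    model: CoarseGrainModel
    energy: float
    iteration: int = 0
    accepted: int = 0
    best_model: CoarseGrainModel | None = None
    best_energy: float = np.inf
    rng_seed: int | None = None
    measures: dict[str, float] = field(default_factory=dict)


@dataclass
class TrajectoryRecord:
    iteration: int
    energy: float
    accepted: bool
    measures: dict[str, float]
    rmsd: float | None = None


@dataclass
class SimulationResult:
    trajectory: list[TrajectoryRecord]
    best_model: CoarseGrainModel
    best_energy: float
    state: SamplerState

    def measure_series(self, name: str) -> np.ndarray:
        return np.array(
            [r.measures[name] for r in self.trajectory if name in r.measures]
        )

    @property
    def acceptance_rate(self) -> float:
        return self.state.accepted / max(self.state.iteration, 1)


def mh_step(
    state: SamplerState,
    table: StatsTable,
    energy_fn: EnergyFunction,
    rng: np.random.Generator,
) -> SamplerState:
    """One Metropolis-Hastings step; rejected proposals restore the
    previous model exactly (the state keeps the old object)."""
    names = _sampleable_elements(state.model.graph)
    name = names[rng.integers(len(names))]
    state.iteration += 1
    proposal = resample_element(
        state.model, name, table, rng, iteration=state.iteration
    )
    e_new, meas_new = energy_fn.evaluate_with_measures(proposal)
    de = e_new - state.energy
    if de <= 0 or rng.random() < np.exp(-de):
        state.model = proposal
        state.energy = e_new
        state.measures = meas_new
        state.accepted += 1
        if e_new < state.best_energy:
            state.best_energy = e_new
            state.best_model = proposal
    return state


def run_simulation(
    g: SkeletonGraph,
    table: StatsTable,
    energy_fn: EnergyFunction | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    reference_model: CoarseGrainModel | None = None,
    update_every: int = 10,
    build_retries: int = 50,
    track_measures: dict | None = None,
) -> SimulationResult:
    """Run the MH chain and record feasible samples.

    Reference distributions absorb the current structure's measure
    values every ``update_every`` steps (one value per term).  When a
    reference model with the same skeleton graph is given, each record
    carries the coarse RMSD to it.  ``track_measures`` maps extra
    measure names to callables recorded per sample without entering the
    energy (useful for constant-energy baselines).  Deterministic given
    ``seed``.
    """
    energy_fn = energy_fn if energy_fn is not None else EnergyFunction.zero()
    rng = np.random.default_rng(seed)

    model = None
    for _ in range(build_retries):
        cand = build_model(g, table, rng)
        if (
            not energy_fn.use_constraints
            or energy_fn.constraint_energy(cand) == 0.0
        ):
            model = cand
            break
    if model is None:
        raise RuntimeError(
            f"no feasible initial model within {build_retries} builds"
        )

    e0, meas0 = energy_fn.evaluate_with_measures(model)
    state = SamplerState(
        model=model,
        energy=e0,
        best_model=model,
        best_energy=e0,
        rng_seed=seed,
        measures=meas0,
    )

    def rmsd_to_ref(m):
        if reference_model is None:
            return None
        from .io_eval import cg_rmsd

        return cg_rmsd(m, reference_model)

    trajectory: list[TrajectoryRecord] = []
    for it in range(1, n_iter + 1):
        accepted_before = state.accepted
        state = mh_step(state, table, energy_fn, rng)
        accepted = state.accepted > accepted_before
        feasible = (
            energy_fn.constraint_energy(state.model) == 0.0
            if energy_fn.use_constraints
            else True
        )
        if feasible:
            measures = dict(state.measures)
            if track_measures:
                for mname, fn in track_measures.items():
                    measures.setdefault(mname, float(fn(state.model)))
            trajectory.append(
                TrajectoryRecord(
                    iteration=it,
                    energy=state.energy,
                    accepted=accepted,
                    measures=measures,
                    rmsd=rmsd_to_ref(state.model),
                )
            )
        if energy_fn.terms and it % update_every == 0 and feasible:
            energy_fn.update_references(state.measures)
            # the energy landscape moved; re-evaluate the current model
            state.energy, state.measures = energy_fn.evaluate_with_measures(
                state.model
            )
    return SimulationResult(
        trajectory=trajectory,
        best_model=state.best_model,
        best_energy=state.best_energy,
        state=state,
    )


def js_divergence(sampled, target, grid_size: int = 512) -> float:
    """Jensen-Shannon divergence between KDE-smoothed sample densities.

    Both sample sets are smoothed with Scott's-rule Gaussian KDEs and
    compared on a shared grid spanning both supports; the result lies in
    [0, log 2].
    """
    s = np.asarray(sampled, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.size == 0 or t.size == 0:
        raise ValueError("both sample sets must be non-empty")
    hs = scott_bandwidth(s) if s.size > 1 else 1.0
    ht = scott_bandwidth(t) if t.size > 1 else 1.0
    lo = min(s.min() - 4 * hs, t.min() - 4 * ht)
    hi = max(s.max() + 4 * hs, t.max() + 4 * ht)
    grid = np.linspace(lo, hi, grid_size)
    p = GaussianKDE(s, hs).evaluate(grid)
    q = GaussianKDE(t, ht).evaluate(grid)
    # renormalise on the grid to compensate truncation
    p = p / np.trapezoid(p, grid)
    q = q / np.trapezoid(q, grid)
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        ip = np.where(p > 0, p * np.log(p / m), 0.0)
        iq = np.where(q > 0, q * np.log(q / m), 0.0)
    js = 0.5 * np.trapezoid(ip, grid) + 0.5 * np.trapezoid(iq, grid)
    return float(np.clip(js, 0.0, np.log(2.0)))


def js_series(
    sampled, target, n_checkpoints: int = 20
) -> list[tuple[int, float]]:
    """Running JS divergence of growing sample prefixes against a target."""
    s = np.asarray(sampled, dtype=float)
    out = []
    for k in np.linspace(
        max(5, len(s) // n_checkpoints), len(s), n_checkpoints
    ).astype(int):
        out.append((int(k), js_divergence(s[:k], target)))
    return out
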