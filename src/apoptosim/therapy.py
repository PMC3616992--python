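"""In-silico therapy design over the calibrated apoptosis model.

A therapy is staurosporine (the cytotoxic backbone) plus up to four
pre-incubation agents: Src inhibition, Bcl2-pool depletion, Bax
downregulation, tBid upregulation.  Both cell populations receive the same
exposure; efficacy is the apoptotic percentage in Src-transformed (cancer)
cells, toxicity the apoptotic percentage in parental (healthy) cells.  A
design is feasible when toxicity stays below 1%.  The search minimizes

    surviving % of cancer cells + 1000 * [toxicity > 1%]

with the same evolution-strategy engine as the calibration, seeded by a
coarse grid pre-scan to escape the flat penalty plateau.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .network import ApoptosisParams, CellLineSpec, PARENTAL_CELL, SRC_CELL
from .treatments import TreatmentSpec, simulate_treated
from .optimize import evolve

__all__ = [
    "TherapyDesign",
    "TherapyProblem",
    "KNOBS",
    "evaluate_design",
    "therapy_cost",
    "optimize_full",
    "rank_combinations",
    "protective_bax_delta",
    "bax_alone_design",
]

#: Tunable agents and their physical ranges (caps from the measured totals:
#: bax_delta cannot exceed the parental total, tbid_up the parental Bid total).
KNOBS: dict[str, tuple[float, float]] = {
    "src_inhibition": (0.0, 1.0),
    "bcl2_depletion": (0.0, 600.0),
    "bax_delta": (0.0, 47.9),
    "tbid_up": (0.0, 52.0),
}


@dataclass
class TherapyDesign:
    """One drug combination and its simulated outcome."""

    knobs: dict  # knob name -> value
    efficacy: float = math.nan   # apoptotic % in Src-transformed cells
    toxicity: float = math.nan   # apoptotic % in parental cells
    toxicity_cap: float = 1.0

    @property
    def feasible(self) -> bool:
        return self.toxicity <= self.toxicity_cap

    def treatment(self) -> TreatmentSpec:
        return TreatmentSpec(staurosporine=True,
                             **{k: float(v) for k, v in self.knobs.items()})


@dataclass
class TherapyProblem:
    params: ApoptosisParams | None = None
    healthy: CellLineSpec = PARENTAL_CELL
    cancer: CellLineSpec = SRC_CELL
    toxicity_cap: float = 1.0
    penalty: float = 1000.0
    t_end: float = 480.0
    sim_kw: dict = field(default_factory=lambda: {"rtol": 1e-6, "atol": 1e-8,
                                                  "grid_min": 2.0})


def evaluate_design(knobs: dict, problem: TherapyProblem) -> TherapyDesign:
    """Simulate one combination in both populations (knobs clipped to range)."""
    clipped = {k: float(np.clip(v, *KNOBS[k])) for k, v in knobs.items()}
    design = TherapyDesign(knobs=clipped, toxicity_cap=problem.toxicity_cap)
    rx = design.treatment()
    cancer = simulate_treated(problem.cancer, rx, net=problem.params,
                              t_end=problem.t_end, **problem.sim_kw)
    healthy = simulate_treated(problem.healthy, rx, net=problem.params,
                               t_end=problem.t_end, **problem.sim_kw)
    design.efficacy = cancer.apoptotic_pct
    design.toxicity = healthy.apoptotic_pct
    return design


def therapy_cost(design: TherapyDesign, problem: TherapyProblem | None = None) -> float:
    """Surviving cancer % plus a 1000 penalty when toxicity exceeds the cap."""
    cap = problem.toxicity_cap if problem is not None else design.toxicity_cap
    pen = problem.penalty if problem is not None else 1000.0
    if math.isnan(design.efficacy) or math.isnan(design.toxicity):
        return 1e9
    return (100.0 - design.efficacy) + (pen if design.toxicity > cap else 0.0)


def _grid_prescan(names, problem, points_per_knob=10):
    """Coarse scan used to seed the evolution strategy.

    Full factorial for <= 2 knobs; for more knobs, per-axis scans on top of
    a Bax-protected base point (bax_delta at its cap) plus a joint diagonal,
    which is where the feasible basin lives.
    """
    axes = {n: np.linspace(*KNOBS[n], points_per_knob) for n in names}
    if len(names) <= 2:
        combos = list(itertools.product(*(axes[n] for n in names)))
    else:
        combos = [tuple(axes[n][i] for n in names) for i in range(points_per_knob)]
        for j, n in enumerate(names):
            for v in axes[n]:
                base = [KNOBS[m][1] if m == "bax_delta" else 0.0 for m in names]
                base[j] = v
                combos.append(tuple(base))
    scored = []
    for combo in combos:
        d = evaluate_design(dict(zip(names, combo)), problem)
        scored.append((therapy_cost(d, problem), combo))
    scored.sort(key=lambda t: t[0])
    return [np.array(c) for _, c in scored[:4]]


def _optimize_subset(names, problem, seed, maxiter=25, popsize=8):
    if not names:
        return evaluate_design({}, problem)
    bounds = [KNOBS[n] for n in names]
    seeds = _grid_prescan(names, problem)

    def objective(x):
        d = evaluate_design(dict(zip(names, x)), problem)
        return therapy_cost(d, problem)

    res = evolve(objective, bounds=bounds, seed=seed, x0=seeds[0],
                 init_points=seeds[1:], maxiter=maxiter, popsize=popsize,
                 polish=True)
    return evaluate_design(dict(zip(names, res.x)), problem)


def optimize_full(problem: TherapyProblem | None = None, seed: int = 0,
                  maxiter: int = 30, popsize: int = 10) -> TherapyDesign:
    """Four-knob search for the maximally selective combination.

    The winning mechanism is threshold protection: Bax downregulation pushes
    the parental Bax total below the apoptotic threshold (toxicity ~ 0
    whatever the other agents do), while the Bax excess of the transformed
    line keeps it killable; the remaining knobs then push efficacy to ~99%.
    """
    problem = problem if problem is not None else TherapyProblem()
    return _optimize_subset(tuple(KNOBS), problem, seed=seed,
                            maxiter=maxiter, popsize=popsize)


def protective_bax_delta(cell: CellLineSpec | None = None,
                         params: ApoptosisParams | None = None,
                         margin: float = 1.0) -> float:
    """Bax-downregulator dose that shelters a cell line from apoptosis.

    The dosing rule of the optimal strategy: remove enough Bax that the
    line's total falls below the apoptotic threshold (plus a small margin),
    so oligomerized Bax can never reach it and the death gate stays shut.
    """
    cell = cell if cell is not None else PARENTAL_CELL
    if params is None:
        from .network import DEFAULT_NETWORK_PARAMS
        params = DEFAULT_NETWORK_PARAMS
    return max(cell.bax_total - params.bax_star + margin, 0.0)


def bax_alone_design(problem: TherapyProblem | None = None) -> TherapyDesign:
    """Bax downregulation as the only agent on top of staurosporine.

    Uses the protective dosing rule (healthy-line Bax below threshold); the
    tolerability constraint is then met by construction, and the efficacy
    that remains in the cancer line is what the design is judged on.
    """
    problem = problem if problem is not None else TherapyProblem()
    delta = protective_bax_delta(problem.healthy, problem.params)
    return evaluate_design({"bax_delta": delta}, problem)


def rank_combinations(max_agents: int = 2, problem: TherapyProblem | None = None,
                      seed: int = 0) -> list[dict]:
    """Optimize every knob subset of size <= max_agents and rank by efficacy.

    Returns one record per subset with the optimized knob values, efficacy,
    toxicity, feasibility and cost, sorted feasible-first then by efficacy
    descending.  The empty subset is the staurosporine-alone baseline.
    """
    if max_agents not in (1, 2):
        raise ValueError("max_agents must be 1 or 2")
    problem = problem if problem is not None else TherapyProblem()
    records = []
    names = tuple(KNOBS)
    subsets = [()]
    subsets += [(n,) for n in names]
    if max_agents == 2:
        subsets += list(itertools.combinations(names, 2))
    for i, subset in enumerate(subsets):
        design = _optimize_subset(subset, problem, seed=seed + i)
        records.append({
            "subset": subset,
            "knobs": design.knobs,
            "efficacy": design.efficacy,
            "toxicity": design.toxicity,
            "feasible": design.feasible,
            "cost": therapy_cost(design, problem),
        })
    records.sort(key=lambda r: (not r["feasible"], -r["efficacy"]))
    return records
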