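"""Evolutionary optimization of conductance gradients and geometry.

A (mu + lambda) evolution strategy with truncation selection, Gaussian
mutation with per-parameter sigma annealing and box-constraint clipping.
Candidates are parameter vectors over per-branch gradient endpoints
(KLT and H conductance densities), diameters and soma radius; the
objective maximizes the resonance-frequency range Delta = max f_R(x) -
min f_R(x) of the tree transfer-impedance profile subject to a hard
mean-sharpness constraint <Q> >= q_min (death penalty: infeasible
candidates never outrank feasible ones).  Runs are bitwise reproducible
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import builders
from .membrane import default_grid
from .tree import Morphology, spatial_profile_tree


class OptimizationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# search space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded parameter vector with named entries."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names/bounds length mismatch")
        if np.any(self.upper <= self.lower):
            raise ValueError("upper bounds must exceed lower bounds")

    @property
    def dim(self):
        return len(self.names)

    def clip(self, x):
        return np.clip(x, self.lower, self.upper)

    def sample(self, rng):
        return rng.uniform(self.lower, self.upper)

    def as_dict(self, x):
        return dict(zip(self.names, x))


def gradient_space(builder: str) -> SearchSpace:
    """Per-branch gradient endpoints + geometry for an abstract builder."""
    n_branch = {"cable": 1, "ballstick": 1, "bipolar": 2, "y": 3}[builder]
    names, lo, hi = [], [], []
    g0, g1 = builders.PARAM_RANGES["gbar_klt"]
    h0, h1 = builders.PARAM_RANGES["g_h"]
    d0, d1 = builders.PARAM_RANGES["diam"]
    for b in range(n_branch):
        for tag, a, z in (("gbar0", g0, g1), ("gbar1", g0, g1),
                          ("gh0", h0, h1), ("gh1", h0, h1),
                          ("diam0", d0, d1), ("diam1", d0, d1)):
            names.append(f"b{b}_{tag}")
            lo.append(a)
            hi.append(z)
    if builder != "cable":
        s0, s1 = builders.PARAM_RANGES["soma_radius"]
        names.append("soma_radius")
        lo.append(s0)
        hi.append(s1)
    return SearchSpace(tuple(names), np.array(lo), np.array(hi))


def candidate_morphology(builder: str, space: SearchSpace, x) -> Morphology:
    """Build the morphology for a candidate vector (diameter taper repaired
    to be non-increasing distally)."""
    d = space.as_dict(space.clip(x))
    n_branch = {"cable": 1, "ballstick": 1, "bipolar": 2, "y": 3}[builder]
    gbar, g_h, diam = [], [], []
    for b in range(n_branch):
        gbar.append((d[f"b{b}_gbar0"], d[f"b{b}_gbar1"]))
        g_h.append((d[f"b{b}_gh0"], d[f"b{b}_gh1"]))
        d1 = min(d[f"b{b}_diam1"], d[f"b{b}_diam0"])
        diam.append((d[f"b{b}_diam0"], d1))
    kw = {}
    if builder != "cable":
        kw["soma_radius"] = d["soma_radius"]
    if builder in ("cable", "ballstick"):
        return builders.build(builder, gbar=gbar[0], g_h=g_h[0], diam=diam[0], **kw)
    return builders.build(builder, gbar=tuple(gbar), g_h=tuple(g_h),
                          diam=tuple(diam), **kw)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Objective:
    """Maximize the f_R range subject to a mean-Q floor."""

    q_min: float = 0.8
    spacing_um: float = 20.0
    seg_len_um: float = 5.0
    grid: np.ndarray = field(default_factory=lambda: default_grid(n=800))

    def __call__(self, morph: Morphology):
        prof = spatial_profile_tree(morph, grid=self.grid,
                                    seg_len_um=self.seg_len_um,
                                    spacing_um=self.spacing_um)
        if not np.all(prof.is_resonant):
            return False, 0.0, {"reason": "non-resonant positions"}
        q = prof.q[np.isfinite(prof.q)]
        mean_q = float(q.mean()) if q.size else 0.0
        delta = float(prof.f_r_hz.max() - prof.f_r_hz.min())
        feasible = mean_q >= self.q_min and q.size == prof.q.size
        return feasible, delta, {"mean_q": mean_q,
                                 "f_min": float(prof.f_r_hz.min()),
                                 "f_max": float(prof.f_r_hz.max())}


def evaluate(builder: str, x, space: SearchSpace | None = None,
             objective: Objective | None = None):
    """(feasible, Delta, info) for one candidate; deterministic."""
    space = space or gradient_space(builder)
    objective = objective or Objective()
    return objective(candidate_morphology(builder, space, x))


# ---------------------------------------------------------------------------
# evolution strategy
# ---------------------------------------------------------------------------

@dataclass
class EvolutionResult:
    best_x: np.ndarray
    best_score: float
    best_info: dict
    history: list
    n_evaluations: int


def evolve(fun, space: SearchSpace, seed: int, pop: int = 24, lam: int = 48,
           generations: int = 60, sigma0: float = 0.25,
           anneal: float = 0.97, initial=None) -> EvolutionResult:
    """(mu + lambda)-ES maximizing ``fun(x) -> (feasible, score, info)``.

    ``sigma0`` scales the per-parameter mutation width as a fraction of
    the box range; sigma anneals geometrically each generation.
    ``initial`` optionally injects candidate vectors into the first
    population (the rest is sampled uniformly in the box).
    """
    if pop < 8:
        raise OptimizationError("population must be >= 8")
    rng = np.random.default_rng(seed)
    width = space.upper - space.lower
    seeds_x = [space.clip(np.asarray(x, float)) for x in (initial or [])][:pop]

    def key(entry):           # feasible first, then score
        feasible, score, _ = entry[1]
        return (1 if feasible else 0, score)

    n_evals = 0

    def init_population():
        nonlocal n_evals
        members = []
        for i in range(pop):
            x = seeds_x[i] if i < len(seeds_x) else space.sample(rng)
            members.append((x, fun(x)))
            n_evals += 1
        return members

    members = init_population()
    if not any(m[1][0] for m in members):
        members = init_population()
        if not any(m[1][0] for m in members):
            raise OptimizationError("no feasible candidate after reinitialization")
    members.sort(key=key, reverse=True)

    sigma = sigma0
    history = []
    for gen in range(generations):
        offspring = []
        successes = 0
        for k in range(lam):
            # rank-biased parent selection: the best members produce most
            # offspring, the tail keeps some diversity; every generation
            # one fine-scale mutant of the incumbent sharpens the endgame
            if k == 0:
                parent, step = members[0], 0.15 * sigma
            else:
                parent = members[int(len(members) * rng.random() ** 4)]
                step = sigma
            child = space.clip(parent[0] + rng.normal(0.0, step * width))
            entry = (child, fun(child))
            successes += key(entry) > key(parent)
            offspring.append(entry)
        n_evals += lam
        members = sorted(members + offspring, key=key, reverse=True)[:pop]
        best = members[0]
        history.append({"generation": gen, "sigma": sigma,
                        "best_score": best[1][1],
                        "best_feasible": best[1][0],
                        "mean_score": float(np.mean([m[1][1] for m in members]))})
        # annealed step size with a 1/5-success correction: shrink fast when
        # the population stops improving, re-expand when most moves help
        sigma *= anneal * (1.4 if successes > 0.2 * lam else 0.75)
    best = members[0]
    if not best[1][0]:
        raise OptimizationError("no feasible candidate found")
    return EvolutionResult(best_x=best[0], best_score=best[1][1],
                           best_info=best[1][2], history=history,
                           n_evaluations=n_evals)
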