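"""Equivalent current dipole reconstruction by downhill-simplex search.

An unconstrained moving single-dipole fit: the nonlinear search runs over
the dipole position only; at each candidate position the moment is the
linear least-squares solution against the measured map.  The position search
is a Nelder--Mead downhill simplex with reflection -1.0, expansion 2.0,
contraction 0.5, at most 200 iterations and an initial simplex size of
10 mm (the scale of a ~3 cm brain).  The cost is 1 minus the explained
variance; candidate positions outside the brain compartment are penalized
with cost 2 (the RDM* maximum) to keep the simplex well defined near
boundaries.  Because the sensor array is mono-directional, the moment
component normal to the coil plane is poorly determined and can be zeroed
after the fit (:func:`project_moment_inplane`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import Dipole, FieldMap, ForwardModel

#: penalty cost for source candidates outside the brain compartment
OUT_OF_BRAIN_COST = 2.0


@dataclass(frozen=True)
class FitConfig:
    """Downhill-simplex parameters (defaults are the study's values)."""

    reflection: float = -1.0
    expansion: float = 2.0
    contraction: float = 0.5
    max_iterations: int = 200
    initial_simplex_size: float = 10.0   # mm
    position_tolerance: float = 0.01     # mm, simplex-diameter stop rule


@dataclass
class ReconResult:
    """A fitted equivalent dipole with goodness of fit."""

    dipole: Dipole
    explained_variance: float
    iterations: int
    model_id: str = ""
    cost_initial: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.explained_variance <= 1.0):
            raise ValueError("explained variance must lie in [0, 1]")


def explained_variance(measured, modeled) -> float:
    """1 - |measured - modeled|^2 / |measured|^2, clipped at 0."""
    m = measured.values if isinstance(measured, FieldMap) else \
        np.asarray(measured, dtype=float)
    s = modeled.values if isinstance(modeled, FieldMap) else \
        np.asarray(modeled, dtype=float)
    if m.shape != s.shape:
        raise ValueError("maps have different channel counts")
    nm = np.linalg.norm(m)
    if nm == 0.0:
        raise ValueError("explained variance is undefined for a zero map")
    return float(max(0.0, 1.0 - np.linalg.norm(m - s) ** 2 / nm ** 2))


def moment_lsq(measured, lead_field: np.ndarray) -> np.ndarray:
    """Least-squares dipole moment at a fixed position.

    ``lead_field`` holds per-unit-moment maps as columns (m x 3 or m x 2);
    raises on a rank-deficient lead field.
    """
    v = measured.values if isinstance(measured, FieldMap) else \
        np.asarray(measured, dtype=float)
    L = np.asarray(lead_field, dtype=float)
    if np.linalg.matrix_rank(L) < L.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient lead field: unit-moment maps are linearly "
            "dependent at this position"
        )
    m, *_ = np.linalg.lstsq(L, v, rcond=None)
    return m


def project_moment_inplane(moment: np.ndarray,
                           coil_plane_normal: np.ndarray) -> np.ndarray:
    """Zero the moment component along the coil-plane normal."""
    n = np.asarray(coil_plane_normal, dtype=float)
    if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-9):
        raise ValueError("coil_plane_normal must be a unit vector")
    m = np.asarray(moment, dtype=float)
    return m - (m @ n) * n


def _fit_cost(model: ForwardModel, measured: np.ndarray,
              position: np.ndarray) -> tuple[float, np.ndarray]:
    """(1 - explained variance, moment) at a candidate position."""
    if not model.in_brain(position):
        return OUT_OF_BRAIN_COST, np.zeros(3)
    L = model.lead_field(position)
    m, *_ = np.linalg.lstsq(L, measured, rcond=None)
    resid = measured - L @ m
    cost = float(np.linalg.norm(resid) ** 2 / np.linalg.norm(measured) ** 2)
    return cost, m


def fit_moving_dipole(measured, model: ForwardModel,
                      initial_position: np.ndarray,
                      cfg: FitConfig = FitConfig()) -> ReconResult:
    """Downhill-simplex position search with linear moment estimation.

    ``initial_position`` is typically the known physical source position.
    Deterministic: ordering ties are broken by insertion order (stable
    sort).  Single run, no restarts; after the iteration cap the best
    vertex is accepted.
    """
    v = measured.values if isinstance(measured, FieldMap) else \
        np.asarray(measured, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("measured map contains non-finite values")
    x0 = np.asarray(initial_position, dtype=float)

    # initial simplex: x0 plus one vertex per axis at the simplex size
    simplex = [x0] + [x0 + cfg.initial_simplex_size * e for e in np.eye(3)]
    costs = [_fit_cost(model, v, x)[0] for x in simplex]
    if all(c >= OUT_OF_BRAIN_COST for c in costs):
        raise ValueError("all initial simplex vertices lie outside the mesh "
                         "or brain compartment")
    cost_initial = costs[0]

    n_iter = 0
    for n_iter in range(1, cfg.max_iterations + 1):
        order = np.argsort(costs, kind="stable")
        simplex = [simplex[i] for i in order]
        costs = [costs[i] for i in order]
        if np.max([np.linalg.norm(s - simplex[0]) for s in simplex[1:]]) \
                < cfg.position_tolerance:
            break
        centroid = np.mean(simplex[:-1], axis=0)
        worst = simplex[-1]
        # reflection: x_r = centroid + reflection * (worst - centroid);
        # the conventional factor is -1.0 (mirror through the centroid)
        x_r = centroid + cfg.reflection * (worst - centroid)
        c_r = _fit_cost(model, v, x_r)[0]
        if c_r < costs[0]:
            x_e = centroid + cfg.expansion * (x_r - centroid)
            c_e = _fit_cost(model, v, x_e)[0]
            if c_e < c_r:
                simplex[-1], costs[-1] = x_e, c_e
            else:
                simplex[-1], costs[-1] = x_r, c_r
        elif c_r < costs[-2]:
            simplex[-1], costs[-1] = x_r, c_r
        else:
            # contraction toward the better of worst / reflected
            if c_r < costs[-1]:
                simplex[-1], costs[-1] = x_r, c_r
            x_c = centroid + cfg.contraction * (simplex[-1] - centroid)
            c_c = _fit_cost(model, v, x_c)[0]
            if c_c < costs[-1]:
                simplex[-1], costs[-1] = x_c, c_c
            else:
                # shrink toward the best vertex
                for i in range(1, len(simplex)):
                    simplex[i] = simplex[0] + 0.5 * (simplex[i] - simplex[0])
                    costs[i] = _fit_cost(model, v, simplex[i])[0]

    best = int(np.argmin(costs))
    x_best = simplex[best]
    cost_best, moment = _fit_cost(model, v, x_best)
    # never worse than the initial guess
    if cost_initial < cost_best:
        x_best = x0
        cost_best, moment = _fit_cost(model, v, x0)
    ev = max(0.0, 1.0 - cost_best)
    return ReconResult(
        dipole=Dipole(tuple(x_best), tuple(moment)),
        explained_variance=min(1.0, ev),
        iterations=n_iter,
        model_id=model.model_id,
        cost_initial=cost_initial,
    )
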