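"""Microkinetic engine: mass-action ODE systems for reaction networks.

A :class:`KineticNetwork` holds n species, m reversible steps with rate
constants, and the n×m signed stoichiometric matrix ν.  The net rate of step
j under mass action is

    r_j = k_f,j · Π_i c_i^{ν⁻_ij}  −  k_r,j · Π_i c_i^{ν⁺_ij}

(ν⁻/ν⁺ the reactant/product orders) and dC/dt = ν · r.  Integration uses a
stiff-capable implicit method with an analytic Jacobian — TST rate constants
routinely span ten or more orders of magnitude, so stiffness is the norm.

On top of the trajectories the module extracts the quantities an
experimentalist would measure: product selectivity at equilibrium, apparent
activation energies from an Arrhenius fit over simulations at several
temperatures, and reaction orders from initial rates at several starting
concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import sympy
from scipy.integrate import solve_ivp

from .constants import R_KCAL
from .errors import (
    CompositionError,
    DomainError,
    FitError,
    SolverError,
    UndefinedSelectivityError,
)

__all__ = [
    "KineticNetwork",
    "MKMProblem",
    "MKMResult",
    "ArrheniusFit",
    "OrderFit",
    "build_network",
    "rhs",
    "simulate",
    "conserved_moieties",
    "selectivity",
    "apparent_activation_energy",
    "reaction_order",
]


@dataclass
class NetworkStep:
    """One reversible step of a kinetic network, in species-name terms."""

    reactants: dict[str, int]
    products: dict[str, int]
    k_f: float
    k_r: float = 0.0
    label: str = ""
    composition: dict[str, dict[str, int]] | None = None  # optional, for balance checks

    def __post_init__(self) -> None:
        if self.k_f < 0 or self.k_r < 0:
            raise DomainError("rate constants must be non-negative")


@dataclass
class KineticNetwork:
    """Species list, steps, and the signed stoichiometric matrix ν (n×m)."""

    species: list[str]
    steps: list[NetworkStep]
    stoich: np.ndarray          # ν, n×m signed integers
    orders_f: np.ndarray        # reactant orders, n×m ≥ 0
    orders_r: np.ndarray        # product orders, n×m ≥ 0

    @property
    def k_f(self) -> np.ndarray:
        return np.array([s.k_f for s in self.steps])

    @property
    def k_r(self) -> np.ndarray:
        return np.array([s.k_r for s in self.steps])

    def index(self, name: str) -> int:
        return self.species.index(name)


def build_network(
    steps: Sequence[NetworkStep] | Sequence[dict],
    compositions: dict[str, dict[str, int]] | None = None,
) -> KineticNetwork:
    """Assemble a :class:`KineticNetwork` from reversible steps.

    Species order is first-appearance order (reactants before products,
    steps in input order).  When ``compositions`` is given, every step is
    checked for elemental balance and an imbalance raises
    :class:`CompositionError`.
    """
    parsed: list[NetworkStep] = [
        s if isinstance(s, NetworkStep) else NetworkStep(**s) for s in steps
    ]
    species: list[str] = []
    for s in parsed:
        for name in list(s.reactants) + list(s.products):
            if name not in species:
                species.append(name)
    if compositions is not None:
        for s in parsed:
            lhs: dict[str, int] = {}
            rhs_: dict[str, int] = {}
            for name, cnt in s.reactants.items():
                for el, n in compositions.get(name, {}).items():
                    lhs[el] = lhs.get(el, 0) + cnt * n
            for name, cnt in s.products.items():
                for el, n in compositions.get(name, {}).items():
                    rhs_[el] = rhs_.get(el, 0) + cnt * n
            if lhs != rhs_:
                raise CompositionError(
                    f"step {s.label or s.reactants}: element imbalance {lhs} vs {rhs_}"
                )
    n, m = len(species), len(parsed)
    stoich = np.zeros((n, m), dtype=int)
    of = np.zeros((n, m), dtype=int)
    orr = np.zeros((n, m), dtype=int)
    for j, s in enumerate(parsed):
        for name, cnt in s.reactants.items():
            i = species.index(name)
            stoich[i, j] -= cnt
            of[i, j] += cnt
        for name, cnt in s.products.items():
            i = species.index(name)
            stoich[i, j] += cnt
            orr[i, j] += cnt
    return KineticNetwork(species=species, steps=parsed, stoich=stoich,
                          orders_f=of, orders_r=orr)


def _step_rates_vector(network: KineticNetwork, c: np.ndarray) -> np.ndarray:
    c = np.maximum(np.asarray(c, dtype=float), 0.0)
    # Π c_i^order with 0^0 = 1
    log_safe = np.where(c > 0, c, 1.0)
    fwd = network.k_f * np.prod(
        np.where(network.orders_f > 0, log_safe[:, None] ** network.orders_f, 1.0)
        * np.where((network.orders_f > 0) & (c[:, None] == 0), 0.0, 1.0),
        axis=0,
    )
    rev = network.k_r * np.prod(
        np.where(network.orders_r > 0, log_safe[:, None] ** network.orders_r, 1.0)
        * np.where((network.orders_r > 0) & (c[:, None] == 0), 0.0, 1.0),
        axis=0,
    )
    return fwd - rev


def rhs(network: KineticNetwork, c: np.ndarray) -> np.ndarray:
    """Mass-action dC/dt = ν · r(c)."""
    return network.stoich @ _step_rates_vector(network, c)


def _jacobian(network: KineticNetwork, c: np.ndarray) -> np.ndarray:
    """Analytic Jacobian ∂(dC/dt)/∂c for the implicit solver."""
    c = np.maximum(np.asarray(c, dtype=float), 0.0)
    n, m = network.stoich.shape
    safe = np.where(c > 0, c, 1.0)
    fwd_prod = network.k_f * np.prod(
        np.where(network.orders_f > 0, safe[:, None] ** network.orders_f, 1.0)
        * np.where((network.orders_f > 0) & (c[:, None] == 0), 0.0, 1.0),
        axis=0,
    )
    rev_prod = network.k_r * np.prod(
        np.where(network.orders_r > 0, safe[:, None] ** network.orders_r, 1.0)
        * np.where((network.orders_r > 0) & (c[:, None] == 0), 0.0, 1.0),
        axis=0,
    )
    drate = np.zeros((m, n))
    for j in range(m):
        for i in range(n):
            pf = network.orders_f[i, j]
            pr = network.orders_r[i, j]
            if pf > 0:
                if c[i] > 0:
                    drate[j, i] += pf * fwd_prod[j] / c[i]
                else:
                    # derivative at c_i = 0: nonzero only for first order
                    others = np.prod(
                        [
                            safe[k] ** network.orders_f[k, j]
                            if c[k] > 0 or network.orders_f[k, j] == 0
                            else 0.0
                            for k in range(n)
                            if k != i
                        ]
                    )
                    drate[j, i] += network.k_f[j] * others if pf == 1 else 0.0
            if pr > 0:
                if c[i] > 0:
                    drate[j, i] -= pr * rev_prod[j] / c[i]
                else:
                    others = np.prod(
                        [
                            safe[k] ** network.orders_r[k, j]
                            if c[k] > 0 or network.orders_r[k, j] == 0
                            else 0.0
                            for k in range(n)
                            if k != i
                        ]
                    )
                    drate[j, i] -= network.k_r[j] * others if pr == 1 else 0.0
    return network.stoich @ drate


@dataclass
class MKMProblem:
    """A batch isothermal reactor simulation request."""

    network: KineticNetwork
    c0: dict[str, float] | np.ndarray
    t_end: float
    T: float = 298.15
    rtol: float = 1e-8
    atol: float = 1e-12
    eq_tol: float | None = None     # default: 1e-12 · max(c0) per second
    n_points: int = 200             # output grid size (log-spaced + t=0)

    def initial_vector(self) -> np.ndarray:
        if isinstance(self.c0, dict):
            c = np.zeros(len(self.network.species))
            for name, value in self.c0.items():
                c[self.network.index(name)] = value
        else:
            c = np.asarray(self.c0, dtype=float)
        if c.shape != (len(self.network.species),):
            raise DomainError("c0 length does not match species count")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise DomainError("c0 must be finite and non-negative")
        return c

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise DomainError("t_end must be positive")
        if self.rtol <= 0 or self.atol <= 0:
            raise DomainError("solver tolerances must be positive")


@dataclass
class MKMResult:
    """Time grid, per-species trajectories, and equilibrium/conservation info."""

    network: KineticNetwork
    times: np.ndarray
    conc: np.ndarray                 # shape (n_species, n_times)
    reached_equilibrium: bool
    equilibrium_time: float | None
    conserved_residual: float

    def trajectory(self, name: str) -> np.ndarray:
        return self.conc[self.network.index(name)]

    def final(self, name: str) -> float:
        return float(self.conc[self.network.index(name), -1])


def conserved_moieties(network: KineticNetwork) -> list[np.ndarray]:
    """Rational basis of the left null space of ν (conserved moieties).

    Computed by exact elimination over the rationals; returned as float
    arrays of exact rational values.
    """
    n, m = network.stoich.shape
    if m == 0 or n == 0:
        return [np.eye(n)[i] for i in range(n)]
    mat = sympy.Matrix(network.stoich.T.tolist())
    basis = mat.nullspace()
    out = []
    for vec in basis:
        denominators = [sympy.fraction(sympy.nsimplify(v))[1] for v in vec]
        scale = sympy.lcm(denominators) if denominators else 1
        out.append(np.array([float(v * scale) for v in vec]))
    return out


def _conserved_drift(network: KineticNetwork, conc: np.ndarray) -> float:
    """Max relative drift of every conserved moiety over a trajectory."""
    worst = 0.0
    for w in conserved_moieties(network):
        totals = w @ conc
        ref = max(abs(totals[0]), 1e-300)
        worst = max(worst, float(np.max(np.abs(totals - totals[0])) / ref))
    return worst


def simulate(problem: MKMProblem, t_eval: np.ndarray | None = None) -> MKMResult:
    """Integrate the network ODEs to ``t_end`` or until equilibrium.

    Uses BDF with the analytic Jacobian.  Equilibrium is declared when
    ‖dC/dt‖∞ stays below ``eq_tol`` (default 10⁻¹²·max(c0) s⁻¹); the event
    is terminal, so the returned grid may end early.  Negative undershoots
    beyond −atol are clipped with a warning.
    """
    network = problem.network
    c0 = problem.initial_vector()
    eq_tol = problem.eq_tol
    if eq_tol is None:
        eq_tol = 1e-12 * max(float(c0.max()), 1.0)

    if t_eval is None:
        # log-spaced grid resolves both the fast transient and the approach
        # to equilibrium
        t_small = problem.t_end * 1e-9
        t_eval = np.concatenate(
            [[0.0], np.geomspace(t_small, problem.t_end, problem.n_points)]
        )

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        return rhs(network, y)

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        return _jacobian(network, y)

    def equilibrium_event(t: float, y: np.ndarray) -> float:
        return float(np.max(np.abs(rhs(network, y)))) - eq_tol

    equilibrium_event.terminal = True
    equilibrium_event.direction = -1

    sol = solve_ivp(
        fun,
        (0.0, problem.t_end),
        c0,
        method="BDF",
        jac=jac,
        rtol=problem.rtol,
        atol=problem.atol,
        t_eval=t_eval,
        events=[equilibrium_event],
        dense_output=False,
    )
    if not sol.success and sol.status != 1:
        raise SolverError(
            f"integration failed: {sol.message}", times=sol.t, conc=sol.y
        )

    times, conc = sol.t, sol.y
    reached_eq = sol.status == 1 and len(sol.t_events[0]) > 0
    eq_time = float(sol.t_events[0][0]) if reached_eq else None
    if reached_eq and (times.size == 0 or sol.t_events[0][0] > times[-1]):
        times = np.append(times, sol.t_events[0][0])
        conc = np.column_stack([conc, sol.y_events[0][0]]) if conc.size else \
            np.asarray(sol.y_events[0][0])[:, None]
    if times.size == 0 or times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        conc = np.column_stack([c0, conc]) if conc.size else c0[:, None]
    # equilibrium may also be effectively reached at t_end without the event
    if not reached_eq:
        final_drift = float(np.max(np.abs(rhs(network, conc[:, -1]))))
        if final_drift < eq_tol:
            reached_eq, eq_time = True, float(times[-1])

    undershoot = conc.min() if conc.size else 0.0
    if undershoot < -problem.atol:
        warnings.warn(
            f"negative concentration undershoot {undershoot:.3e} clipped",
            stacklevel=2,
        )
    conc = np.maximum(conc, -problem.atol)

    return MKMResult(
        network=network,
        times=times,
        conc=conc,
        reached_equilibrium=reached_eq,
        equilibrium_time=eq_time,
        conserved_residual=_conserved_drift(network, conc),
    )


def selectivity(
    result: MKMResult,
    target: str,
    competitors: Iterable[str],
    force: bool = False,
) -> float:
    """S = c_target / (c_target + Σ c_competitors) at the evaluation time.

    Evaluated at equilibrium; if equilibrium was not reached, requires
    ``force=True`` to evaluate at ``t_end`` (with a warning).
    """
    if not result.reached_equilibrium:
        if not force:
            raise DomainError(
                "system did not reach equilibrium; pass force=True to "
                "evaluate selectivity at t_end"
            )
        warnings.warn("selectivity evaluated before equilibrium", stacklevel=2)
    c_t = result.final(target)
    c_comp = sum(result.final(name) for name in competitors)
    total = c_t + c_comp
    if total <= 0:
        raise UndefinedSelectivityError(
            "all product concentrations are zero; selectivity undefined"
        )
    return c_t / total


# ---------------------------------------------------------------------------
# Initial-rate probes and fits

def _initial_rate(
    problem: MKMProblem,
    probe: str,
    limiting: str | None = None,
    max_conversion: float = 0.05,
) -> float:
    """Initial formation/consumption rate of ``probe`` (mol L⁻¹ s⁻¹).

    Finite difference over the earliest window in which conversion of the
    limiting reactant stays ≤ ``max_conversion``.
    """
    network = problem.network
    c0 = problem.initial_vector()
    if limiting is None:
        rates0 = rhs(network, c0)
        candidates = [
            i for i in range(len(network.species))
            if c0[i] > 0 and rates0[i] < 0
        ]
        if not candidates:
            raise FitError("no limiting reactant with positive c0 found")
        limiting_idx = min(candidates, key=lambda i: c0[i])
    else:
        limiting_idx = network.index(limiting)
        if c0[limiting_idx] <= 0:
            raise FitError(f"limiting reactant {limiting!r} has zero c0")

    r0 = rhs(network, c0)[limiting_idx]
    if r0 >= 0:
        # limiting species not consumed initially; fall back to a short window
        t_window = problem.t_end * 1e-6
    else:
        t_window = min(problem.t_end, max_conversion * c0[limiting_idx] / abs(r0))
    grid = np.linspace(0.0, t_window, 8)[1:]
    short = MKMProblem(
        network=network,
        c0=c0,
        t_end=t_window,
        T=problem.T,
        rtol=problem.rtol,
        atol=problem.atol,
        eq_tol=1e-300,  # no equilibrium cutoff for a rate probe
    )
    res = simulate(short, t_eval=np.concatenate([[0.0], grid]))
    conv = (c0[limiting_idx] - res.conc[limiting_idx]) / max(c0[limiting_idx], 1e-300)
    ok = np.where(conv <= max_conversion)[0]
    last = int(ok[-1]) if ok.size > 1 else len(res.times) - 1
    probe_traj = res.trajectory(probe)
    dt = res.times[last] - res.times[0]
    if dt <= 0:
        raise FitError("empty rate window")
    return float((probe_traj[last] - probe_traj[0]) / dt)


@dataclass
class ArrheniusFit:
    """ln r = intercept − (Ea/R)·(1/T) least-squares fit."""

    ea_apparent: float            # kcal/mol
    intercept: float              # ln(rate) extrapolated to 1/T = 0
    r_squared: float
    points: list[tuple[float, float]]  # (T, rate)


@dataclass
class OrderFit:
    """ln r = intercept + order·ln c₀ least-squares fit."""

    order: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]]  # (c0, rate)


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), r2


def apparent_activation_energy(
    problem_factory: Callable[[float], MKMProblem],
    temperatures: Sequence[float],
    probe: str,
    limiting: str | None = None,
) -> ArrheniusFit:
    """Arrhenius fit of simulated initial rates over several temperatures.

    Ea = −R · slope of ln r vs 1/T, reported in kcal/mol.
    """
    if len(temperatures) < 2:
        raise DomainError("need at least two temperatures")
    points: list[tuple[float, float]] = []
    for T in temperatures:
        if T <= 0:
            raise DomainError("temperatures must be positive")
        rate = abs(_initial_rate(problem_factory(T), probe, limiting))
        if rate <= 0:
            raise FitError(f"non-positive probe rate at T = {T} K")
        points.append((float(T), rate))
    x = np.array([1.0 / T for T, _ in points])
    y = np.array([np.log(r) for _, r in points])
    slope, intercept, r2 = _linear_fit(x, y)
    return ArrheniusFit(
        ea_apparent=-R_KCAL * slope,
        intercept=intercept,
        r_squared=r2,
        points=points,
    )


def reaction_order(
    problem_factory: Callable[[float], MKMProblem],
    initial_concs: Sequence[float],
    species: str,
    probe: str | None = None,
) -> OrderFit:
    """Reaction order in ``species``: slope of ln(initial rate) vs ln c₀.

    ``probe`` defaults to ``species`` itself (consumption rate).
    """
    if len(initial_concs) < 2:
        raise DomainError("need at least two initial concentrations")
    if any(c <= 0 for c in initial_concs):
        raise DomainError("initial concentrations must be positive")
    probe = probe or species
    points: list[tuple[float, float]] = []
    for c0 in initial_concs:
        rate = abs(_initial_rate(problem_factory(float(c0)), probe, limiting=species))
        if rate <= 0:
            raise FitError(f"non-positive probe rate at c0 = {c0}")
        points.append((float(c0), rate))
    x = np.log([c for c, _ in points])
    y = np.log([r for _, r in points])
    slope, intercept, r2 = _linear_fit(np.asarray(x), np.asarray(y))
    return OrderFit(order=slope, intercept=intercept, r_squared=r2, points=points)
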