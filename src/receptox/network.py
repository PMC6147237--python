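"""Mass-action reaction-network engine.

A biochemical network is represented as a Petri net: *places* are molecular
species carrying an amount (token count in stochastic mode, continuum amount
in ODE mode) and *transitions* are mass-action reactions. The same
:class:`ReactionNetwork` object drives

* exact stochastic simulation (Gillespie direct method),
* the continuum ODE approximation ``dS/dt = N v(S)``,
* steady-state location (long-time integration plus Newton refinement), and
* conserved-moiety analysis (rational left null space of the stoichiometric
  matrix).

Species can be *clamped* (boundary species): they contribute to reaction
rates but their net derivative is zero by construction, which is how a
sustained ligand stimulus or a constant synthesis source is realised.

Rate units are arbitrary ("Petri-net time units"); no mapping to wall-clock
time is attempted.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "NetworkState",
    "Trajectory",
    "NetworkError",
    "SimulationError",
    "SteadyStateError",
    "SteadyStateConfig",
    "ODEConfig",
    "mass_action_flux",
    "simulate_ode",
    "simulate_ssa",
    "find_steady_state",
    "conserved_moieties",
    "reachable_species",
    "to_token_network",
    "read_network_csv",
    "write_network_csv",
]


class NetworkError(ValueError):
    """Malformed network, state or argument."""


class SimulationError(RuntimeError):
    """Integration or stochastic simulation failed; message carries diagnostics."""


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge.

    Attributes
    ----------
    residual : float
        Relative residual ``max |dS_i/dt| / (1 + |S_i|)`` at the best state.
    state : NetworkState
        Best state found (for post-mortem inspection).
    """

    def __init__(self, message, residual=None, state=None):
        super().__init__(message)
        self.residual = residual
        self.state = state


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Species:
    """A place of the Petri net.

    ``clamped`` marks a boundary species whose amount is held constant during
    any simulation (its row of the stoichiometric matrix is zeroed in the
    dynamics, but it still multiplies into reaction rates).
    """

    id: str
    name: str = ""
    clamped: bool = False


@dataclass
class Reaction:
    """A transition of the Petri net with mass-action kinetics.

    ``reactants``/``products`` map species id to a positive integer
    stoichiometry. ``modifiers`` are read arcs: catalysts that multiply the
    rate linearly but have zero net stoichiometry. A reaction with no
    reactants and no modifiers fires at the constant rate ``rate_constant``
    (a zero-order source).
    """

    id: str
    reactants: dict = field(default_factory=dict)
    products: dict = field(default_factory=dict)
    modifiers: list = field(default_factory=list)
    rate_constant: float = 1.0
    name: str = ""

    def validate(self):
        if not self.reactants and not self.products:
            raise NetworkError(f"reaction {self.id!r}: reactants and products both empty")
        if self.rate_constant < 0:
            raise NetworkError(f"reaction {self.id!r}: negative rate constant")
        for d in (self.reactants, self.products):
            for sp, st in d.items():
                if int(st) != st or st <= 0:
                    raise NetworkError(
                        f"reaction {self.id!r}: stoichiometry of {sp!r} must be a positive integer"
                    )


class ReactionNetwork:
    """Ordered species + reactions with a cached integer stoichiometric matrix.

    Column *j* of :attr:`stoichiometric_matrix` is the net stoichiometry of
    reaction *j* (products minus reactants; modifiers contribute zero).
    """

    def __init__(self, species, reactions):
        self.species = list(species)
        self.reactions = list(reactions)
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate species ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise NetworkError("duplicate reaction ids")
        self.species_index = {s.id: i for i, s in enumerate(self.species)}
        self.reaction_index = {r.id: j for j, r in enumerate(self.reactions)}
        for r in self.reactions:
            r.validate()
            for sp in list(r.reactants) + list(r.products) + list(r.modifiers):
                if sp not in self.species_index:
                    raise NetworkError(f"reaction {r.id!r} references unknown species {sp!r}")
        self._stoich = None
        self._compiled = None
        self._moieties = None

    @property
    def n_species(self):
        return len(self.species)

    @property
    def n_reactions(self):
        return len(self.reactions)

    @property
    def stoichiometric_matrix(self):
        if self._stoich is None:
            N = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
            for j, r in enumerate(self.reactions):
                for sp, st in r.reactants.items():
                    N[self.species_index[sp], j] -= int(st)
                for sp, st in r.products.items():
                    N[self.species_index[sp], j] += int(st)
            self._stoich = N
        return self._stoich

    @property
    def clamped_mask(self):
        return np.array([s.clamped for s in self.species], dtype=bool)

    @property
    def rate_constants(self):
        return np.array([r.rate_constant for r in self.reactions], dtype=float)

    def state(self, amounts=None, time=0.0):
        """Build a :class:`NetworkState` from a mapping id -> amount (others 0)."""
        x = np.zeros(self.n_species)
        if amounts:
            for sp, a in amounts.items():
                x[self.species_index[sp]] = a
        return NetworkState(amounts=x, time=time)

    def with_rate(self, reaction_id, rate_constant):
        """Copy of the network with one rate constant replaced."""
        reactions = []
        for r in self.reactions:
            if r.id == reaction_id:
                r = Reaction(r.id, dict(r.reactants), dict(r.products),
                             list(r.modifiers), rate_constant, r.name)
            reactions.append(r)
        net = ReactionNetwork([Species(s.id, s.name, s.clamped) for s in self.species], reactions)
        net._moieties = self._moieties  # null space does not depend on rates
        return net

    def compiled(self):
        if self._compiled is None:
            self._compiled = _compile(self)
        return self._compiled


@dataclass
class NetworkState:
    """Marking of the Petri net: per-species amounts at a time point."""

    amounts: np.ndarray
    time: float = 0.0
    meta: dict = field(default_factory=dict)

    def copy(self):
        return NetworkState(self.amounts.copy(), self.time, dict(self.meta))


@dataclass
class Trajectory:
    """Time-resolved output of a simulation (rows of ``states`` follow
    ``species_ids``; ``mode`` is ``"ode"`` or ``"stochastic"``)."""

    times: np.ndarray
    states: np.ndarray
    mode: str
    species_ids: list
    seed: int | None = None

    def series(self, species_id):
        return self.states[:, self.species_ids.index(species_id)]

    def final_state(self):
        return NetworkState(self.states[-1].astype(float).copy(), float(self.times[-1]))


# ---------------------------------------------------------------------------
# compilation to flat arrays (shared by ODE and SSA paths)
# ---------------------------------------------------------------------------


class _Compiled:
    __slots__ = ("k", "ex_ptr", "ex_sp", "ex_exp", "up_ptr", "up_sp", "up_delta", "n_species")


def _compile(net: ReactionNetwork):
    """Flatten the network into CSR-style arrays.

    ``ex_*`` hold the rate-law exponents per reaction (reactant stoichiometry
    plus one per modifier occurrence — a species that is both reactant and
    modifier gets the summed exponent). ``up_*`` hold the net state updates
    with clamped rows removed.
    """
    c = _Compiled()
    c.n_species = net.n_species
    c.k = net.rate_constants
    ex_ptr, ex_sp, ex_exp = [0], [], []
    for r in net.reactions:
        exps = {}
        for sp, st in r.reactants.items():
            exps[net.species_index[sp]] = exps.get(net.species_index[sp], 0) + int(st)
        for sp in r.modifiers:
            exps[net.species_index[sp]] = exps.get(net.species_index[sp], 0) + 1
        for i in sorted(exps):
            ex_sp.append(i)
            ex_exp.append(exps[i])
        ex_ptr.append(len(ex_sp))
    N = net.stoichiometric_matrix.copy()
    N[net.clamped_mask, :] = 0
    up_ptr, up_sp, up_delta = [0], [], []
    for j in range(net.n_reactions):
        nz = np.nonzero(N[:, j])[0]
        up_sp.extend(nz.tolist())
        up_delta.extend(N[nz, j].tolist())
        up_ptr.append(len(up_sp))
    c.ex_ptr = np.array(ex_ptr, dtype=np.int64)
    c.ex_sp = np.array(ex_sp, dtype=np.int64)
    c.ex_exp = np.array(ex_exp, dtype=np.int64)
    c.up_ptr = np.array(up_ptr, dtype=np.int64)
    c.up_sp = np.array(up_sp, dtype=np.int64)
    c.up_delta = np.array(up_delta, dtype=np.int64)
    return c


@njit(cache=True)
def _flux_kernel(y, k, ex_ptr, ex_sp, ex_exp):
    v = np.empty(k.size)
    for j in range(k.size):
        f = k[j]
        for q in range(ex_ptr[j], ex_ptr[j + 1]):
            s = y[ex_sp[q]]
            e = ex_exp[q]
            if e == 1:
                f *= s
            else:
                f *= s ** e
        v[j] = f
    return v


@njit(cache=True)
def _rhs_kernel(y, k, ex_ptr, ex_sp, ex_exp, up_ptr, up_sp, up_delta):
    v = _flux_kernel(y, k, ex_ptr, ex_sp, ex_exp)
    dy = np.zeros(y.size)
    for j in range(k.size):
        for q in range(up_ptr[j], up_ptr[j + 1]):
            dy[up_sp[q]] += up_delta[q] * v[j]
    return dy


@njit(cache=True)
def _jac_kernel(y, k, ex_ptr, ex_sp, ex_exp, up_ptr, up_sp, up_delta):
    n = y.size
    J = np.zeros((n, n))
    for j in range(k.size):
        lo, hi = ex_ptr[j], ex_ptr[j + 1]
        for q in range(lo, hi):
            l = ex_sp[q]
            e = ex_exp[q]
            d = k[j] * e * y[l] ** (e - 1)
            for p in range(lo, hi):
                if p != q:
                    d *= y[ex_sp[p]] ** ex_exp[p]
            for u in range(up_ptr[j], up_ptr[j + 1]):
                J[up_sp[u], l] += up_delta[u] * d
    return J


# ---------------------------------------------------------------------------
# deterministic simulation
# ---------------------------------------------------------------------------


@dataclass
class ODEConfig:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    n_points: int = 201  # output grid when t_eval not given


def _check_state(net, state):
    x = np.asarray(state.amounts, dtype=float)
    if x.shape != (net.n_species,):
        raise NetworkError(
            f"state has {x.shape} amounts for a network of {net.n_species} species"
        )
    if np.any(x < 0):
        bad = net.species[int(np.argmin(x))].id
        raise NetworkError(f"negative amount for species {bad!r}")
    return x


def mass_action_flux(network, state):
    """Mass-action flux vector, one nonnegative real per reaction.

    ``flux_j = k_j * prod(amount^stoichiometry)`` over reactants and
    modifiers; a zero amount anywhere gives a zero flux.
    """
    x = _check_state(network, state)
    c = network.compiled()
    return _flux_kernel(x, c.k, c.ex_ptr, c.ex_sp, c.ex_exp)


def _make_rhs(net):
    c = net.compiled()

    def rhs(t, y):
        return _rhs_kernel(y, c.k, c.ex_ptr, c.ex_sp, c.ex_exp, c.up_ptr, c.up_sp, c.up_delta)

    def jac(t, y):
        return _jac_kernel(y, c.k, c.ex_ptr, c.ex_sp, c.ex_exp, c.up_ptr, c.up_sp, c.up_delta)

    return rhs, jac


def simulate_ode(network, state0, t_end, config=None, t_eval=None):
    """Integrate the continuum approximation ``dS/dt = N v(S)``.

    Uses a stiff-capable integrator (LSODA by default) with the analytic
    mass-action Jacobian. Clamped species are held fixed. Raises
    :class:`SimulationError` with the solver message on failure.
    """
    cfg = config or ODEConfig()
    if t_end <= 0:
        raise NetworkError("t_end must be positive")
    x0 = _check_state(network, state0)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, cfg.n_points)
    rhs, jac = _make_rhs(network)
    sol = solve_ivp(rhs, (0.0, float(t_end)), x0, method=cfg.method,
                    t_eval=np.asarray(t_eval, dtype=float), rtol=cfg.rtol,
                    atol=cfg.atol, jac=jac)
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed at t={sol.t[-1] if sol.t.size else 0}: {sol.message}"
        )
    return Trajectory(times=sol.t, states=sol.y.T.copy(), mode="ode",
                      species_ids=[s.id for s in network.species])


# ---------------------------------------------------------------------------
# stochastic simulation (Gillespie direct method)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _propensities(x, k, ex_ptr, ex_sp, ex_exp):
    a = np.empty(k.size)
    for j in range(k.size):
        f = k[j]
        for q in range(ex_ptr[j], ex_ptr[j + 1]):
            c = x[ex_sp[q]]
            e = ex_exp[q]
            if e == 1:
                f *= c
            else:
                # combinatorial mass action: C(c, e) distinct e-tuples
                num = 1.0
                for m in range(e):
                    num *= c - m
                for m in range(2, e + 1):
                    num /= m
                f *= num
        a[j] = f if f > 0.0 else 0.0
    return a


@njit(cache=True)
def _ssa_kernel(x0, t_end, k, ex_ptr, ex_sp, ex_exp, up_ptr, up_sp, up_delta,
                t_eval, record_events, max_events, seed):
    np.random.seed(seed)
    n = x0.size
    x = x0.copy()
    t = 0.0
    n_grid = t_eval.size
    grid = np.zeros((n_grid, n), dtype=np.int64)
    gi = 0
    cap = max_events + 1 if record_events else 1
    ev_t = np.zeros(cap)
    ev_x = np.zeros((cap, n), dtype=np.int64)
    ne = 0
    if record_events:
        ev_t[0] = 0.0
        ev_x[0] = x
    overflow = 0
    while True:
        a = _propensities(x, k, ex_ptr, ex_sp, ex_exp)
        a0 = a.sum()
        if a0 <= 0.0:
            t_next = np.inf
        else:
            t_next = t - math.log(np.random.random()) / a0
        while gi < n_grid and t_eval[gi] < t_next:
            grid[gi] = x
            gi += 1
        if t_next > t_end or not np.isfinite(t_next):
            break
        t = t_next
        r = np.random.random() * a0
        acc = 0.0
        jchosen = a.size - 1
        for j in range(a.size):
            acc += a[j]
            if r < acc:
                jchosen = j
                break
        for q in range(up_ptr[jchosen], up_ptr[jchosen + 1]):
            x[up_sp[q]] += up_delta[q]
        ne += 1
        if record_events:
            if ne >= cap:
                overflow = 1
                break
            ev_t[ne] = t
            ev_x[ne] = x
    while gi < n_grid:
        grid[gi] = x
        gi += 1
    return grid, ev_t[: ne + 1], ev_x[: ne + 1], ne, overflow


def simulate_ssa(network, state0, t_end, seed, t_eval=None, max_events=1_000_000):
    """Exact stochastic simulation with combinatorial mass-action propensities.

    Token counts must be integers. With ``t_eval`` given, the trajectory is
    sampled on that grid (suitable for large ensembles); otherwise every
    firing event is recorded (up to ``max_events``). Identical arguments give
    a bit-identical trajectory. A state with zero total propensity before
    ``t_end`` terminates cleanly at the absorbing state.
    """
    if seed is None:
        raise NetworkError("simulate_ssa requires an explicit seed")
    x = _check_state(network, state0)
    xi = np.rint(x).astype(np.int64)
    if np.any(np.abs(x - xi) > 1e-9):
        raise NetworkError("stochastic simulation requires integer token counts")
    if t_end <= 0:
        raise NetworkError("t_end must be positive")
    c = network.compiled()
    record_events = t_eval is None
    grid_times = (np.empty(0) if record_events else np.asarray(t_eval, dtype=float))
    grid, ev_t, ev_x, ne, overflow = _ssa_kernel(
        xi, float(t_end), c.k, c.ex_ptr, c.ex_sp, c.ex_exp,
        c.up_ptr, c.up_sp, c.up_delta, grid_times, record_events,
        int(max_events), int(seed) & 0x7FFFFFFF)
    if overflow:
        raise SimulationError(
            f"SSA exceeded max_events={max_events} before t_end={t_end}; "
            "pass t_eval for grid sampling or raise max_events")
    ids = [s.id for s in network.species]
    if record_events:
        return Trajectory(times=ev_t, states=ev_x, mode="stochastic",
                          species_ids=ids, seed=int(seed))
    return Trajectory(times=grid_times, states=grid, mode="stochastic",
                      species_ids=ids, seed=int(seed))


# ---------------------------------------------------------------------------
# conserved moieties
# ---------------------------------------------------------------------------


def conserved_moieties(network):
    """Rational basis of the left null space of N over unclamped species.

    Returns a list of dicts ``{species_id: integer weight}``; every vector v
    satisfies ``v^T N = 0`` exactly (rational arithmetic), so ``v . state``
    is invariant under all reactions. Vectors are scaled to primitive
    integers and made nonnegative where a small integer recombination
    achieves it. Clamped species are excluded (they are constant anyway and
    would otherwise generate spurious singleton invariants).
    """
    if network.n_species == 0:
        raise NetworkError("empty network")
    mask = ~network.clamped_mask
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    N = sympy.Matrix(network.stoichiometric_matrix[idx, :])
    basis = N.T.nullspace()
    vecs = []
    for b in basis:
        fracs = [Fraction(sympy.Rational(v).p, sympy.Rational(v).q) for v in b]
        denom = 1
        for f in fracs:
            denom = denom * f.denominator // math.gcd(denom, f.denominator)
        ints = [int(f * denom) for f in fracs]
        g = 0
        for v in ints:
            g = math.gcd(g, abs(v))
        if g > 1:
            ints = [v // g for v in ints]
        vecs.append(np.array(ints, dtype=object))
    vecs = _nonnegativize(vecs)
    out = []
    for v in vecs:
        d = {}
        for pos, i in enumerate(idx):
            if v[pos] != 0:
                d[network.species[i].id] = int(v[pos])
        if d:
            out.append(d)
    return out


def _nonnegativize(vecs):
    """Greedy small-integer recombination toward nonnegative vectors."""
    vecs = [v.copy() for v in vecs]
    for _ in range(4):
        changed = False
        for i, v in enumerate(vecs):
            if all(x >= 0 for x in v):
                continue
            if all(x <= 0 for x in v):
                vecs[i] = -v
                changed = True
                continue
            for j, w in enumerate(vecs):
                if i == j:
                    continue
                for c in (1, -1, 2, -2, 3, -3):
                    cand = v + c * w
                    if all(x >= 0 for x in cand) and any(x != 0 for x in cand):
                        vecs[i] = cand
                        changed = True
                        break
                if changed:
                    break
        if not changed:
            break
    return vecs


def moiety_totals(network, state, moieties=None):
    """Weighted sums ``v . amounts`` for each conservation vector."""
    if moieties is None:
        moieties = conserved_moieties(network)
    x = state.amounts
    return np.array([
        sum(w * x[network.species_index[sp]] for sp, w in m.items()) for m in moieties
    ])


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------


@dataclass
class SteadyStateConfig:
    horizon: float = 1e4       # integration horizon before refinement
    rtol: float = 1e-8
    atol: float = 1e-12
    residual_tol: float = 1e-10  # relative residual for convergence
    refine: bool = True        # Newton refinement with moiety constraints


def _residual(net, x):
    c = net.compiled()
    dy = _rhs_kernel(x, c.k, c.ex_ptr, c.ex_sp, c.ex_exp, c.up_ptr, c.up_sp, c.up_delta)
    mask = ~net.clamped_mask
    return float(np.max(np.abs(dy[mask]) / (1.0 + np.abs(x[mask])))) if mask.any() else 0.0


def find_steady_state(network, state0, config=None):
    """Locate a steady state by long-time integration + Newton refinement.

    The refinement solves ``N v(S) = 0`` on the unclamped species with one
    row per conserved moiety replaced by the linear constraint pinning that
    moiety's total to its value in ``state0``, so conservation laws are
    preserved exactly. Raises :class:`SteadyStateError` (carrying the
    residual and best state) on non-convergence, with oscillatory dynamics
    flagged in the message.
    """
    cfg = config or SteadyStateConfig()
    x0 = _check_state(network, state0)
    rhs, jac = _make_rhs(network)
    tchk = (0.0, cfg.horizon * 0.5, cfg.horizon)
    sol = solve_ivp(rhs, (0.0, cfg.horizon), x0, method="LSODA",
                    t_eval=tchk, rtol=cfg.rtol, atol=cfg.atol, jac=jac)
    if not sol.success:
        raise SteadyStateError(f"integration toward steady state failed: {sol.message}")
    x_mid, x_end = sol.y[:, 1], sol.y[:, 2]
    x = np.maximum(x_end, 0.0)
    if cfg.refine:
        x = _newton_refine(network, x, state0, cfg)
    res = _residual(network, x)
    if res > cfg.residual_tol:
        moving = np.max(np.abs(x_end - x_mid) / (1.0 + np.abs(x_end)))
        osc = " (state still changing over the horizon tail: possibly oscillatory)" \
            if moving > 1e-6 else ""
        raise SteadyStateError(
            f"steady state not reached within horizon {cfg.horizon}: "
            f"relative residual {res:.3e}{osc}",
            residual=res, state=NetworkState(x, cfg.horizon))
    st = NetworkState(np.maximum(x, 0.0), time=cfg.horizon)
    st.meta["residual"] = res
    return st


def _newton_refine(net, x_guess, state0, cfg):
    mask = ~net.clamped_mask
    uidx = np.nonzero(mask)[0]
    if uidx.size == 0:
        return x_guess
    moieties = net._moieties
    if moieties is None:
        moieties = conserved_moieties(net)
        net._moieties = moieties
    # pivot row per moiety: largest-weight member not yet taken
    pivots, mrows = [], []
    taken = set()
    pos_of = {int(i): p for p, i in enumerate(uidx)}
    for m in moieties:
        row = np.zeros(uidx.size)
        for sp, w in m.items():
            row[pos_of[net.species_index[sp]]] = w
        order = np.argsort(-np.abs(row))
        piv = next((int(q) for q in order if row[q] != 0 and q not in taken), None)
        if piv is None:
            continue
        taken.add(piv)
        pivots.append(piv)
        mrows.append(row)
    totals0 = [float(row @ state0.amounts[uidx]) for row in mrows]
    rhs, _ = _make_rhs(net)
    full = x_guess.copy()

    def F(xu):
        full[uidx] = xu
        dy = rhs(0.0, full)[uidx]
        out = dy.copy()
        for row, piv, tot in zip(mrows, pivots, totals0):
            out[piv] = row @ xu - tot
        return out

    solr = root(F, x_guess[uidx], method="hybr", tol=1e-12)
    xu = solr.x
    if np.any(xu < -1e-8):
        return x_guess  # refinement left the physical region; keep integrated state
    # a refinement only polishes: reject solutions far from the integrated state
    if np.linalg.norm(xu - x_guess[uidx]) > 0.1 * (1.0 + np.linalg.norm(x_guess[uidx])):
        return x_guess
    xu = np.maximum(xu, 0.0)
    cand = x_guess.copy()
    cand[uidx] = xu
    return cand if _residual(net, cand) <= _residual(net, x_guess) else x_guess


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------


def reachable_species(network, state0):
    """Set of species ids markable from ``state0`` (Petri-net reachability
    over-approximation: a transition is enabled once all reactants and
    modifiers have been marked)."""
    marked = {s.id for s, a in zip(network.species, state0.amounts) if a > 0}
    changed = True
    while changed:
        changed = False
        for r in network.reactions:
            need = set(r.reactants) | set(r.modifiers)
            if need <= marked:
                new = set(r.products) - marked
                if new:
                    marked |= new
                    changed = True
    return marked


def to_token_network(network, state, scale):
    """Convert continuum amounts to token counts at a given scale.

    Amounts are multiplied by ``scale`` and rounded; each rate constant is
    converted as ``k' = k * scale**(1 - order)`` (order = total rate-law
    exponent), the standard concentration-to-counts change of units with the
    scale playing the role of a volume. The ODE solution of the returned
    network in token units equals ``scale`` times the original solution.
    """
    if scale <= 0:
        raise NetworkError("scale must be positive")
    reactions = []
    for r in network.reactions:
        order = sum(int(v) for v in r.reactants.values()) + len(r.modifiers)
        k = r.rate_constant * float(scale) ** (1 - order)
        reactions.append(Reaction(r.id, dict(r.reactants), dict(r.products),
                                  list(r.modifiers), k, r.name))
    net = ReactionNetwork(
        [Species(s.id, s.name, s.clamped) for s in network.species], reactions)
    st = NetworkState(np.rint(np.asarray(state.amounts) * scale), state.time)
    return net, st


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_TERM = re.compile(r"^\s*(?:(\d+)\s*\*\s*)?([A-Za-z_][\w:.-]*)\s*$")


def _parse_side(text):
    d = {}
    text = (text or "").strip()
    if not text:
        return d
    for term in text.split("+"):
        m = _TERM.match(term)
        if not m:
            raise NetworkError(f"cannot parse stoichiometry term {term!r}")
        st = int(m.group(1) or 1)
        d[m.group(2)] = d.get(m.group(2), 0) + st
    return d


def _format_side(d):
    return " + ".join(f"{st}*{sp}" if st != 1 else sp for sp, st in d.items())


def write_network_csv(network, species_path, reactions_path):
    with open(species_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "name", "clamped"])
        for s in network.species:
            w.writerow([s.id, s.name, int(s.clamped)])
    with open(reactions_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "reactants", "products", "modifiers", "rate_constant"])
        for r in network.reactions:
            w.writerow([r.id, _format_side(r.reactants), _format_side(r.products),
                        " + ".join(r.modifiers), repr(r.rate_constant)])


def read_network_csv(species_path, reactions_path):
    species = []
    with open(species_path, newline="") as fh:
        for row in csv.DictReader(fh):
            species.append(Species(row["id"], row.get("name", ""),
                                   bool(int(row.get("clamped", "0") or 0))))
    reactions = []
    with open(reactions_path, newline="") as fh:
        for row in csv.DictReader(fh):
            mods = [sp for sp in _parse_side(row.get("modifiers", ""))]
            reactions.append(Reaction(row["id"], _parse_side(row.get("reactants", "")),
                                      _parse_side(row.get("products", "")), mods,
                                      float(row.get("rate_constant", 1.0))))
    return ReactionNetwork(species, reactions)
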