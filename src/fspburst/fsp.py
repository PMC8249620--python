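"""Finite State Projection solution of the time-varying CME.

The chemical master equation dp/dt = A(t) p(t) for one gene is solved on
the truncated lattice (gene state, mRNA count 0..max_count).
Transcription flux leaving the top copy-number bin is routed into a
single absorbing sink state, so the probability lost to truncation is
tracked exactly and certifies the solution error: if the sink mass
exceeds the requested tolerance the space is enlarged (doubling
max_count) and the integration restarted, up to a configured ceiling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _integrate
from .models import (
    CombinatorialModel,
    Condition,
    GeneRateParams,
    GeneTopology,
    InhibitorMap,
    SignalParams,
    effective_rates,
)

__all__ = [
    "StateSpace",
    "FSPSolution",
    "FSPTruncationError",
    "build_generator",
    "fsp_solve",
    "solve_gene",
    "stationary_distribution",
    "marginal_mrna",
    "state_occupancy",
    "mean_transcription_rate",
    "moments",
]

_MODE_CODE = {"enhance": _integrate.MODE_ENHANCE}
_SUPPRESS_CODE = {"saturating": _integrate.MODE_SUPPRESS_SAT,
                  "linear": _integrate.MODE_SUPPRESS_LIN}


class FSPTruncationError(RuntimeError):
    """State-space ceiling reached with sink mass above tolerance."""

    def __init__(self, achieved: float, tol: float, max_count: int):
        self.achieved = achieved
        self.tol = tol
        self.max_count = max_count
        super().__init__(
            f"FSP truncation failure: sink mass {achieved:.3e} > tol {tol:.3e} "
            f"at max_count={max_count}"
        )


@dataclass(frozen=True)
class StateSpace:
    """Truncated lattice of (gene state, mRNA copy number 0..max_count)."""

    n_states: int
    max_count: int

    def __post_init__(self) -> None:
        if self.max_count < 1:
            raise ValueError("max_count must be >= 1")

    @property
    def dim(self) -> int:
        return self.n_states * (self.max_count + 1)

    def index(self, state: int, count: int) -> int:
        return state * (self.max_count + 1) + count


def build_generator(topology: GeneTopology, rates: dict, space: StateSpace,
                    *, reflecting: bool = False) -> sp.csr_matrix:
    """Transition-rate matrix A on the truncated space (columns sum <= 0).

    ``rates`` is a frozen rate map as produced by
    :func:`fspburst.models.effective_rates`.  Column deficits equal the
    transcription flux leaving the max_count boundary; with
    ``reflecting=True`` that flux is switched off instead (columns sum
    to 0), which is the convention used for stationary solves.
    """
    edges = rates["edges"]
    alpha = rates["alpha"]
    delta = rates["delta"]
    for q in list(edges.values()) + list(alpha.values()) + [delta]:
        if not np.isfinite(q) or q < 0:
            raise ValueError("all rates must be finite and >= 0")
    M = space.max_count
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    diag = np.zeros(space.dim)

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for g in range(space.n_states):
        a = alpha[g]
        for x in range(M + 1):
            j = space.index(g, x)
            for (gi, gj), q in edges.items():
                if gi == g and q:
                    add(space.index(gj, x), j, q)
                    diag[j] -= q
            if a:
                if x < M:
                    add(space.index(g, x + 1), j, a)
                    diag[j] -= a
                elif not reflecting:
                    diag[j] -= a  # flux into the truncation sink
            if x > 0 and delta:
                add(space.index(g, x - 1), j, delta * x)
                diag[j] -= delta * x
    for j in range(space.dim):
        add(j, j, diag[j])
    return sp.coo_matrix((vals, (rows, cols)), shape=(space.dim, space.dim)).tocsr()


def _split_generators(topology: GeneTopology, params: GeneRateParams,
                      space: StateSpace) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Sink-augmented (A0, E): A(t) = A0 + g(t) * E on dim+1 states.

    ``params`` must already carry the condition substitutions.  A0 holds
    every reaction except the signal edge, plus the sink row; E is the
    signal edge at unit rate.
    """
    M = space.max_count
    n = space.dim
    sink = n
    rates = {
        "edges": {e: params.k[e] for e in topology.edges if e != topology.signal_edge},
        "alpha": {i: params.alpha[i] for i in range(topology.n_states)},
        "delta": params.delta,
    }
    A = build_generator(topology, {**rates, "edges": dict(rates["edges"])}, space)
    A = sp.lil_matrix(sp.vstack(
        [sp.hstack([A, sp.csr_matrix((n, 1))]),
         sp.csr_matrix((1, n + 1))]))
    # sink row: transcription flux out of the top bin
    for g in range(space.n_states):
        a = params.alpha[g]
        if a:
            A[sink, space.index(g, M)] = a
    A0 = sp.csr_matrix(A)

    gi, gj = topology.signal_edge
    rows, cols, vals = [], [], []
    for x in range(M + 1):
        j = space.index(gi, x)
        rows.extend([space.index(gj, x), j])
        cols.extend([j, j])
        vals.extend([1.0, -1.0])
    E = sp.coo_matrix((vals, (rows, cols)), shape=(n + 1, n + 1)).tocsr()
    return A0, E


@dataclass
class FSPSolution:
    """Time-indexed probability over (gene state, mRNA count) plus sink mass."""

    times: np.ndarray                    # (T,) seconds
    prob: np.ndarray                     # (T, n_states, max_count+1)
    sink_mass: np.ndarray                # (T,)
    space: StateSpace
    alpha: tuple[float, ...]             # transcription rates used (per state)
    tol: float
    expansions: int = 0

    def diagnostics(self) -> dict:
        return {
            "dimension": self.space.dim,
            "max_count": self.space.max_count,
            "expansions": self.expansions,
            "tolerance": self.tol,
            "final_sink_mass": float(self.sink_mass[-1]),
        }

    def to_tsv(self, path) -> None:
        """Write (time_s, state_or_count, probability) rows for marginals."""
        occ = state_occupancy(self)
        marg = marginal_mrna(self)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("time_s\tstate_or_count\tprobability\n")
            for ti, t in enumerate(self.times):
                for g in range(self.space.n_states):
                    fh.write(f"{t:g}\tG{g}\t{occ[ti, g]:.10g}\n")
                for x in range(self.space.max_count + 1):
                    fh.write(f"{t:g}\t{x}\t{marg[ti, x]:.10g}\n")

    def diagnostics_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.diagnostics(), fh, indent=2)


def stationary_distribution(
    topology: GeneTopology,
    params: GeneRateParams,
    inhibitor_map: InhibitorMap | None = None,
    condition: Condition | str = Condition.NONE,
    space: StateSpace | None = None,
    *,
    max_count: int = 1500,
) -> np.ndarray:
    """Stationary law of the signal-free (s=0) system, condition constants applied.

    Solves A p = 0 on the reflecting truncated space and normalizes.
    Used as the initial condition at t=0: unstimulated cells have
    equilibrated under the (possibly inhibitor-substituted) basal rates.
    """
    inhibitor_map = inhibitor_map or InhibitorMap()
    if space is None:
        space = StateSpace(topology.n_states, max_count)
    eff = inhibitor_map.apply(params, condition)
    eff.validate_for(topology)
    if all(v == 0 for v in eff.k.values()) and all(a == 0 for a in eff.alpha):
        raise ValueError("degenerate chain: all rates are zero")
    rates = {
        "edges": {e: eff.k[e] for e in topology.edges},
        "alpha": {i: eff.alpha[i] for i in range(topology.n_states)},
        "delta": eff.delta,
    }
    # s(0) = 0, so the signal edge sits at its basal (substituted) value
    A = build_generator(topology, rates, space, reflecting=True).tolil()
    rhs = np.zeros(space.dim)
    A[0, :] = 1.0
    rhs[0] = 1.0
    p = spla.spsolve(sp.csc_matrix(A), rhs)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def fsp_solve(
    topology: GeneTopology,
    params: GeneRateParams,
    inhibitor_map: InhibitorMap | None,
    condition: Condition | str,
    sp_signal: SignalParams,
    times,
    *,
    init: np.ndarray | None = None,
    tol: float = 1e-4,
    max_count: int = 1500,
    max_count_ceiling: int = 8192,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    suppress_form: str = "saturating",
) -> FSPSolution:
    """Solve the time-varying CME for one gene under one condition.

    ``times`` must be strictly increasing and start at 0.  By default
    the initial condition is the signal-free stationary distribution
    computed with this condition's substituted constants.  The space is
    doubled and the solve restarted while the final sink mass exceeds
    ``tol``.
    """
    inhibitor_map = inhibitor_map or InhibitorMap()
    condition = Condition.coerce(condition)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    eff = inhibitor_map.apply(params, condition)
    eff.validate_for(topology)
    if topology.signal_mode == "enhance":
        mode = _MODE_CODE["enhance"]
    else:
        mode = _SUPPRESS_CODE[suppress_form]
    k_sig = eff.k[topology.signal_edge]

    if init is not None:
        init = np.asarray(init, dtype=float).ravel()
        if abs(init.sum() - 1.0) > 1e-9:
            raise ValueError("init must sum to 1 within 1e-9")

    expansions = 0
    while True:
        space = StateSpace(topology.n_states, max_count)
        if init is None:
            p0_core = stationary_distribution(
                topology, params, inhibitor_map, condition, space)
        else:
            p0_core = np.zeros(space.dim)
            per = init.size // topology.n_states
            src = init.reshape(topology.n_states, per)
            m = min(per, max_count + 1)
            dst = p0_core.reshape(topology.n_states, max_count + 1)
            dst[:, :m] = src[:, :m]
            p0_core = dst.ravel()
        A0, E = _split_generators(topology, eff, space)
        p0 = np.concatenate([p0_core, [0.0]])
        out, status = _integrate.integrate_linear(
            A0.data, A0.indices, A0.indptr, E.data, E.indices, E.indptr,
            mode, k_sig, eff.b, sp_signal.r1, sp_signal.r2,
            p0, times, rtol, atol)
        if status != 0:
            raise RuntimeError("FSP integrator step size underflow")
        sink = out[:, -1].copy()
        if sink[-1] <= tol:
            prob = out[:, :-1]
            if prob.min() < -1e-7:
                raise RuntimeError(
                    f"FSP produced a significantly negative probability "
                    f"({prob.min():.3e}); tighten rtol/atol")
            prob = np.clip(prob, 0.0, None)
            return FSPSolution(
                times=times,
                prob=prob.reshape(len(times), topology.n_states, max_count + 1),
                sink_mass=np.maximum(sink, 0.0),
                space=space,
                alpha=eff.alpha,
                tol=tol,
                expansions=expansions,
            )
        if max_count >= max_count_ceiling:
            raise FSPTruncationError(float(sink[-1]), tol, max_count)
        max_count = min(2 * max_count, max_count_ceiling)
        expansions += 1


def solve_gene(model: CombinatorialModel, gene: str, condition, times,
               **kwargs) -> FSPSolution:
    """Solve the CME for one gene of a combinatorial model."""
    gm = model.genes[gene]
    return fsp_solve(gm.topology, gm.params, gm.inhibitors, condition,
                     model.signal, times, **kwargs)


def marginal_mrna(sol: FSPSolution) -> np.ndarray:
    """Per-time mRNA copy-number marginal (sums to 1 - sink_mass)."""
    return sol.prob.sum(axis=1)


def state_occupancy(sol: FSPSolution) -> np.ndarray:
    """Per-time gene-state occupancy probabilities."""
    return sol.prob.sum(axis=2)


def mean_transcription_rate(sol: FSPSolution, alpha=None) -> np.ndarray:
    """Per-time mean transcription rate sum_i alpha_i P(G_i) (molecules/s)."""
    a = np.asarray(alpha if alpha is not None else sol.alpha, dtype=float)
    return state_occupancy(sol) @ a


def moments(sol: FSPSolution) -> tuple[np.ndarray, np.ndarray]:
    """Per-time mean and SD of mRNA count, on the renormalized marginal."""
    marg = marginal_mrna(sol)
    x = np.arange(sol.space.max_count + 1, dtype=float)
    tot = marg.sum(axis=1)
    mean = (marg @ x) / tot
    second = (marg @ x**2) / tot
    var = np.maximum(second - mean**2, 0.0)
    return mean, np.sqrt(var)
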