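"""Exact stochastic simulation and synthetic single-cell datasets.

Replicates the smFISH study design in silico: per condition, replicate
and measurement time, an independent batch of cells is drawn by exact
simulation of the time-inhomogeneous Markov chain (thinning against a
closed-form propensity bound), starting from the signal-free stationary
law of that condition.  The two genes are simulated independently given
the shared signal, mirroring the conditional-independence assumption.
Every stochastic operation takes an explicit seed; sub-seeds are derived
deterministically with ``numpy.random.SeedSequence`` so tables are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _integrate, _ssa
from .fsp import StateSpace, stationary_distribution
from .models import (
    CombinatorialModel,
    Condition,
    GeneRateParams,
    GeneTopology,
    InhibitorMap,
    SignalParams,
)

__all__ = [
    "DEFAULT_TIMES",
    "SyntheticDesign",
    "ssa_trajectory",
    "generate_dataset",
    "empirical_distribution",
    "EmptySelectionError",
]

#: Measurement times (seconds) of the study design: 0, 30, 60, 120, 240 min.
DEFAULT_TIMES = (0.0, 1800.0, 3600.0, 7200.0, 14400.0)

COUNT_COLUMNS = ("replicate", "condition", "time_s", "cell_id")


class EmptySelectionError(ValueError):
    """No cells match the requested (gene, condition, time) selection."""


@dataclass(frozen=True)
class SyntheticDesign:
    """Layout of a synthetic smFISH experiment.

    Defaults follow the study design: all four inhibitor conditions,
    five time points (0-240 min), four biological replicates.  The
    per-replicate cell number is the module's own choice (the study
    reports "several hundreds to thousands" of cells per condition).
    """

    seed: int
    conditions: tuple = tuple(Condition)
    times: tuple = DEFAULT_TIMES
    replicates: int = 4
    cells_per_replicate: int = 500

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "conditions", tuple(Condition.coerce(c) for c in self.conditions)
        )
        t = tuple(float(x) for x in self.times)
        if sorted(t) != list(t) or len(set(t)) != len(t) or (t and t[0] != 0.0):
            raise ValueError("times must be sorted, unique, starting at 0")
        object.__setattr__(self, "times", t)
        if self.replicates < 1 or self.cells_per_replicate < 1:
            raise ValueError("replicates and cells_per_replicate must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory for synthetic data generation")


def _mode_code(topology: GeneTopology, suppress_form: str) -> int:
    if topology.signal_mode == "enhance":
        return _integrate.MODE_ENHANCE
    return (_integrate.MODE_SUPPRESS_SAT if suppress_form == "saturating"
            else _integrate.MODE_SUPPRESS_LIN)


def _kernel_args(topology: GeneTopology, eff: GeneRateParams):
    """Basal up/down rate arrays with the signal edge zeroed out."""
    n = topology.n_states
    ku = np.zeros(n)
    kd = np.zeros(n)
    for (i, j), q in eff.k.items():
        if (i, j) == topology.signal_edge:
            continue
        if j == i + 1:
            ku[i] = q
        else:
            kd[i] = q
    return ku, kd


def _sample_initial(topology, params, inhibitor_map, condition, rng,
                    n_cells, init_max_count):
    pi = stationary_distribution(topology, params, inhibitor_map, condition,
                                 max_count=init_max_count)
    idx = rng.choice(pi.size, size=n_cells, p=pi)
    per = init_max_count + 1
    return (idx // per).astype(np.int64), (idx % per).astype(np.int64)


def ssa_trajectory(
    topology: GeneTopology,
    params: GeneRateParams,
    inhibitor_map: InhibitorMap | None,
    condition: Condition | str,
    sp: SignalParams,
    t_grid,
    seed: int,
    *,
    n_cells: int = 1,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    init_max_count: int = 1500,
    suppress_form: str = "saturating",
) -> tuple[np.ndarray, np.ndarray]:
    """Exact trajectories of (gene state, mRNA count) at grid times.

    Returns ``(states, counts)`` of shape ``(n_cells, len(t_grid))``.
    When ``init`` is None the initial states are drawn from the
    signal-free stationary distribution of the given condition (the same
    initial law the FSP solver uses).
    """
    inhibitor_map = inhibitor_map or InhibitorMap()
    condition = Condition.coerce(condition)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be sorted")
    eff = inhibitor_map.apply(params, condition)
    eff.validate_for(topology)
    ss = np.random.SeedSequence(seed)
    if init is None:
        rng = np.random.default_rng(ss.spawn(1)[0])
        g0, x0 = _sample_initial(topology, params, inhibitor_map, condition,
                                 rng, n_cells, init_max_count)
    else:
        g0 = np.asarray(init[0], dtype=np.int64)
        x0 = np.asarray(init[1], dtype=np.int64)
    ku, kd = _kernel_args(topology, eff)
    kernel_seed = int(ss.generate_state(1, dtype=np.uint32)[0])
    return _ssa.ssa_batch(
        kernel_seed, g0, x0, topology.n_states, ku, kd,
        topology.signal_edge[0], topology.signal_edge[1],
        _mode_code(topology, suppress_form),
        eff.k[topology.signal_edge], eff.b, sp.r1, sp.r2,
        np.asarray(eff.alpha), eff.delta, t_grid)


def generate_dataset(
    design: SyntheticDesign,
    model: CombinatorialModel,
    *,
    init_max_count: int = 1500,
    suppress_form: str = "saturating",
) -> pd.DataFrame:
    """Synthetic count table replicating the study design.

    One row per cell with ``replicate, condition, time_s, cell_id`` and a
    ``<gene>_count`` column per model gene.  Cells at distinct
    measurement times are independent (smFISH is destructive).
    Deterministic given ``design.seed``.
    """
    rows: dict[str, list] = {c: [] for c in COUNT_COLUMNS}
    gene_counts: dict[str, list] = {f"{g}_count": [] for g in model.gene_names}
    root = np.random.SeedSequence(design.seed)
    for ci, condition in enumerate(design.conditions):
        for rep in range(design.replicates):
            for ti, t in enumerate(design.times):
                n = design.cells_per_replicate
                rows["replicate"].extend([rep] * n)
                rows["condition"].extend([condition.value] * n)
                rows["time_s"].extend([t] * n)
                rows["cell_id"].extend(range(n))
                for gi, gname in enumerate(model.gene_names):
                    gm = model.genes[gname]
                    sub = np.random.SeedSequence(
                        entropy=design.seed, spawn_key=(ci, rep, ti, gi))
                    seed = int(sub.generate_state(1, dtype=np.uint32)[0])
                    _, counts = ssa_trajectory(
                        gm.topology, gm.params, gm.inhibitors, condition,
                        model.signal, np.array([t]), seed, n_cells=n,
                        init_max_count=init_max_count,
                        suppress_form=suppress_form)
                    gene_counts[f"{gname}_count"].extend(counts[:, 0].tolist())
    table = pd.DataFrame({**rows, **gene_counts})
    table["replicate"] = table["replicate"].astype(int)
    table["cell_id"] = table["cell_id"].astype(int)
    return table


def empirical_distribution(
    table: pd.DataFrame,
    gene: str,
    condition: Condition | str,
    time_s: float,
    max_count: int,
) -> tuple[np.ndarray, int]:
    """Normalized count histogram over 0..max_count, with top-bin censoring.

    Counts above ``max_count`` accumulate in the top bin.  Returns the
    probability vector and the number of cells used.
    """
    condition = Condition.coerce(condition)
    col = f"{gene}_count"
    if col not in table.columns:
        raise KeyError(f"table has no column {col!r}")
    sel = table[(table["condition"] == condition.value)
                & (np.isclose(table["time_s"].to_numpy(dtype=float), float(time_s)))]
    if sel.empty:
        raise EmptySelectionError(
            f"no cells for gene={gene}, condition={condition.value}, time_s={time_s}")
    counts = np.minimum(sel[col].to_numpy(dtype=int), max_count)
    hist = np.bincount(counts, minlength=max_count + 1).astype(float)
    n = int(hist.sum())
    return hist / n, n
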