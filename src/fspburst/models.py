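"""Signal-activated multi-state bursting gene models.

A gene switches among 2 or 3 discrete activity states arranged as a
birth-death chain (G0 <-> G1 <-> G2), transcribes mRNA at a
state-dependent rate alpha_i, and degrades mRNA with first-order rate
constant delta.  Exactly one switching edge is modulated by a shared,
time-varying nuclear NF-kB signal

    s(t) = exp(-r1 * t) * (1 - exp(-r2 * t)),

either additively (``enhance``: k -> k + b*s(t)) or by repression
(``suppress``: k -> k / (1 + b*s(t)) by default).  Small-molecule
inhibitor conditions are modelled as parameter substitutions: MG132
replaces the signal coefficient b by a reduced value, U0126 replaces the
basal activation rate k01.  Two genes (IL-1beta, TNF-alpha) are
conditionally independent given the shared signal, so a combinatorial
two-gene model is a pair of single-gene models sharing one
:class:`SignalParams`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Condition",
    "TRAINING_CONDITIONS",
    "TEST_CONDITION",
    "ConfigurationError",
    "SignalParams",
    "GeneTopology",
    "GeneRateParams",
    "InhibitorMap",
    "GeneModel",
    "CombinatorialModel",
    "nfkb_signal",
    "effective_rates",
    "signal_edge_rate",
    "enumerate_single_gene_topologies",
    "enumerate_combinatorial_models",
    "topology_by_name",
    "load_model",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent model/inhibitor configuration."""


class Condition(str, Enum):
    """Inhibitor treatment condition."""

    NONE = "none"
    MG132 = "mg132"
    U0126 = "u0126"
    BOTH = "both"

    @classmethod
    def coerce(cls, value: "Condition | str") -> "Condition":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ConfigurationError(f"unknown condition {value!r}") from exc

    @property
    def has_mg132(self) -> bool:
        return self in (Condition.MG132, Condition.BOTH)

    @property
    def has_u0126(self) -> bool:
        return self in (Condition.U0126, Condition.BOTH)


#: Conditions used to calibrate parameters.
TRAINING_CONDITIONS = (Condition.NONE, Condition.MG132, Condition.U0126)
#: Held-out condition used only to test predictions.
TEST_CONDITION = Condition.BOTH


@dataclass(frozen=True)
class SignalParams:
    """Phenomenological nuclear NF-kB signal e^{-r1 t}(1 - e^{-r2 t}).

    Parameters
    ----------
    r1 : float
        Decay rate of the signal (s^-1).
    r2 : float
        Rise rate of the signal (s^-1).
    """

    r1: float
    r2: float

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.r2 > 0):
            raise ConfigurationError("signal rates r1, r2 must be positive")

    def value(self, t):
        """Signal amplitude at time(s) ``t`` (seconds, arbitrary units)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = np.exp(-self.r1 * t) * (-np.expm1(-self.r2 * t))
        return float(out) if out.ndim == 0 else out

    __call__ = value

    @property
    def peak_time(self) -> float:
        """Analytic maximiser ln(1 + r2/r1)/r2 of the signal (seconds)."""
        return math.log1p(self.r2 / self.r1) / self.r2

    @property
    def peak_value(self) -> float:
        return float(self.value(self.peak_time))


def nfkb_signal(t, sp: SignalParams):
    """Evaluate the nuclear NF-kB signal e^{-r1 t}(1 - e^{-r2 t}) at ``t`` seconds."""
    return sp.value(t)


def _edge_name(edge: tuple[int, int]) -> str:
    return f"k{edge[0]}{edge[1]}"


_SIGNAL_MODES = ("enhance", "suppress")


@dataclass(frozen=True)
class GeneTopology:
    """A birth-death chain of gene states with one signal-modulated edge.

    ``signal_mode='enhance'`` means the signal adds to the edge rate;
    ``'suppress'`` means it represses the edge rate.
    """

    n_states: int
    signal_edge: tuple[int, int]
    signal_mode: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_states not in (2, 3):
            raise ConfigurationError("n_states must be 2 or 3")
        i, j = self.signal_edge
        if abs(i - j) != 1 or not (0 <= i < self.n_states and 0 <= j < self.n_states):
            raise ConfigurationError("signal_edge must connect adjacent gene states")
        if self.signal_mode not in _SIGNAL_MODES:
            raise ConfigurationError(f"signal_mode must be one of {_SIGNAL_MODES}")
        if not self.name:
            mode = "act" if self.signal_mode == "enhance" else "rep"
            object.__setattr__(
                self, "name", f"{self.n_states}S-{mode}{self.signal_edge[0]}{self.signal_edge[1]}"
            )

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        """All directed switching edges of the chain (both directions)."""
        out = []
        for i in range(self.n_states - 1):
            out.append((i, i + 1))
            out.append((i + 1, i))
        return tuple(out)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(f"G{i}" for i in range(self.n_states))


def enumerate_single_gene_topologies() -> list[GeneTopology]:
    """The six candidate single-gene mechanisms.

    Two 2-state variants (signal enhances G0->G1 or suppresses G1->G0)
    and four 3-state variants (signal enhances G0->G1 or G1->G2, or
    suppresses G1->G0 or G2->G1).  Each has exactly one signal edge.
    """
    tops = [
        GeneTopology(2, (0, 1), "enhance"),
        GeneTopology(2, (1, 0), "suppress"),
        GeneTopology(3, (0, 1), "enhance"),
        GeneTopology(3, (1, 2), "enhance"),
        GeneTopology(3, (1, 0), "suppress"),
        GeneTopology(3, (2, 1), "suppress"),
    ]
    return tops


def topology_by_name(name: str) -> GeneTopology:
    for top in enumerate_single_gene_topologies():
        if top.name == name:
            return top
    raise ConfigurationError(f"unknown topology name {name!r}")


@dataclass(frozen=True)
class GeneRateParams:
    """Kinetic constants of one gene.

    Parameters
    ----------
    k : mapping (i, j) -> float
        Basal switching rates (s^-1) for every edge of the topology.
    b : float
        Signal coefficient of the signal edge (s^-1 in enhance mode,
        dimensionless repression strength in suppress mode).
    alpha : tuple of float
        Transcription rate (molecules s^-1) per gene state.
    delta : float
        First-order mRNA degradation rate constant (s^-1).
    """

    k: Mapping[tuple[int, int], float]
    b: float
    alpha: tuple[float, ...]
    delta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", dict(self.k))
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        for edge, rate in self.k.items():
            if rate < 0:
                raise ConfigurationError(f"negative rate for edge {_edge_name(edge)}")
        if self.b < 0:
            raise ConfigurationError("signal coefficient b must be >= 0")
        if any(a < 0 for a in self.alpha):
            raise ConfigurationError("transcription rates must be >= 0")
        if not self.delta > 0:
            raise ConfigurationError("degradation rate delta must be positive")

    def validate_for(self, topology: GeneTopology) -> None:
        missing = set(topology.edges) - set(self.k)
        if missing:
            raise ConfigurationError(
                f"missing basal rates for edges {[ _edge_name(e) for e in sorted(missing)]}"
            )
        if len(self.alpha) != topology.n_states:
            raise ConfigurationError("alpha must have one entry per gene state")


@dataclass(frozen=True)
class InhibitorMap:
    """Parameter substitutions applied under each inhibitor.

    MG132 substitutes the signal coefficient (key ``"b"``); U0126
    substitutes a basal switching rate (key ``"k01"``).  The ``both``
    condition applies both sets; the substitution sets are disjoint, so
    order is irrelevant.
    """

    mg132: Mapping[str, float] = field(default_factory=dict)
    u0126: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mg132", dict(self.mg132))
        object.__setattr__(self, "u0126", dict(self.u0126))
        for sub in (self.mg132, self.u0126):
            for key, val in sub.items():
                if key != "b" and not (key.startswith("k") and len(key) == 3):
                    raise ConfigurationError(f"unknown substitution key {key!r}")
                if val < 0:
                    raise ConfigurationError(f"negative substitution value for {key!r}")

    def substitutions(self, condition: Condition | str) -> dict[str, float]:
        condition = Condition.coerce(condition)
        subs: dict[str, float] = {}
        if condition.has_mg132:
            if not self.mg132:
                raise ConfigurationError(
                    f"condition {condition.value!r} requested but no MG132 "
                    "substitution values are configured")
            subs.update(self.mg132)
        if condition.has_u0126:
            if not self.u0126:
                raise ConfigurationError(
                    f"condition {condition.value!r} requested but no U0126 "
                    "substitution values are configured")
            subs.update(self.u0126)
        return subs

    def apply(self, params: GeneRateParams, condition: Condition | str) -> GeneRateParams:
        """Return ``params`` with this condition's substitutions in place."""
        subs = self.substitutions(condition)
        if not subs:
            return params
        k = dict(params.k)
        b = params.b
        for key, val in subs.items():
            if key == "b":
                b = val
            else:
                edge = (int(key[1]), int(key[2]))
                if edge not in k:
                    raise ConfigurationError(
                        f"substitution {key!r} targets an edge absent from the topology"
                    )
                k[edge] = val
        return replace(params, k=k, b=b)


def signal_edge_rate(
    topology: GeneTopology,
    params: GeneRateParams,
    sp: SignalParams,
    t,
    suppress_form: str = "saturating",
):
    """Instantaneous rate of the signal-modulated edge at time ``t``.

    ``params`` must already carry any condition substitutions.  In
    enhance mode the rate is ``k + b*s(t)``; in suppress mode it is
    ``k / (1 + b*s(t))`` (``suppress_form='saturating'``, always
    positive) or ``k * max(0, 1 - b*s(t))`` (``'linear'``).
    """
    k = params.k[topology.signal_edge]
    s = sp.value(t)
    if topology.signal_mode == "enhance":
        return k + params.b * s
    if suppress_form == "saturating":
        return k / (1.0 + params.b * s)
    if suppress_form == "linear":
        return k * np.maximum(0.0, 1.0 - params.b * s)
    raise ConfigurationError(f"unknown suppress_form {suppress_form!r}")


def effective_rates(
    topology: GeneTopology,
    params: GeneRateParams,
    inhibitor_map: InhibitorMap,
    condition: Condition | str,
    sp: SignalParams,
    t: float,
    suppress_form: str = "saturating",
) -> dict:
    """Instantaneous edge and transcription rates under a condition.

    Returns ``{"edges": {(i, j): rate}, "alpha": {state: rate},
    "delta": rate}``.  Non-signal edges keep their (possibly
    substituted) basal rates; the signal edge is evaluated at s(t).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    params.validate_for(topology)
    eff = inhibitor_map.apply(params, condition)
    edges = {edge: eff.k[edge] for edge in topology.edges}
    edges[topology.signal_edge] = float(
        signal_edge_rate(topology, eff, sp, t, suppress_form)
    )
    return {
        "edges": edges,
        "alpha": {i: eff.alpha[i] for i in range(topology.n_states)},
        "delta": eff.delta,
    }


@dataclass(frozen=True)
class GeneModel:
    """One gene's topology, kinetic constants and inhibitor substitutions."""

    topology: GeneTopology
    params: GeneRateParams
    inhibitors: InhibitorMap = field(default_factory=InhibitorMap)

    def __post_init__(self) -> None:
        self.params.validate_for(self.topology)

    def condition_params(self, condition: Condition | str) -> GeneRateParams:
        return self.inhibitors.apply(self.params, condition)


@dataclass(frozen=True)
class CombinatorialModel:
    """A multi-gene model: conditionally independent genes, shared signal."""

    name: str
    signal: SignalParams
    genes: Mapping[str, GeneModel]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", dict(self.genes))
        if not self.genes:
            raise ConfigurationError("a combinatorial model needs at least one gene")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(self.genes)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {
            "name": self.name,
            "signal": {"r1": self.signal.r1, "r2": self.signal.r2},
            "genes": {},
        }
        for gname, gm in self.genes.items():
            gd: dict = {"topology": gm.topology.name}
            for edge in gm.topology.edges:
                gd[_edge_name(edge)] = gm.params.k[edge]
            gd["b"] = gm.params.b
            for i, a in enumerate(gm.params.alpha):
                gd[f"alpha{i}"] = a
            gd["delta"] = gm.params.delta
            gd["inhibitors"] = {
                "mg132": dict(gm.inhibitors.mg132),
                "u0126": dict(gm.inhibitors.u0126),
            }
            out["genes"][gname] = gd
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "CombinatorialModel":
        try:
            signal = SignalParams(float(data["signal"]["r1"]), float(data["signal"]["r2"]))
            genes: dict[str, GeneModel] = {}
            for gname, gd in data["genes"].items():
                top = topology_by_name(gd["topology"])
                k = {e: float(gd[_edge_name(e)]) for e in top.edges}
                alpha = tuple(float(gd[f"alpha{i}"]) for i in range(top.n_states))
                inh = gd.get("inhibitors", {})
                genes[gname] = GeneModel(
                    topology=top,
                    params=GeneRateParams(k=k, b=float(gd.get("b", 0.0)),
                                          alpha=alpha, delta=float(gd["delta"])),
                    inhibitors=InhibitorMap(
                        mg132={k_: float(v) for k_, v in inh.get("mg132", {}).items()},
                        u0126={k_: float(v) for k_, v in inh.get("u0126", {}).items()},
                    ),
                )
        except KeyError as exc:
            raise ConfigurationError(f"model config missing key: {exc}") from exc
        return cls(name=str(data.get("name", "model")), signal=signal, genes=genes)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CombinatorialModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def enumerate_combinatorial_models(
    genes: Mapping[str, Sequence[GeneModel]],
    signal: SignalParams,
    prefix: str = "CM",
) -> list[CombinatorialModel]:
    """Cartesian product of per-gene candidate mechanisms.

    With 3 candidates per gene for two genes this yields the 9
    combinatorial models of the default screen; with all 6 per gene, 36.
    Names are deterministic: ``<prefix>-<topo1>-<topo2>-...``.
    """
    names = list(genes)
    for gname in names:
        if not genes[gname]:
            raise ConfigurationError(f"no candidate topologies supplied for gene {gname!r}")
    out = []
    for combo in itertools.product(*(genes[g] for g in names)):
        label = prefix + "-" + "-".join(gm.topology.name for gm in combo)
        out.append(
            CombinatorialModel(name=label, signal=signal, genes=dict(zip(names, combo)))
        )
    return out


def load_model(name: str) -> CombinatorialModel:
    """Load a packaged model config (``"cm1"`` or ``"cm2"``) or a YAML path."""
    key = name.lower()
    if key in ("cm1", "cm2"):
        ref = resources.files("fspburst.data").joinpath(f"{key}.yaml")
        return CombinatorialModel.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))
    return CombinatorialModel.from_yaml(name)
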