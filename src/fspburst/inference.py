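"""Maximum-likelihood fitting of bursting models to count tables.

The objective is the multinomial log-likelihood of the observed per-gene
marginal count histograms under the FSP-predicted distributions, summed
over genes, conditions and time points with each sample weighted by its
cell count.  Up to a data-only entropy constant this equals minus the
weighted sum of Kullback-Leibler divergences from the empirical to the
model distributions, so minimising the weighted KL sum and maximising
the likelihood are the same fit.

Optimisation is multistart local search over log10-transformed free
parameters within bounds.  The primary entry point is the
scikit-learn-style :class:`BurstModelEstimator`; :func:`fit_model` and
:func:`dataset_loglik` are thin functional wrappers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import fsp
from .models import (
    CombinatorialModel,
    Condition,
    ConfigurationError,
    GeneModel,
    GeneRateParams,
    InhibitorMap,
    SignalParams,
    TRAINING_CONDITIONS,
)
from .simulate import empirical_distribution

__all__ = [
    "MODEL_FLOOR",
    "kl_divergence",
    "dataset_loglik",
    "fit_model",
    "FitResult",
    "BurstModelEstimator",
    "free_parameter_names",
    "get_parameter",
    "with_parameters",
]

#: Probability floor applied to model distributions before taking logs,
#: keeping the objective finite when an observed count falls where the
#: model assigns essentially zero mass.
MODEL_FLOOR = 1e-12


def kl_divergence(p_emp, q_model, eps: float = MODEL_FLOOR) -> float:
    """Kullback-Leibler divergence sum p ln(p/q) in nats.

    ``q_model`` is floored at ``eps`` before the ratio; terms with
    p(x) = 0 contribute zero.
    """
    p = np.asarray(p_emp, dtype=float)
    q = np.asarray(q_model, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p_emp and q_model must have the same length")
    q = np.maximum(q, eps)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


# ---------------------------------------------------------------------------
# free-parameter plumbing

def _gene_param_names(gname: str, gm: GeneModel) -> list[str]:
    names = [f"{gname}.{f'k{i}{j}'}" for (i, j) in gm.topology.edges]
    names.append(f"{gname}.b")
    names += [f"{gname}.alpha{i}" for i in range(gm.topology.n_states)]
    names.append(f"{gname}.delta")
    names += [f"{gname}.mg132.{k}" for k in gm.inhibitors.mg132]
    names += [f"{gname}.u0126.{k}" for k in gm.inhibitors.u0126]
    return names


def free_parameter_names(model: CombinatorialModel) -> list[str]:
    """Every free parameter of a model: shared signal rates, then per-gene
    switching rates, signal coefficient, transcription rates, degradation
    rate and inhibitor substitution values."""
    names = ["r1", "r2"]
    for gname, gm in model.genes.items():
        names += _gene_param_names(gname, gm)
    return names


def get_parameter(model: CombinatorialModel, name: str) -> float:
    if name == "r1":
        return model.signal.r1
    if name == "r2":
        return model.signal.r2
    gname, _, rest = name.partition(".")
    gm = model.genes[gname]
    if rest.startswith("mg132."):
        return gm.inhibitors.mg132[rest[6:]]
    if rest.startswith("u0126."):
        return gm.inhibitors.u0126[rest[6:]]
    if rest == "b":
        return gm.params.b
    if rest == "delta":
        return gm.params.delta
    if rest.startswith("alpha"):
        return gm.params.alpha[int(rest[5:])]
    if rest.startswith("k"):
        return gm.params.k[(int(rest[1]), int(rest[2]))]
    raise ConfigurationError(f"unknown parameter name {name!r}")


def with_parameters(model: CombinatorialModel, values: dict[str, float]) -> CombinatorialModel:
    """Return a copy of ``model`` with the named parameters replaced."""
    r1 = values.get("r1", model.signal.r1)
    r2 = values.get("r2", model.signal.r2)
    genes = {}
    for gname, gm in model.genes.items():
        k = dict(gm.params.k)
        b = gm.params.b
        alpha = list(gm.params.alpha)
        delta = gm.params.delta
        mg = dict(gm.inhibitors.mg132)
        u0 = dict(gm.inhibitors.u0126)
        prefix = gname + "."
        for name, val in values.items():
            if not name.startswith(prefix):
                continue
            rest = name[len(prefix):]
            if rest.startswith("mg132."):
                mg[rest[6:]] = val
            elif rest.startswith("u0126."):
                u0[rest[6:]] = val
            elif rest == "b":
                b = val
            elif rest == "delta":
                delta = val
            elif rest.startswith("alpha"):
                alpha[int(rest[5:])] = val
            elif rest.startswith("k"):
                k[(int(rest[1]), int(rest[2]))] = val
            else:
                raise ConfigurationError(f"unknown parameter name {name!r}")
        genes[gname] = GeneModel(
            topology=gm.topology,
            params=GeneRateParams(k=k, b=b, alpha=tuple(alpha), delta=delta),
            inhibitors=InhibitorMap(mg132=mg, u0126=u0),
        )
    return CombinatorialModel(name=model.name, signal=SignalParams(r1, r2), genes=genes)


# ---------------------------------------------------------------------------
# likelihood

class _PreparedData:
    """Count histograms pre-aggregated per (gene, condition, time).

    Avoids re-selecting the table on every objective evaluation; the
    histograms are censored to the FSP truncation at evaluation time, so
    the result is identical to :func:`dataset_loglik` on the raw table.
    """

    def __init__(self, table: pd.DataFrame, genes, conditions):
        self.items = []  # (gene, condition, data_times, solve_times, hists, ns)
        for condition in conditions:
            sub = table[table["condition"] == condition.value]
            if sub.empty:
                raise ValueError(f"table has no cells for condition {condition.value!r}")
            data_times = np.sort(sub["time_s"].unique().astype(float))
            solve_times = data_times if data_times[0] == 0 else np.r_[0.0, data_times]
            for gname in genes:
                hists, ns = [], []
                for t in data_times:
                    counts = sub.loc[np.isclose(sub["time_s"], t),
                                     f"{gname}_count"].to_numpy(dtype=int)
                    hists.append(np.bincount(counts).astype(float))
                    ns.append(len(counts))
                self.items.append((gname, condition, data_times, solve_times,
                                   hists, ns))

    def loglik(self, model: CombinatorialModel, **solve_kwargs) -> float:
        total = 0.0
        for gname, condition, data_times, solve_times, hists, ns in self.items:
            sol = fsp.solve_gene(model, gname, condition, solve_times, **solve_kwargs)
            marg = fsp.marginal_mrna(sol)
            M = sol.space.max_count
            for j, t in enumerate(data_times):
                ti = int(np.searchsorted(solve_times, t))
                q = marg[ti].copy()
                q[-1] += sol.sink_mass[ti]
                q = np.maximum(q, MODEL_FLOOR)
                h = hists[j]
                if h.size > M + 1:
                    h = np.r_[h[:M], h[M:].sum()]
                mask = h > 0
                total += float(np.sum(h[mask] * np.log(q[:h.size][mask])))
        return total


def _table_genes(table: pd.DataFrame, model: CombinatorialModel) -> list[str]:
    genes = [g for g in model.gene_names if f"{g}_count" in table.columns]
    if not genes:
        raise ValueError("table has no count column matching any model gene")
    return genes


def dataset_loglik(
    table: pd.DataFrame,
    model: CombinatorialModel,
    conditions=TRAINING_CONDITIONS,
    *,
    max_count: int = 1500,
    fsp_tol: float = 1e-4,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    suppress_form: str = "saturating",
) -> float:
    """Total log-likelihood (nats) of the count table under the model.

    Sums n_cells * sum_x phat(x) ln q(x) over genes, conditions and time
    points; the CME is solved once per (gene, condition) across all
    times.  Counts above the FSP truncation are censored into the top
    bin on both the empirical and the model side, and the model's sink
    mass is assigned to that bin for consistency.
    """
    conditions = [Condition.coerce(c) for c in conditions]
    genes = _table_genes(table, model)
    total = 0.0
    for condition in conditions:
        sub = table[table["condition"] == condition.value]
        if sub.empty:
            raise ValueError(f"table has no cells for condition {condition.value!r}")
        data_times = np.sort(sub["time_s"].unique().astype(float))
        solve_times = data_times if data_times[0] == 0 else np.r_[0.0, data_times]
        for gname in genes:
            sol = fsp.solve_gene(model, gname, condition, solve_times,
                                 tol=fsp_tol, max_count=max_count,
                                 rtol=rtol, atol=atol,
                                 suppress_form=suppress_form)
            marg = fsp.marginal_mrna(sol)
            M = sol.space.max_count
            for t in data_times:
                ti = int(np.searchsorted(solve_times, t))
                q = marg[ti].copy()
                q[-1] += sol.sink_mass[ti]
                q = np.maximum(q, MODEL_FLOOR)
                p_emp, n = empirical_distribution(sub, gname, condition, t, M)
                mask = p_emp > 0
                total += n * float(np.sum(p_emp[mask] * np.log(q[mask])))
    return total


@dataclass
class FitResult:
    """Estimated model, its training likelihood and optimizer metadata."""

    model: CombinatorialModel
    loglik: float
    n_params: int
    n_obs: int
    free_params: list
    seed: int
    n_starts: int
    trace: list

    def to_json(self, path) -> None:
        payload = {
            "model": self.model.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "free_params": list(self.free_params),
            "optimizer": {"seed": self.seed, "n_starts": self.n_starts,
                          "starts": self.trace},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            model=CombinatorialModel.from_dict(d["model"]),
            loglik=d["loglik"], n_params=d["n_params"], n_obs=d["n_obs"],
            free_params=d["free_params"], seed=d["optimizer"]["seed"],
            n_starts=d["optimizer"]["n_starts"], trace=d["optimizer"]["starts"],
        )


class BurstModelEstimator(BaseEstimator):
    """Fit a signal-activated bursting model to a single-cell count table.

    scikit-learn-style estimator: ``X`` is a tidy count table (one row
    per cell, columns ``replicate, condition, time_s, cell_id,
    <gene>_count``).  ``fit`` maximises the multinomial log-likelihood
    of the training conditions over log10-transformed free parameters by
    multistart bounded Nelder-Mead; ``score`` evaluates the fitted model
    on any table, e.g. the held-out combined-inhibitor condition.

    Parameters
    ----------
    model : CombinatorialModel
        Template model; its parameter values seed the first start.
    training_conditions : sequence of Condition
        Conditions used for fitting; must not include ``both``.
    free_params : sequence of str, optional
        Subset of :func:`free_parameter_names` to optimise (default all).
    n_starts : int
        Multistart count; starts beyond the first are log-uniform
        perturbations of the template within ``start_spread`` decades.
    bounds : (float, float)
        Lower/upper bounds applied to every free parameter (s^-1).
    """

    def __init__(self, model, training_conditions=TRAINING_CONDITIONS,
                 free_params=None, n_starts=20, random_state=0,
                 start_spread=0.5, bounds=(1e-7, 10.0), maxfev=None,
                 fatol=0.05, xatol=1e-4, max_count=1500, fsp_tol=1e-4,
                 suppress_form="saturating"):
        self.model = model
        self.training_conditions = training_conditions
        self.free_params = free_params
        self.n_starts = n_starts
        self.random_state = random_state
        self.start_spread = start_spread
        self.bounds = bounds
        self.maxfev = maxfev
        self.fatol = fatol
        self.xatol = xatol
        self.max_count = max_count
        self.fsp_tol = fsp_tol
        self.suppress_form = suppress_form

    # ------------------------------------------------------------------
    def _solve_kwargs(self):
        return dict(max_count=self.max_count, tol=self.fsp_tol,
                    suppress_form=self.suppress_form)

    def _loglik(self, table, model, conditions):
        return dataset_loglik(table, model, conditions,
                              max_count=self.max_count, fsp_tol=self.fsp_tol,
                              suppress_form=self.suppress_form)

    def fit(self, X, y=None):
        conditions = [Condition.coerce(c) for c in self.training_conditions]
        if Condition.BOTH in conditions:
            raise ValueError(
                "the combined-inhibitor condition is reserved for testing and "
                "cannot be used for training")
        names = list(self.free_params) if self.free_params else free_parameter_names(self.model)
        lo, hi = np.log10(self.bounds[0]), np.log10(self.bounds[1])
        x0 = np.clip(np.log10([max(get_parameter(self.model, n), self.bounds[0])
                               for n in names]), lo, hi)
        rng = np.random.default_rng(self.random_state)
        prepared = _PreparedData(X, _table_genes(X, self.model), conditions)
        solve_kwargs = self._solve_kwargs()

        def objective(x):
            values = dict(zip(names, 10.0 ** np.asarray(x)))
            try:
                return -prepared.loglik(with_parameters(self.model, values),
                                        **solve_kwargs)
            except fsp.FSPTruncationError:
                return np.inf

        best = None
        trace = []
        for start in range(self.n_starts):
            xs = x0 if start == 0 else np.clip(
                x0 + rng.uniform(-self.start_spread, self.start_spread, len(names)),
                lo, hi)
            res = minimize(
                objective, xs, method="Nelder-Mead",
                bounds=[(lo, hi)] * len(names),
                options={"fatol": self.fatol, "xatol": self.xatol,
                         "maxfev": self.maxfev or 200 * len(names),
                         "adaptive": len(names) > 6},
            )
            trace.append({"start": start, "x0": [float(v) for v in np.round(xs, 6)],
                          "fun": float(res.fun), "nfev": int(res.nfev),
                          "converged": bool(res.success)})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"all optimizer starts failed: {trace}")

        values = dict(zip(names, 10.0 ** best.x))
        self.model_ = with_parameters(self.model, values)
        self.loglik_ = -float(best.fun)
        self.n_params_ = len(names)
        n_obs = 0
        for c in conditions:
            n_obs += int((X["condition"] == c.value).sum()) * len(_table_genes(X, self.model))
        self.n_obs_ = n_obs
        self.result_ = FitResult(
            model=self.model_, loglik=self.loglik_, n_params=self.n_params_,
            n_obs=self.n_obs_, free_params=names, seed=self.random_state,
            n_starts=self.n_starts, trace=trace)
        return self

    def score(self, X, y=None, conditions=None):
        """Log-likelihood of ``X`` under the fitted model (nats)."""
        conds = conditions if conditions is not None else self.training_conditions
        return self._loglik(X, self.model_, [Condition.coerce(c) for c in conds])


def fit_model(model_template: CombinatorialModel, table: pd.DataFrame,
              training_conditions=TRAINING_CONDITIONS, opt_config: dict | None = None,
              ) -> FitResult:
    """Functional wrapper around :class:`BurstModelEstimator`.

    ``opt_config`` keys map to estimator parameters (``n_starts``,
    ``random_state``, ``free_params``, ``bounds``, ``maxfev``,
    ``max_count``, ...).
    """
    est = BurstModelEstimator(model_template, training_conditions,
                              **(opt_config or {}))
    est.fit(table)
    return est.result_
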