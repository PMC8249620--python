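"""Model scoring, ranking, combined-inhibitor prediction and summaries.

Fitted models are compared by training log-likelihood, BIC and the
log-likelihood of the held-out combined-inhibitor condition, which is
predicted with the single-drug-calibrated parameters and *no*
refitting: under ``both``, the MG132 substitution of the signal
coefficient and the U0126 substitution of the basal activation rate are
simply active at the same time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fsp
from .inference import FitResult, dataset_loglik, fit_model, free_parameter_names
from .models import (
    Condition,
    GeneModel,
    GeneRateParams,
    GeneTopology,
    InhibitorMap,
    SignalParams,
    TEST_CONDITION,
    TRAINING_CONDITIONS,
    CombinatorialModel,
    enumerate_combinatorial_models,
    enumerate_single_gene_topologies,
)
from .simulate import DEFAULT_TIMES

__all__ = [
    "ModelScore",
    "PredictionReport",
    "bic",
    "rank_models",
    "predict_combined",
    "summarize",
    "ranking_to_tsv",
]


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian Information Criterion k ln(n) - 2 logL (lower is better)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return n_params * math.log(n_obs) - 2.0 * loglik


@dataclass(frozen=True)
class ModelScore:
    """Fit + held-out prediction scores for one combinatorial model."""

    name: str
    loglik_train: float
    bic: float
    loglik_test: float

    @property
    def combined(self) -> float:
        """Training + held-out log-likelihood; the selection statistic."""
        return self.loglik_train + self.loglik_test


def rank_models(fits, test_table: pd.DataFrame, **loglik_kwargs) -> list[ModelScore]:
    """Rank fitted models by combined (training + held-out) log-likelihood.

    ``fits`` is a sequence of :class:`FitResult`.  The held-out
    log-likelihood is evaluated on the ``both`` condition of
    ``test_table`` with parameters unchanged.  Ties break by lower BIC,
    then by model name; input order is irrelevant.
    """
    if not (test_table["condition"] == TEST_CONDITION.value).any():
        raise ValueError("test table must contain the combined-inhibitor condition")
    scores = []
    for fit in fits:
        ll_test = dataset_loglik(test_table, fit.model, [TEST_CONDITION],
                                 **loglik_kwargs)
        scores.append(ModelScore(
            name=fit.model.name,
            loglik_train=fit.loglik,
            bic=bic(fit.loglik, fit.n_params, fit.n_obs),
            loglik_test=ll_test,
        ))
    return sorted(scores, key=lambda s: (-s.combined, s.bic, s.name))


@dataclass
class PredictionReport:
    """FSP predictions for the combined-inhibitor condition, per gene."""

    model_name: str
    times: tuple
    distributions: dict   # gene -> (T, max_count+1) renormalized marginals
    means: dict           # gene -> (T,)
    sds: dict             # gene -> (T,)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "condition": TEST_CONDITION.value,
            "times_s": list(self.times),
            "genes": {
                g: {"mean": [round(float(v), 10) for v in self.means[g]],
                    "sd": [round(float(v), 10) for v in self.sds[g]]}
                for g in sorted(self.distributions)
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def distributions_to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene\ttime_s\tcount\tprobability\n")
            for g in sorted(self.distributions):
                dist = self.distributions[g]
                for ti, t in enumerate(self.times):
                    for x, p in enumerate(dist[ti]):
                        fh.write(f"{g}\t{t:g}\t{x}\t{p:.10g}\n")


def predict_combined(fit: FitResult, times=DEFAULT_TIMES, **solve_kwargs) -> PredictionReport:
    """Predict the combined-drug condition from a single-drug-calibrated fit.

    Pure function of the stored estimates: both inhibitor substitutions
    are applied simultaneously and the CME re-solved; no parameter is
    re-estimated.  Distributions are renormalized after removing the
    truncation sink mass.
    """
    model = fit.model
    for gname, gm in model.genes.items():
        if not gm.inhibitors.mg132 or not gm.inhibitors.u0126:
            raise ValueError(
                f"gene {gname!r} lacks MG132 and/or U0126 substitution values; "
                "cannot form the combined condition")
    times = tuple(float(t) for t in times)
    distributions, means, sds = {}, {}, {}
    for gname in model.gene_names:
        sol = fsp.solve_gene(model, gname, TEST_CONDITION, np.asarray(times),
                             **solve_kwargs)
        marg = fsp.marginal_mrna(sol)
        marg = marg / marg.sum(axis=1, keepdims=True)
        distributions[gname] = marg
        mean, sd = fsp.moments(sol)
        means[gname], sds[gname] = mean, sd
    return PredictionReport(model_name=model.name, times=times,
                            distributions=distributions, means=means, sds=sds)


def _ratio(num: float, den: float) -> float | None:
    if den == 0:
        return None
    return num / den


def _as_model(fit) -> "CombinatorialModel":
    return fit.model if isinstance(fit, FitResult) else fit


def summarize(fit, other=None) -> dict:
    """Named kinetic-ratio table computed from stored estimates only.

    ``fit`` is a :class:`FitResult` or a bare :class:`CombinatorialModel`.
    Per gene: deactivation/activation ratio ``k10/k01``, reverse/forward
    ratio of the upper edge ``k21/k12`` (3-state genes), inhibitor fold
    changes ``b/b_mg132`` and ``k01/k01_u0126``.  If a second fit is
    given, also the relative difference of the degradation rates
    between the two models, per gene, in percent.
    """
    model = _as_model(fit)
    out: dict = {"model": model.name, "genes": {}}
    for gname, gm in model.genes.items():
        k = gm.params.k
        g: dict = {}
        if (1, 0) in k:
            g["k10_over_k01"] = _ratio(k[(1, 0)], k[(0, 1)])
        if (2, 1) in k:
            g["k21_over_k12"] = _ratio(k[(2, 1)], k[(1, 2)])
        if "b" in gm.inhibitors.mg132:
            g["b_over_b_mg132"] = _ratio(gm.params.b, gm.inhibitors.mg132["b"])
        if "k01" in gm.inhibitors.u0126:
            g["k01_over_k01_u0126"] = _ratio(k[(0, 1)], gm.inhibitors.u0126["k01"])
        out["genes"][gname] = g
    if other is not None:
        other_model = _as_model(other)
        out["delta_rel_diff_pct"] = {}
        for gname in model.genes:
            if gname in other_model.genes:
                d1 = model.genes[gname].params.delta
                d2 = other_model.genes[gname].params.delta
                out["delta_rel_diff_pct"][gname] = 100.0 * abs(d1 - d2) / max(d1, d2)
    return out


# ---------------------------------------------------------------------------
# two-stage screen

def default_gene_model(topology: GeneTopology) -> GeneModel:
    """Generic, weakly-informative template used to seed screen fits."""
    k = {e: 1e-3 for e in topology.edges}
    alpha = [1e-4] * topology.n_states
    alpha[-1] = 0.5
    b = 1e-2 if topology.signal_mode == "enhance" else 1.0
    return GeneModel(
        topology=topology,
        params=GeneRateParams(k=k, b=b, alpha=tuple(alpha), delta=1e-4),
        inhibitors=InhibitorMap(mg132={"b": b}, u0126={"k01": 1e-3}),
    )


def screen_single_gene(table, gene: str, signal: SignalParams,
                       candidates=None, n_keep: int = 3,
                       condition=Condition.NONE, opt_config: dict | None = None,
                       ) -> list[tuple[GeneModel, FitResult, float]]:
    """Stage 1: BIC screen of single-gene mechanisms on one condition.

    Fits each candidate topology (default: all six) to the ``gene``
    counts of ``table`` under ``condition`` alone and returns the
    ``n_keep`` best by BIC, ascending.  Inhibitor substitutions are not
    identifiable from a single condition and are excluded from the
    screen's free parameters.
    """
    condition = Condition.coerce(condition)
    if candidates is None:
        candidates = [default_gene_model(t) for t in enumerate_single_gene_topologies()]
    opt_config = dict(opt_config or {})
    results = []
    for cand in candidates:
        template = CombinatorialModel(
            name=f"screen-{cand.topology.name}", signal=signal, genes={gene: cand})
        cfg = dict(opt_config)
        cfg.setdefault("free_params", [
            n for n in free_parameter_names(template)
            if ".mg132." not in n and ".u0126." not in n])
        fit = fit_model(template, table, [condition], cfg)
        results.append((cand, fit, bic(fit.loglik, fit.n_params, fit.n_obs)))
    results.sort(key=lambda r: (r[2], r[0].topology.name))
    return results[:n_keep]


def two_stage_screen(table, signal: SignalParams, genes=("il1b", "tnfa"),
                     n_keep: int = 3, full: bool = False,
                     screen_opt: dict | None = None,
                     fit_opt: dict | None = None) -> list[FitResult]:
    """Default pipeline: per-gene BIC screen, then combinatorial fits.

    Stage 1 fits the six single-gene mechanisms to each gene under the
    no-inhibitor condition and keeps the top ``n_keep`` per gene by BIC
    (with ``full=True`` all six are kept, yielding the exhaustive
    combinatorial set).  Stage 2 fits every combination jointly across
    the three training conditions.
    """
    per_gene: dict[str, list[GeneModel]] = {}
    for gene in genes:
        if full:
            kept = [default_gene_model(t) for t in enumerate_single_gene_topologies()]
        else:
            kept = [gm_fit.model.genes[gene] for _, gm_fit, _ in
                    screen_single_gene(table, gene, signal, n_keep=n_keep,
                                       opt_config=screen_opt)]
        per_gene[gene] = kept
    fits = []
    for cm in enumerate_combinatorial_models(per_gene, signal):
        fits.append(fit_model(cm, table, TRAINING_CONDITIONS, dict(fit_opt or {})))
    return fits


def ranking_to_tsv(scores, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("model\tloglik_train\tBIC\tloglik_test\tscore\n")
        for s in scores:
            fh.write(f"{s.name}\t{s.loglik_train:.6f}\t{s.bic:.6f}"
                     f"\t{s.loglik_test:.6f}\t{s.combined:.6f}\n")
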