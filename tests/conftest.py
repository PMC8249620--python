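import numpy as np
import pytest

from fspburst.inference import with_parameters
from fspburst.models import (
    CombinatorialModel,
    GeneModel,
    GeneRateParams,
    GeneTopology,
    InhibitorMap,
    SignalParams,
    load_model,
)


def tv_distance(p, q) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def scale_transcription(model: CombinatorialModel, factor: float) -> CombinatorialModel:
    """Scale every transcription rate; switching kinetics and signal unchanged.

    Shrinks mRNA copy numbers (hence the FSP state space) without
    changing the gene-state dynamics, which keeps repeated solves cheap
    in tests while exercising the same code paths.
    """
    vals = {}
    for g in model.gene_names:
        for i, a in enumerate(model.genes[g].params.alpha):
            vals[f"{g}.alpha{i}"] = a * factor
    return with_parameters(model, vals)


def constitutive_model(alpha: float, delta: float) -> GeneModel:
    """Constitutive expression emulated by equal transcription in both states."""
    top = GeneTopology(2, (0, 1), "enhance")
    return GeneModel(
        topology=top,
        params=GeneRateParams(k={(0, 1): 1e-3, (1, 0): 1e-3}, b=0.0,
                              alpha=(alpha, alpha), delta=delta),
    )


@pytest.fixture(scope="session")
def cm1() -> CombinatorialModel:
    return load_model("cm1")


@pytest.fixture(scope="session")
def cm2() -> CombinatorialModel:
    return load_model("cm2")


@pytest.fixture(scope="session")
def cm1_scaled(cm1) -> CombinatorialModel:
    """CM1 with transcription scaled down 20x (counts ~5% of the study's)."""
    return scale_transcription(cm1, 1.0 / 20.0)


@pytest.fixture(scope="session")
def il1b_scaled(cm1_scaled) -> CombinatorialModel:
    """Single-gene (IL-1beta) scaled model used by the recovery harnesses."""
    return CombinatorialModel("il1b-scaled", cm1_scaled.signal,
                              {"il1b": cm1_scaled.genes["il1b"]})
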