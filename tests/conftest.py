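import numpy as np
import pytest

from netcoreg.coordination import coordination_B
from netcoreg.fit import Hyperparameters, fit_one_tg
from netcoreg.ppin import CandidateSet, PPINetwork, subset_and_complete
from netcoreg.simulate import make_sim_fixture

FIVE_TF_NAMES = ("TF1", "TF2", "TF3", "TF4", "TF5")


@pytest.fixture
def five_tf_net() -> PPINetwork:
    """Two known strong edges among five TFs: TF1-TF2 (0.8), TF4-TF5 (0.95)."""
    return PPINetwork({frozenset(("TF1", "TF2")): 0.8, frozenset(("TF4", "TF5")): 0.95})


@pytest.fixture
def five_tf_ppin(five_tf_net):
    cand = CandidateSet(tg="TG", tfs=FIVE_TF_NAMES)
    return subset_and_complete(five_tf_net, cand, eta=0.01)


@pytest.fixture(scope="session")
def study():
    """Full five-TF simulation study fitted once and shared across tests."""
    fx = make_sim_fixture(seed=1)
    cand = CandidateSet(tg=fx.tg_name, tfs=fx.tf_names)
    hp = Hyperparameters(beta=fx.beta, alpha=fx.alpha, eta=fx.eta, intercept=False)
    res = fit_one_tg(
        fx.X_raw[fx.train_idx],
        fx.y_raw[fx.train_idx],
        fx.net,
        cand,
        hp,
        fx.X_raw[fx.test_idx],
        fx.y_raw[fx.test_idx],
    )
    coord = coordination_B(res.embedding, res)
    return {"fixture": fx, "fit": res, "coord": coord, "hp": hp}


def random_complete_ppin(rng: np.random.Generator, n: int):
    """Random fully connected weighted network on n TFs (weights in (0.01, 1])."""
    tfs = tuple(f"TF{i + 1}" for i in range(n))
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            edges[frozenset((tfs[i], tfs[j]))] = float(rng.uniform(0.011, 1.0))
    net = PPINetwork(edges)
    return subset_and_complete(net, CandidateSet(tg="TG", tfs=tfs), eta=0.01)
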