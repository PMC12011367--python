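"""Synthetic expression and network generators.

Single-TG generator: the TG expression ``y`` is standard normal and each TF
is ``x_i = r_i * y + sqrt(1 - r_i^2) * eps_i`` with independent standard
normal noise, so TFs are conditionally independent given the TG and
``corr(x_i, y) = r_i`` exactly in population (TF-TF correlations are then
``r_i * r_j``). Dropout emulates single-cell sparsity; the default mode zeroes
whole cells (the same rows of X and y), which produces the configured
fraction of zeros while preserving all pairwise Pearson correlations — the
regime in which the five-TF study conditions (training correlations close to
the targets at ~40% sparsity) are simultaneously satisfiable. Entry-wise
dropout is also available and attenuates correlations by roughly the
retention rate.

Multi-TG generator: exogenous standard-normal TFs drive each TG through a
signed linear combination plus Gaussian noise, giving a known ground-truth
GRN for recovery benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netcoreg.ppin import PPINetwork

logger = logging.getLogger(__name__)

FIG_R_TARGETS = (0.9, 0.5, 0.4, -0.3, -0.8)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of the single-TG simulation study.

    Defaults are the study conditions: 10,000 cells, five TFs with TF-TG
    correlations (0.9, 0.5, 0.4, -0.3, -0.8), ~40% dropout, 70/30 split.
    """

    n_cells: int = 10_000
    r_targets: tuple[float, ...] = FIG_R_TARGETS
    dropout_rate: float = 0.40
    dropout_mode: str = "cell"  # "cell" (joint rows) or "entry" (independent entries)
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if any(abs(r) >= 1 for r in self.r_targets):
            raise ValueError("every target correlation must satisfy |r| < 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dropout_mode not in ("cell", "entry"):
            raise ValueError("dropout_mode must be 'cell' or 'entry'")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ToyGRN:
    """Signed ground-truth regulatory network for the multi-TG generator."""

    links: pd.DataFrame  # columns: TF, TG, effect_sign, effect_size
    tf_list: tuple[str, ...]
    tg_list: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.links["TF"]) & set(self.links["TG"])
        if bad:
            raise ValueError(f"genes regulate themselves in toy GRN: {sorted(bad)}")
        if not set(self.links["effect_sign"]) <= {-1, 1}:
            raise ValueError("effect_sign entries must be +1 or -1")

    def truth_pairs(self, signed: bool = True) -> set[tuple]:
        if signed:
            return {
                (r.TF, r.TG, int(r.effect_sign)) for r in self.links.itertuples(index=False)
            }
        return {(r.TF, r.TG) for r in self.links.itertuples(index=False)}


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one seed out to independent per-purpose generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _apply_dropout(
    X: np.ndarray, y: np.ndarray, rate: float, mode: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if rate == 0:
        return X, y
    if mode == "cell":
        mask = rng.random(X.shape[0]) < rate
        X = X.copy()
        X[mask] = 0.0
        y = np.where(mask, 0.0, y)
    else:
        mx = rng.random(X.shape) < rate
        my = rng.random(y.shape) < rate
        X = np.where(mx, 0.0, X)
        y = np.where(my, 0.0, y)
    return X, y


def simulate_single_tg(
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate (X_raw, y_raw, train_idx, test_idx) under ``cfg``.

    Deterministic under ``cfg.seed``; the data, dropout-mask, and split
    streams are independently seeded so each is reproducible on its own.
    """
    rng_data, rng_mask, rng_split = _streams(cfg.seed, 3)
    r = np.asarray(cfg.r_targets, dtype=float)
    n, p = cfg.n_cells, len(r)

    y = rng_data.standard_normal(n)
    eps = rng_data.standard_normal((n, p))
    X = r * y[:, None] + np.sqrt(1.0 - r**2) * eps

    X, y = _apply_dropout(X, y, cfg.dropout_rate, cfg.dropout_mode, rng_mask)

    perm = rng_split.permutation(n)
    n_train = int(round(cfg.train_fraction * n))
    return X, y, perm[:n_train], perm[n_train:]


def random_toy_grn(
    n_tfs: int,
    n_tgs: int,
    regulators_per_tg: tuple[int, int] = (2, 4),
    effect_range: tuple[float, float] = (0.5, 1.5),
    seed: int = 0,
) -> ToyGRN:
    """Draw a random signed TF->TG network with 2-4 regulators per TG."""
    rng = np.random.default_rng(seed)
    tfs = tuple(f"TF{i + 1}" for i in range(n_tfs))
    tgs = tuple(f"TG{i + 1}" for i in range(n_tgs))
    rows = []
    lo, hi = regulators_per_tg
    hi = min(hi, n_tfs)
    lo = min(lo, hi)
    for tg in tgs:
        k = int(rng.integers(lo, hi + 1))
        regs = rng.choice(n_tfs, size=k, replace=False)
        signs = rng.choice([-1, 1], size=k)
        sizes = rng.uniform(*effect_range, size=k)
        for r, s, e in zip(regs, signs, sizes):
            rows.append((tfs[r], tg, int(s), float(e)))
    links = pd.DataFrame(rows, columns=["TF", "TG", "effect_sign", "effect_size"])
    return ToyGRN(links=links, tf_list=tfs, tg_list=tgs)


def simulate_multi_tg(
    grn: ToyGRN,
    n_cells: int = 2_000,
    noise_sd: float = 1.0,
    dropout_rate: float = 0.0,
    dropout_mode: str = "cell",
    seed: int = 0,
) -> pd.DataFrame:
    """Expression frame (cells x [TFs, TGs]) driven by the toy GRN.

    TF columns are standard normal; each TG is its signed linear combination
    of regulators plus ``noise_sd`` Gaussian noise. A TG with no regulators
    is generated as pure noise with a warning.
    """
    rng_data, rng_mask = _streams(seed, 2)
    tf_expr = rng_data.standard_normal((n_cells, len(grn.tf_list)))
    tf_index = {t: i for i, t in enumerate(grn.tf_list)}

    tg_cols = {}
    grouped = dict(tuple(grn.links.groupby("TG")))
    for tg in grn.tg_list:
        noise = noise_sd * rng_data.standard_normal(n_cells)
        if tg not in grouped:
            logger.warning("TG %s has no regulators: generated as pure noise", tg)
            tg_cols[tg] = noise
            continue
        grp = grouped[tg]
        coef = np.zeros(len(grn.tf_list))
        for row in grp.itertuples(index=False):
            coef[tf_index[row.TF]] = row.effect_sign * row.effect_size
        tg_cols[tg] = tf_expr @ coef + noise

    expr = pd.DataFrame(tf_expr, columns=list(grn.tf_list))
    for tg in grn.tg_list:
        expr[tg] = tg_cols[tg]
    if dropout_rate > 0:
        vals = expr.to_numpy()
        dummy = np.zeros(n_cells)
        vals, _ = _apply_dropout(vals, dummy, dropout_rate, dropout_mode, rng_mask)
        expr = pd.DataFrame(vals, columns=expr.columns)
    return expr


def coregulation_ppin(grn: ToyGRN, weight: float = 0.8) -> PPINetwork:
    """PPIN whose known edges connect TFs that co-regulate at least one TG."""
    edges: dict[frozenset[str], float] = {}
    for _, grp in grn.links.groupby("TG"):
        tfs = list(grp["TF"])
        for i in range(len(tfs)):
            for j in range(i + 1, len(tfs)):
                edges[frozenset((tfs[i], tfs[j]))] = weight
    if not edges:
        raise ValueError("toy GRN implies no co-regulating TF pairs")
    return PPINetwork(edges)


@dataclass
class SimFixture:
    """Complete single-TG study bundle, ready for :func:`netcoreg.fit.fit_one_tg`."""

    X_raw: np.ndarray
    y_raw: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    net: PPINetwork
    tf_names: tuple[str, ...]
    tg_name: str
    config: SimulationConfig
    beta: float = 1.0
    alpha: float = 0.1
    eta: float = 0.01


def make_sim_fixture(seed: int = 0) -> SimFixture:
    """The five-TF, one-TG study: 10,000 cells, correlation targets
    (0.9, 0.5, 0.4, -0.3, -0.8), ~40% dropout, PPIN edges TF1-TF2 = 0.8 and
    TF4-TF5 = 0.95, eta = 0.01, beta = 1, alpha = 0.1."""
    cfg = SimulationConfig(seed=seed)
    X, y, tr, te = simulate_single_tg(cfg)
    net = PPINetwork(
        {frozenset(("TF1", "TF2")): 0.8, frozenset(("TF4", "TF5")): 0.95}
    )
    return SimFixture(
        X_raw=X,
        y_raw=y,
        train_idx=tr,
        test_idx=te,
        net=net,
        tf_names=("TF1", "TF2", "TF3", "TF4", "TF5"),
        tg_name="TG",
        config=cfg,
    )
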