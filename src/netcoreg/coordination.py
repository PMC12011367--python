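"""Signed TF->TG regulatory network and TF-TF coordination scores.

Coordination between two selected TFs combines two ingredients:

* the *magnitude* is the cosine similarity of their embedding columns,
  |cos(X~_i, X~_j)| — how close the TFs sit in the expression+network
  embedding space;
* the *sign* comes solely from coefficient agreement, C_ij = sign(c_i* c_j*):
  co-activators and co-repressors are cooperative (+), activator-repressor
  pairs antagonistic (-).

Scores are max-absolute scaled to [-100, 100] per target gene. The overall
cell-type network aggregates the per-TG matrices into a signed percentile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from netcoreg.embedding import EmbeddingSpace
from netcoreg.fit import FitResult

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryNetwork:
    """Long-format signed TF->TG link table with the filters that produced it."""

    links: pd.DataFrame  # columns: TF, TG, coef, sign, rank, mse_tg
    c_min: float
    mse_max: float | None

    @property
    def tf_count(self) -> int:
        return self.links["TF"].nunique()

    @property
    def tg_count(self) -> int:
        return self.links["TG"].nunique()

    @property
    def link_count(self) -> int:
        return len(self.links)


@dataclass
class CoordinationMatrix:
    """TG-specific coordination scores B in [-100, 100] with zero diagonal."""

    tg: str
    tf_order: tuple[str, ...]
    B: np.ndarray
    B0: np.ndarray  # pre-scaling coefficient-aware cosines

    @property
    def n_scored(self) -> int:
        """Number of nonzero unordered pairs, N*(N*-1)/2 for N* selected TFs."""
        return int(np.count_nonzero(np.triu(self.B, k=1)))

    def pairs(self) -> pd.DataFrame:
        """Long-format upper-triangle view (all candidate pairs, zeros included)."""
        rows = []
        n = len(self.tf_order)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.tg, self.tf_order[i], self.tf_order[j], self.B[i, j]))
        return pd.DataFrame(rows, columns=["TG", "TF_i", "TF_j", "B"])


def sign_matrix(c_star: np.ndarray) -> np.ndarray:
    """C_ij = sign(c_i* c_j*) with zero diagonal."""
    c = np.asarray(c_star, dtype=float)
    C = np.sign(np.outer(c, c))
    np.fill_diagonal(C, 0.0)
    return C


def assemble_grn(
    fits: list[FitResult],
    c_min: float = 0.0,
    mse_max: float | None = None,
) -> RegulatoryNetwork:
    """Collect per-TG fits into one signed link table.

    Links require |c*| > ``c_min`` (default 0, i.e. any nonzero coefficient);
    TGs whose training MSE exceeds ``mse_max`` are dropped entirely.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for fit in fits:
        if mse_max is not None and fit.mse_train > mse_max:
            logger.info("TG %s dropped: mse %.4g > mse_max %.4g", fit.tg, fit.mse_train, mse_max)
            continue
        ranks = fit.ranks
        for tf, c in zip(fit.tf_order, fit.c_star):
            if c != 0 and abs(c) > c_min:
                rows.append((tf, fit.tg, float(c), int(np.sign(c)), ranks[tf], fit.mse_train))
    links = pd.DataFrame(rows, columns=["TF", "TG", "coef", "sign", "rank", "mse_tg"])
    if links.empty:
        logger.info("assembled regulatory network is empty")
    return RegulatoryNetwork(links=links, c_min=c_min, mse_max=mse_max)


def coordination_B(emb: EmbeddingSpace, fit: FitResult) -> CoordinationMatrix:
    """TG-specific coordination matrix from embeddings and coefficients.

    B0_ij = |cos(X~_i, X~_j)| * C_ij for i != j (zero diagonal), then
    B = 100 * B0 / max|B0|. With fewer than two selected TFs every score is
    zero by convention. TFs whose embedding column was entirely truncated
    (zero norm) cannot be scored and get zeros with a warning.
    """
    if emb.tf_order != fit.tf_order:
        raise ValueError("embedding and fit disagree on TF order")
    n = emb.n
    if fit.n_selected < 2:
        zeros = np.zeros((n, n))
        return CoordinationMatrix(tg=fit.tg, tf_order=fit.tf_order, B=zeros, B0=zeros.copy())

    G = emb.X_tilde.T @ emb.X_tilde  # gram of embedding columns
    norms = np.sqrt(np.diag(G))
    dead = np.where(norms == 0)[0]
    if dead.size:
        warnings.warn(
            f"zero-norm embedding for TFs {[fit.tf_order[i] for i in dead]}; "
            "their coordination scores are set to 0",
            UserWarning,
            stacklevel=2,
        )
    safe = np.where(norms > 0, norms, 1.0)
    cos = G / np.outer(safe, safe)
    cos[dead, :] = 0.0
    cos[:, dead] = 0.0

    C = sign_matrix(fit.c_star)
    B0 = np.abs(cos) * C
    np.fill_diagonal(B0, 0.0)
    max_abs = np.abs(B0).max()
    B = 100.0 * B0 / max_abs if max_abs > 0 else B0.copy()
    return CoordinationMatrix(tg=fit.tg, tf_order=fit.tf_order, B=B, B0=B0)


def aggregate_Bbar(
    Bs: dict[str, CoordinationMatrix] | list[CoordinationMatrix],
    tf_universe: list[str] | tuple[str, ...],
) -> pd.DataFrame:
    """Aggregate per-TG coordination into an overall signed-percentile network.

    For each unordered TF pair the raw aggregate is ``f = sum_k B_ij^(k)``
    over all TGs (pairs absent from a TG contribute 0). Pairs with ``f = 0``
    get ``b_bar = 0``; among pairs with nonzero ``f``,
    ``b_bar = sign(f) * percentile_rank(|f|)`` where the fractional rank
    (average rank for ties) is scaled to (0, 100].

    Returns a frame with columns TF_i, TF_j, b_bar, n_tgs_coregulated,
    aggregate_raw covering every pair in ``tf_universe``.
    """
    mats = list(Bs.values()) if isinstance(Bs, dict) else list(Bs)
    if not mats:
        raise ValueError("no coordination matrices supplied")
    universe = list(tf_universe)
    index = {t: i for i, t in enumerate(universe)}
    nu = len(universe)
    agg = np.zeros((nu, nu))
    count = np.zeros((nu, nu), dtype=int)
    for cm in mats:
        idx = [index[t] for t in cm.tf_order]  # KeyError if outside universe
        sub = np.ix_(idx, idx)
        agg[sub] += cm.B
        count[sub] += (cm.B != 0).astype(int)

    rows = []
    for i in range(nu):
        for j in range(i + 1, nu):
            rows.append((universe[i], universe[j], agg[i, j], count[i, j]))
    df = pd.DataFrame(rows, columns=["TF_i", "TF_j", "aggregate_raw", "n_tgs_coregulated"])

    bbar = np.zeros(len(df))
    nz = df["aggregate_raw"].to_numpy() != 0
    if nz.any():
        f = df.loc[nz, "aggregate_raw"].to_numpy()
        ranks = stats.rankdata(np.abs(f), method="average")
        bbar[nz] = np.sign(f) * 100.0 * ranks / nz.sum()
    df["b_bar"] = bbar
    return df[["TF_i", "TF_j", "b_bar", "n_tgs_coregulated", "aggregate_raw"]]


def differential_B(
    Bs_cond1: dict[str, CoordinationMatrix],
    Bs_cond2: dict[str, CoordinationMatrix],
    shared_tgs: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(pair, TG) coordination changes between two conditions.

    Returns ``(long, summary)``: the long frame holds delta = B(cond2) -
    B(cond1) per TF pair and TG; the summary holds, per pair, the mean delta,
    a Welch t-statistic comparing the pair's condition-2 vs condition-1 scores
    across TGs, and Benjamini-Hochberg adjusted p-values (reported, not used
    for filtering).
    """
    if shared_tgs is None:
        shared_tgs = sorted(set(Bs_cond1) & set(Bs_cond2))
    if not shared_tgs:
        raise ValueError("no shared TGs between conditions")

    rows = []
    for tg in shared_tgs:
        cm1, cm2 = Bs_cond1[tg], Bs_cond2[tg]
        tfs = sorted(set(cm1.tf_order) | set(cm2.tf_order))
        i1 = {t: k for k, t in enumerate(cm1.tf_order)}
        i2 = {t: k for k, t in enumerate(cm2.tf_order)}
        for a in range(len(tfs)):
            for b in range(a + 1, len(tfs)):
                ti, tj = tfs[a], tfs[b]
                v1 = cm1.B[i1[ti], i1[tj]] if ti in i1 and tj in i1 else 0.0
                v2 = cm2.B[i2[ti], i2[tj]] if ti in i2 and tj in i2 else 0.0
                rows.append((ti, tj, tg, v1, v2, v2 - v1))
    long = pd.DataFrame(rows, columns=["TF_i", "TF_j", "TG", "B_cond1", "B_cond2", "delta"])

    summaries = []
    for (ti, tj), grp in long.groupby(["TF_i", "TF_j"], sort=True):
        v1, v2 = grp["B_cond1"].to_numpy(), grp["B_cond2"].to_numpy()
        if len(grp) >= 2 and (v1.std(ddof=1) > 0 or v2.std(ddof=1) > 0):
            t, p = stats.ttest_ind(v2, v1, equal_var=False)
        else:
            t, p = np.nan, np.nan
        summaries.append((ti, tj, float(grp["delta"].mean()), len(grp), t, p))
    summary = pd.DataFrame(
        summaries, columns=["TF_i", "TF_j", "mean_delta", "n_tgs", "t_stat", "p_value"]
    )
    valid = summary["p_value"].notna()
    padj = np.full(len(summary), np.nan)
    if valid.any():
        padj[valid.to_numpy()] = stats.false_discovery_control(
            summary.loc[valid, "p_value"].to_numpy(), method="bh"
        )
    summary["p_adj"] = padj
    return long, summary
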