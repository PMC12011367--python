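"""TF-TF protein-protein interaction network prior.

Loads a weighted undirected edge list among transcription factors, subsets it
to the candidate TFs of one target gene, and completes it into a fully
connected matrix ``W``: missing pairs receive a small artificial weight
``eta`` and the diagonal is set to ``d_i / (N - 1)`` where ``d_i`` is the
off-diagonal degree. Full connectivity guarantees every degree is positive,
which the downstream penalty matrix requires.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_ETA = 0.01
DEFAULT_MIN_WEIGHT = 0.01


class PPINParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass
class PPINetwork:
    """Weighted undirected TF-TF interaction network.

    Edges are stored on unordered pairs; weights are unitless confidences in
    ``(min_weight, 1]``. Self-loops are never stored.
    """

    edges: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for pair in self.edges:
            out.update(pair)
        return out

    @property
    def w_min(self) -> float:
        """Smallest retained known-edge weight (``w_min^0``)."""
        if not self.edges:
            raise ValueError("network has no edges")
        return min(self.edges.values())

    def weight(self, a: str, b: str) -> float | None:
        return self.edges.get(frozenset((a, b)))

    def with_edge(self, a: str, b: str, w: float) -> "PPINetwork":
        """Return a copy with edge (a, b) set to weight ``w``."""
        new = dict(self.edges)
        new[frozenset((a, b))] = float(w)
        return PPINetwork(new)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class CandidateSet:
    """Candidate TFs offered as predictors for one target gene.

    The TG itself is never a candidate: expression of a gene must not predict
    itself. Use :meth:`for_tg` to build a set that silently drops the self-TF.
    """

    tg: str
    tfs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tfs) < 1:
            raise ValueError(f"candidate set for {self.tg!r} is empty")
        if len(set(self.tfs)) != len(self.tfs):
            raise ValueError(f"duplicate candidate TFs for {self.tg!r}")
        if self.tg in self.tfs:
            raise ValueError(f"TG {self.tg!r} listed among its own candidate TFs")

    @classmethod
    def for_tg(cls, tg: str, tfs: list[str] | tuple[str, ...]) -> "CandidateSet":
        """Build a candidate set, removing the TG from its own candidates."""
        kept = tuple(t for t in tfs if t != tg)
        if len(kept) < len(tfs):
            logger.info("TG %s removed from its own candidate TF list", tg)
        return cls(tg=tg, tfs=kept)

    @property
    def n(self) -> int:
        return len(self.tfs)


@dataclass
class PreprocessedPPIN:
    """Fully connected TG-specific TF-TF matrix with the diagonal rule.

    ``W`` is symmetric N x N; off-diagonals are known weights or ``eta``,
    the diagonal is ``d_i / (N - 1)``. ``degenerate`` flags the N == 1 case
    where no pairwise structure (hence no coordination) exists.
    """

    tf_order: tuple[str, ...]
    W: np.ndarray
    eta: float
    d: np.ndarray
    known_mask: np.ndarray  # True where the off-diagonal weight came from the input network
    degenerate: bool = False

    @property
    def n(self) -> int:
        return len(self.tf_order)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def load_ppin(
    path: str | Path,
    min_weight: float = DEFAULT_MIN_WEIGHT,
    max_scale: bool = False,
) -> PPINetwork:
    """Load a 3-column (node, node, weight) edge list into a :class:`PPINetwork`.

    A header row is auto-detected by a nonnumeric third field. Self-loops are
    dropped. With ``max_scale``, raw combined scores are divided by the
    maximum score so weights are capped at 1. Edges with weight <= ``min_weight``
    are then discarded and duplicate pairs are merged keeping the maximum
    weight (conservative confidence merge).

    Raises :class:`PPINParseError` on a malformed line and :class:`ValueError`
    if no edges survive filtering.
    """
    path = Path(path)
    raw: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split("\t")
            fields = [f.strip() for f in fields if f.strip() != ""]
            if len(fields) < 3:
                raise PPINParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            a, b, w_str = fields[0], fields[1], fields[2]
            if lineno == 1 and not _looks_numeric(w_str):
                continue  # header row
            if not _looks_numeric(w_str):
                raise PPINParseError(f"{path}:{lineno}: nonnumeric weight {w_str!r}")
            if a == b:
                continue  # self-loop
            raw.append((a, b, float(w_str)))

    if max_scale and raw:
        top = max(w for _, _, w in raw)
        if top <= 0:
            raise ValueError(f"{path}: maximum combined score is not positive")
        raw = [(a, b, w / top) for a, b, w in raw]

    edges: dict[frozenset[str], float] = {}
    for a, b, w in raw:
        if w <= min_weight:
            continue
        key = frozenset((a, b))
        if key in edges:
            edges[key] = max(edges[key], w)
        else:
            edges[key] = w

    if not edges:
        raise ValueError(
            f"{path}: network is empty after filtering (min_weight={min_weight})"
        )
    return PPINetwork(edges)


def subset_and_complete(
    net: PPINetwork,
    cand: CandidateSet,
    eta: float = DEFAULT_ETA,
) -> PreprocessedPPIN:
    """Subset ``net`` to the candidate TFs and complete it with ``eta`` edges.

    TFs absent from the network are included with all-``eta`` edges. Degrees
    are computed over off-diagonals only, then the diagonal is set to
    ``d_i / (N - 1)``. If ``eta`` is not below the smallest known weight in
    the subset, a warning is emitted (the global guarantee ``eta < w_min``
    can be violated locally after subsetting) and completion proceeds.
    """
    if eta <= 0:
        raise ValueError(f"eta must be positive, got {eta}")
    tfs = cand.tfs
    n = len(tfs)
    if n < 1:
        raise ValueError("candidate set must contain at least one TF")

    if n == 1:
        logger.warning(
            "TG %s has a single candidate TF: degenerate network, no coordination possible",
            cand.tg,
        )
        return PreprocessedPPIN(
            tf_order=tfs,
            W=np.zeros((1, 1)),
            eta=eta,
            d=np.zeros(1),
            known_mask=np.zeros((1, 1), dtype=bool),
            degenerate=True,
        )

    W = np.full((n, n), eta, dtype=float)
    known = np.zeros((n, n), dtype=bool)
    local_known: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            w = net.weight(tfs[i], tfs[j])
            if w is not None:
                W[i, j] = W[j, i] = w
                known[i, j] = known[j, i] = True
                local_known.append(w)

    if local_known and eta >= min(local_known):
        warnings.warn(
            f"eta={eta} >= smallest known subset weight {min(local_known)}; "
            "artificial edges are not strictly below known confidences",
            UserWarning,
            stacklevel=2,
        )

    np.fill_diagonal(W, 0.0)
    d = W.sum(axis=1)
    np.fill_diagonal(W, d / (n - 1))
    return PreprocessedPPIN(
        tf_order=tfs, W=W, eta=eta, d=d, known_mask=known, degenerate=False
    )
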