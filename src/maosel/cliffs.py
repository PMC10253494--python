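"""Structure-activity landscape analysis: SALI scores, cliffs, networks.

An activity cliff is a pair of structurally similar compounds with a large
potency difference.  Cliff severity is quantified by the structure-
activity landscape index

    SALI_ij = |A_i - A_j| / (1 - sim_ij)

where ``A`` is the activity (pIC50 for activity cliffs, log10 SI for
selectivity cliffs — SI spans six orders of magnitude, so the log scale is
the sensible surrogate) and ``sim`` the pairwise molecular similarity.
Identical-structure pairs (sim == 1) with differing activity are flagged
infinite rather than capped so downstream ranking stays explicit.

The default similarity is Tanimoto on binary fingerprints; any symmetric
[0,1] similarity matrix can be plugged in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dataset import CompoundRecord
from .fingerprints import FingerprintMatrix

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    values: np.ndarray  # n x n, symmetric, diagonal 1
    ids: list[str]
    descriptor: str = "fingerprint-tanimoto"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("similarity matrix must be square and match ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")


@dataclass
class CliffPair:
    i: str
    j: str
    activity_delta: float
    sim: float
    sali: float  # math.inf marks an identical-structure pair with delta > 0
    si_i: float | None = None
    si_j: float | None = None

    @property
    def infinite(self) -> bool:
        return math.isinf(self.sali)


def pairwise_similarity(fingerprints: FingerprintMatrix) -> SimilarityMatrix:
    """Tanimoto similarity between all fingerprint rows.

    An all-zero row has no defined Tanimoto similarity; it is assigned 0
    to every other compound (and 1 to itself) with a warning.
    """
    M = fingerprints.matrix.astype(np.float64)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 compounds")
    inter = M @ M.T
    pop = M.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    empty = pop == 0
    if empty.any():
        logger.warning("%d all-zero fingerprint rows; similarity to others set to 0", int(empty.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(values=sim, ids=list(fingerprints.ids))


def sali(a_i: float, a_j: float, sim: float) -> float:
    """SALI score |A_i - A_j| / (1 - sim); inf when sim == 1 and the
    activities differ, 0 whenever the activities are equal."""
    if not 0.0 <= sim <= 1.0:
        raise ValueError(f"similarity must be in [0, 1], got {sim}")
    delta = abs(a_i - a_j)
    if delta == 0.0:
        return 0.0
    if sim == 1.0:
        return math.inf
    return delta / (1.0 - sim)


def _activity_values(records: Sequence[CompoundRecord], mode: str) -> np.ndarray:
    if mode == "activity":
        return np.array([r.pic50_b for r in records])
    if mode == "selectivity":
        vals = []
        for r in records:
            if r.si is None:
                raise ValueError(f"compound {r.id}: selectivity mode requires SI for all records")
            vals.append(math.log10(r.si))
        return np.array(vals)
    raise ValueError(f"unknown mode {mode!r}")


def detect_cliffs(
    records: Sequence[CompoundRecord],
    similarity: SimilarityMatrix,
    mode: str = "activity",
    top_k: int | None = None,
    sali_threshold: float | None = None,
) -> list[CliffPair]:
    """All pairs ranked by SALI descending (infinite pairs first).

    ``mode='activity'`` scores pIC50 differences; ``mode='selectivity'``
    scores log10(SI) differences.  Ties and the infinite group are broken
    deterministically by (i, j) id order.  ``top_k`` truncates the ranking;
    ``sali_threshold`` drops pairs below the threshold.
    """
    A = _activity_values(records, mode)
    n = len(records)
    if similarity.values.shape[0] != n:
        raise ValueError("similarity matrix size must match records")
    pairs: list[CliffPair] = []
    for i in range(n):
        for j in range(i + 1, n):
            s = float(similarity.values[i, j])
            score = sali(A[i], A[j], min(s, 1.0))
            pairs.append(
                CliffPair(
                    i=records[i].id,
                    j=records[j].id,
                    activity_delta=abs(float(A[i] - A[j])),
                    sim=s,
                    sali=score,
                    si_i=records[i].si,
                    si_j=records[j].si,
                )
            )
    pairs.sort(key=lambda p: (not p.infinite, -p.sali if not p.infinite else 0.0, p.i, p.j))
    if sali_threshold is not None:
        pairs = [p for p in pairs if p.infinite or p.sali >= sali_threshold]
    if top_k is not None:
        pairs = pairs[:top_k]
    return pairs


def build_network(
    records: Sequence[CompoundRecord],
    similarity: SimilarityMatrix,
    edge_threshold: float = 0.55,
    mode: str = "activity",
) -> nx.Graph:
    """Similarity graph: one node per compound, edges where sim >= threshold.

    Node attributes carry potency, selectivity class, and the local SALI
    contribution (max SALI over incident above-threshold pairs; infinite
    pairs are recorded with the attribute ``sali_infinite``).  Edge order
    and attributes are deterministic, so GraphML export is reproducible.
    """
    if not 0.0 < edge_threshold <= 1.0:
        raise ValueError("edge_threshold must be in (0, 1]")
    A = _activity_values(records, mode)
    G = nx.Graph()
    for i, rec in enumerate(records):
        G.add_node(rec.id, potency=float(rec.pic50_b), selectivity_class=rec.selectivity_class, local_sali=0.0)
    n = len(records)
    for i in range(n):
        for j in range(i + 1, n):
            s = float(similarity.values[i, j])
            if s >= edge_threshold:
                score = sali(A[i], A[j], min(s, 1.0))
                G.add_edge(
                    records[i].id,
                    records[j].id,
                    sim=s,
                    sali=-1.0 if math.isinf(score) else score,
                    sali_infinite=math.isinf(score),
                )
                for node in (records[i].id, records[j].id):
                    if math.isinf(score):
                        G.nodes[node]["sali_infinite"] = True
                    else:
                        G.nodes[node]["local_sali"] = max(G.nodes[node]["local_sali"], score)
    return G


def cluster(
    similarity: SimilarityMatrix, k: int | None = None, distance_cut: float | None = None
) -> np.ndarray:
    """Average-linkage hierarchical clustering on distance 1 - sim.

    Exactly one of ``k`` (number of clusters) or ``distance_cut`` must be
    given.  Returns integer labels (1-based, scipy convention).
    """
    if (k is None) == (distance_cut is None):
        raise ValueError("specify exactly one of k or distance_cut")
    n = similarity.values.shape[0]
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds number of compounds n={n}")
    dist = 1.0 - similarity.values
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    if k is not None:
        return fcluster(Z, t=k, criterion="maxclust")
    return fcluster(Z, t=distance_cut, criterion="distance")


def cliffs_to_frame(pairs: Sequence[CliffPair]):
    import pandas as pd

    return pd.DataFrame(
        {
            "i": [p.i for p in pairs],
            "j": [p.j for p in pairs],
            "activity_delta": [p.activity_delta for p in pairs],
            "sim": [p.sim for p in pairs],
            "sali": [p.sali for p in pairs],
            "infinite": [p.infinite for p in pairs],
            "si_i": [p.si_i for p in pairs],
            "si_j": [p.si_j for p in pairs],
        }
    )
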