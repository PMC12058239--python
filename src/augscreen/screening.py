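"""Library screening and similarity-network hit selection.

A trained classifier scores every library molecule with a probability of
activation; molecules become nodes of an undirected network whose edges link
structurally similar pairs (ECFP Tanimoto at or above a threshold).  Hits
are molecules with high predicted probability embedded in a structurally
coherent neighborhood (degree >= 3): isolated high-probability singletons are
more likely classifier noise than a real SAR island.  Edges joining nodes
with a large probability difference are activity cliffs; small differences
along edges indicate a continuous SAR.  A 2-D t-SNE embedding on path-based
fingerprints is provided for reporting only — hit selection never depends on
embedding coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_core import FingerprintKind, Molecule, compute_fingerprint
from .classifier import TrainedClassifier, predict_probability

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Per-molecule activation probability for a screened library."""

    ids: list[str]
    probs: np.ndarray
    molecules: list[Molecule]
    library_id: str = "library"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not (len(self.ids) == len(self.probs) == len(self.molecules)):
            raise ValueError("inconsistent screen result lengths")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "smiles": [m.smiles for m in self.molecules], "p": self.probs})


def screen_library(
    clf: TrainedClassifier, library: Sequence[Molecule], chunk_size: int = 2000, library_id: str = "library"
) -> ScreenResult:
    """Score a library in chunks; chunking is invisible in the output.

    Featurization failures are logged per molecule and reported as NaN
    probability rather than aborting the screen.
    """
    ids: list[str] = []
    probs: list[float] = []
    for start in range(0, len(library), chunk_size):
        chunk = list(library[start : start + chunk_size])
        try:
            scored = predict_probability(clf, chunk)
        except Exception:
            # fall back to per-molecule scoring so one bad record cannot sink a chunk
            scored = []
            for m in chunk:
                try:
                    scored.extend(predict_probability(clf, [m]))
                except Exception as exc:  # noqa: BLE001 - logged, not fatal
                    logger.warning("featurization failed for %s: %s", m.id, exc)
                    scored.append((m.id, float("nan")))
        ids.extend(i for i, _ in scored)
        probs.extend(p for _, p in scored)
    return ScreenResult(ids=ids, probs=np.array(probs), molecules=list(library), library_id=library_id)


# ---------------------------------------------------------------------------
# Similarity network
# ---------------------------------------------------------------------------

@dataclass
class SimilarityNetwork:
    """Undirected Tanimoto-thresholded similarity graph with node probabilities."""

    graph: nx.Graph
    edge_threshold: float

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edge_frame(self) -> pd.DataFrame:
        rows = [(i, j, d["weight"]) for i, j, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["i", "j", "weight"])

    def node_frame(self) -> pd.DataFrame:
        deg = self.degrees
        rows = [(n, d["p"], deg[n]) for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(rows, columns=["id", "p", "degree"])


def _fingerprint_matrix(mols: Sequence[Molecule], nbits: int = 2048) -> np.ndarray:
    mat = np.zeros((len(mols), nbits), dtype=np.float32)
    for i, m in enumerate(mols):
        fp = compute_fingerprint(m, FingerprintKind.ECFP, nbits=nbits)
        if fp.bits:
            mat[i, sorted(fp.bits)] = 1.0
    return mat


def pairwise_tanimoto(mols: Sequence[Molecule], nbits: int = 2048, block: int = 512) -> np.ndarray:
    """Dense pairwise ECFP Tanimoto matrix (blockwise bit-count arithmetic)."""
    B = _fingerprint_matrix(mols, nbits)
    counts = B.sum(axis=1)
    n = len(mols)
    sim = np.empty((n, n), dtype=np.float32)
    for start in range(0, n, block):
        stop = min(start + block, n)
        inter = B[start:stop] @ B.T
        union = counts[start:stop, None] + counts[None, :] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(union > 0, inter / union, 1.0)  # two empty fps: identical
        sim[start:stop] = s
    return sim


def build_similarity_network(
    mols: Sequence[Molecule],
    probs: Sequence[float] | dict[str, float],
    edge_threshold: float = 0.6,
    nbits: int = 2048,
) -> SimilarityNetwork:
    """Exact pairwise network construction: edge iff Tanimoto >= threshold.

    No self-edges; the graph is undirected and deterministic.  Intended for
    libraries up to a few tens of thousands of molecules (dense O(n^2)).
    """
    if not (0 < edge_threshold <= 1):
        raise ValueError("edge_threshold must lie in (0, 1]")
    if isinstance(probs, dict):
        pvec = [probs[m.id] for m in mols]
    else:
        pvec = list(probs)
    if len(pvec) != len(mols):
        raise ValueError("probabilities must cover all molecules")
    g = nx.Graph()
    for m, p in zip(mols, pvec):
        g.add_node(m.id, p=float(p), smiles=m.smiles)
    sim = pairwise_tanimoto(mols, nbits=nbits)
    n = len(mols)
    iu, ju = np.triu_indices(n, k=1)
    mask = sim[iu, ju] >= edge_threshold
    for i, j in zip(iu[mask], ju[mask]):
        g.add_edge(mols[i].id, mols[j].id, weight=float(sim[i, j]))
    return SimilarityNetwork(graph=g, edge_threshold=edge_threshold)


@dataclass(frozen=True)
class CliffPair:
    i: str
    j: str
    delta_p: float
    weight: float


def detect_activity_cliffs(net: SimilarityNetwork, cliff_delta: float = 0.5) -> list[CliffPair]:
    """Edges whose endpoint probability difference is >= cliff_delta, sorted
    by delta descending (ties by node ids for determinism)."""
    cliffs = []
    for i, j, d in net.graph.edges(data=True):
        a, b = sorted((i, j))
        dp = abs(net.graph.nodes[i]["p"] - net.graph.nodes[j]["p"])
        if dp >= cliff_delta:
            cliffs.append(CliffPair(i=a, j=b, delta_p=dp, weight=d["weight"]))
    return sorted(cliffs, key=lambda c: (-c.delta_p, c.i, c.j))


# ---------------------------------------------------------------------------
# 2-D embedding (reporting only)
# ---------------------------------------------------------------------------

def embed_2d(mols: Sequence[Molecule], perplexity: float = 30.0, rng_seed: int = 0) -> np.ndarray:
    """t-SNE embedding of the library on hashed path fingerprints.

    The input features are RDKit's path-based hashed fingerprint (a stand-in
    for proprietary path descriptors; not claimed equivalent).  Coordinates
    are reproducible under ``rng_seed``.
    """
    from sklearn.manifold import TSNE

    n = len(mols)
    if n < 5:
        raise ValueError("embedding requires at least 5 molecules")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < number of molecules ({n})")
    X = np.zeros((n, 2048), dtype=np.float32)
    for i, m in enumerate(mols):
        bv = Chem.RDKFingerprint(m.to_rdkit(), fpSize=2048)
        X[i, list(bv.GetOnBits())] = 1.0
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=rng_seed, init="pca")
    return ts.fit_transform(X)


# ---------------------------------------------------------------------------
# Hit selection
# ---------------------------------------------------------------------------

@dataclass
class HitTable:
    """Selected hits with probability, degree and the criteria that chose them."""

    table: pd.DataFrame  # columns: id, smiles, p, degree
    criteria: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()


def select_hits(
    result: ScreenResult,
    net: SimilarityNetwork,
    prob_min: float = 0.7,
    prob_max: float = 1.0,
    min_degree: int = 3,
) -> HitTable:
    """Select hits: prob_min < p <= prob_max and network degree >= min_degree."""
    deg = net.degrees
    missing = [i for i in result.ids if i not in deg]
    if missing:
        raise ValueError(f"network does not cover screened molecules (e.g. {missing[0]!r})")
    rows = []
    for m, p in zip(result.molecules, result.probs):
        if np.isnan(p):
            continue
        if prob_min < p <= prob_max and deg[m.id] >= min_degree:
            rows.append((m.id, m.smiles, float(p), deg[m.id]))
    table = pd.DataFrame(rows, columns=["id", "smiles", "p", "degree"])
    criteria = {
        "prob_min": prob_min,
        "prob_max": prob_max,
        "min_degree": min_degree,
        "edge_threshold": net.edge_threshold,
    }
    return HitTable(table=table, criteria=criteria)
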