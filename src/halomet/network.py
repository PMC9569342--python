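"""Modified-cosine MS/MS similarity and molecular-network construction.

The modified cosine allows fragment pairs matching either directly (equal
m/z within tolerance) or offset by the precursor mass difference, so that
analogs differing by one substituent still align.  Intensities are
square-root transformed and each spectrum L2-normalised before pairing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra import FeatureTable, MsmsSpectrum, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularNetwork",
    "SimilarityEdge",
    "build_network",
    "export_graphml",
    "import_graphml",
    "modified_cosine",
    "modified_cosine_brute_force",
]

Weighting = Literal["sqrt", "identity"]


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity link between two features."""

    id_a: str
    id_b: str
    score: float
    n_matched: int

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError("self-edges are not allowed")
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError(f"score out of [0,1]: {self.score}")


def _weighted_vectors(a: MsmsSpectrum, weighting: Weighting) -> np.ndarray:
    w = np.sqrt(a.intensity) if weighting == "sqrt" else a.intensity.astype(float)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def _candidate_pairs(
    a: MsmsSpectrum, b: MsmsSpectrum, frag_tol: float
) -> list[tuple[int, int]]:
    shift = a.precursor_mz - b.precursor_mz
    pairs: set[tuple[int, int]] = set()
    for offset in (0.0, shift):
        lo = np.searchsorted(b.mz, a.mz - offset - frag_tol, side="left")
        hi = np.searchsorted(b.mz, a.mz - offset + frag_tol, side="right")
        for i, (l, h) in enumerate(zip(lo, hi)):
            for j in range(l, h):
                pairs.add((i, j))
    return sorted(pairs)


def modified_cosine(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    frag_tol: float = 0.02,
    weighting: Weighting = "sqrt",
    pairing: Literal["optimal", "greedy"] = "optimal",
) -> tuple[float, int]:
    """One-to-one modified-cosine score and matched-pair count.

    Candidate fragment pairs match directly or shifted by the precursor
    mass difference.  ``optimal`` (default) solves the maximum-weight
    one-to-one assignment exactly; ``greedy`` accepts pairs by descending
    intensity product (ties broken by smaller fragment m/z).  The two
    agree except on conflict-heavy candidate graphs, where greedy can be
    suboptimal.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    wa, wb = _weighted_vectors(a, weighting), _weighted_vectors(b, weighting)
    candidates = _candidate_pairs(a, b, frag_tol)
    if not candidates:
        return 0.0, 0
    if pairing == "greedy":
        return _greedy_score(a, b, wa, wb, candidates)
    return _optimal_score(wa, wb, candidates)


def _optimal_score(wa, wb, candidates) -> tuple[float, int]:
    rows = sorted({i for i, _ in candidates})
    cols = sorted({j for _, j in candidates})
    row_of = {i: r for r, i in enumerate(rows)}
    col_of = {j: c for c, j in enumerate(cols)}
    weights = np.zeros((len(rows), len(cols)))
    allowed = np.zeros_like(weights, dtype=bool)
    for i, j in candidates:
        weights[row_of[i], col_of[j]] = wa[i] * wb[j]
        allowed[row_of[i], col_of[j]] = True
    r_idx, c_idx = linear_sum_assignment(weights, maximize=True)
    score, n_matched = 0.0, 0
    for r, c in zip(r_idx, c_idx):
        if allowed[r, c]:
            score += float(weights[r, c])
            n_matched += 1
    return min(score, 1.0), n_matched


def _greedy_score(a, b, wa, wb, candidates) -> tuple[float, int]:
    scored = sorted(
        candidates,
        key=lambda ij: (-wa[ij[0]] * wb[ij[1]], a.mz[ij[0]], b.mz[ij[1]]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    score, n_matched = 0.0, 0
    for i, j in scored:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += float(wa[i] * wb[j])
        n_matched += 1
    return min(score, 1.0), n_matched


def modified_cosine_brute_force(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    frag_tol: float = 0.02,
    weighting: Weighting = "sqrt",
) -> tuple[float, int]:
    """Exhaustive maximum-weight one-to-one pairing oracle (small spectra).

    Searches every maximal conflict-free subset of the candidate pairs;
    exponential, for testing the greedy scorer only.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    wa, wb = _weighted_vectors(a, weighting), _weighted_vectors(b, weighting)
    candidates = _candidate_pairs(a, b, frag_tol)
    best = (0.0, 0)

    def explore(idx: int, used_a: frozenset, used_b: frozenset, acc: float, k: int):
        nonlocal best
        if acc > best[0] + 1e-15:
            best = (acc, k)
        for pos in range(idx, len(candidates)):
            i, j = candidates[pos]
            if i in used_a or j in used_b:
                continue
            explore(
                pos + 1, used_a | {i}, used_b | {j}, acc + float(wa[i] * wb[j]), k + 1
            )

    explore(0, frozenset(), frozenset(), 0.0, 0)
    return min(best[0], 1.0), best[1]


class MolecularNetwork:
    """Graph over MS/MS-bearing features with similarity edges."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def similarity_edges(self) -> list[SimilarityEdge]:
        return [
            SimilarityEdge(u, v, data["score"], data["n_matched"])
            for u, v, data in sorted(self.graph.edges(data=True))
        ]

    def component_ids(self) -> dict[str, int]:
        """Stable component index per node (components ordered by min node id)."""
        comps = sorted(nx.connected_components(self.graph), key=min)
        return {node: k for k, comp in enumerate(comps) for node in comp}


def build_network(
    features: FeatureTable,
    frag_tol: float = 0.02,
    min_matched: int = 2,
    min_score: float = 0.65,
    weighting: Weighting = "sqrt",
    preprocess_spectra: bool = True,
) -> MolecularNetwork:
    """Construct the molecular network over features that carry MS/MS.

    Edges require at least ``min_matched`` matched peaks and a modified
    cosine of at least ``min_score``.  Spectra are window-filtered (top 6
    in ±50 Da) and precursor-excluded (±17 Da) beforehand unless disabled.
    """
    if min_matched < 1:
        raise ValueError("min_matched must be >= 1")
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    nodes = sorted(features.with_msms(), key=lambda f: f.id)
    if not nodes:
        logger.warning("no features with MS/MS spectra; returning empty network")
    graph = nx.Graph()
    processed: dict[str, MsmsSpectrum] = {}
    for f in nodes:
        graph.add_node(
            f.id, mz=f.mz, rt=f.rt, condition=f.condition, intensity=f.intensity
        )
        processed[f.id] = preprocess(f.msms) if preprocess_spectra else f.msms
    for fa, fb in itertools.combinations(nodes, 2):
        score, n_matched = modified_cosine(
            processed[fa.id], processed[fb.id], frag_tol=frag_tol, weighting=weighting
        )
        if n_matched >= min_matched and score >= min_score:
            graph.add_edge(fa.id, fb.id, score=score, n_matched=n_matched)
    return MolecularNetwork(graph)


def export_graphml(network: MolecularNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, str(path))


def import_graphml(path: str | Path) -> MolecularNetwork:
    return MolecularNetwork(nx.read_graphml(str(path)))
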