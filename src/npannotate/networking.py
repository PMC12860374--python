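"""Dual-dimension similarity and molecular-network construction.

Spectral relatedness is scored in two dimensions and combined linearly:

    Similarity = alpha * Sim_fragment + beta * Sim_neutral_loss

``Sim_fragment`` is a cosine over one-to-one matched fragment pairs with the
denominator running over *all* valid peaks of both spectra, using raw
intensities.  ``Sim_neutral_loss`` is the Jaccard index of the two
neutral-loss sets under tolerance matching.  The loss dimension links
homologous spectra whose fragments are shifted by a conjugate mass, the
role a "modified cosine" plays elsewhere.  Edges are kept when the combined
score strictly exceeds the threshold (default 0.6, alpha=0.9, beta=0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import networkx as nx

from .feature_io import DEFAULT_MZ_TOL, Feature, Ms2Spectrum, top_k_fragments
from .ms2 import TOP_K, spectrum_neutral_losses


@dataclass(frozen=True)
class SimilarityWeights:
    """Fragment / neutral-loss weight pair; must sum to 1."""

    alpha: float = 0.9
    beta: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or abs(self.alpha + self.beta - 1) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")


DEFAULT_WEIGHTS = SimilarityWeights()
DEFAULT_THRESHOLD = 0.6


def _match_peaks(
    a: Sequence, b: Sequence, mz_tol: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one peak pairing by ascending |Δm/z| within tolerance."""
    pairs = []
    for i, pa in enumerate(a):
        for j, pb in enumerate(b):
            d = abs(pa.mz - pb.mz)
            if d <= mz_tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j))
    return out


def fragment_similarity(
    a: Ms2Spectrum, b: Ms2Spectrum, mz_tol: float = DEFAULT_MZ_TOL, top_k: int = TOP_K
) -> float:
    """Cosine over matched fragment pairs, normalised over all valid peaks."""
    ta = top_k_fragments(a, top_k) if len(a) > top_k else a
    tb = top_k_fragments(b, top_k) if len(b) > top_k else b
    na = math.sqrt(sum(p.intensity ** 2 for p in ta.peaks))
    nb = math.sqrt(sum(p.intensity ** 2 for p in tb.peaks))
    if na == 0 or nb == 0:
        return 0.0
    num = sum(
        ta.peaks[i].intensity * tb.peaks[j].intensity
        for i, j in _match_peaks(ta.peaks, tb.peaks, mz_tol)
    )
    return num / (na * nb)


def neutral_loss_similarity(
    nl_a: Sequence[float], nl_b: Sequence[float], mz_tol: float = DEFAULT_MZ_TOL
) -> float:
    """Jaccard index of two loss sets under one-to-one tolerance matching."""
    if not nl_a and not nl_b:
        return 0.0

    class _L:
        __slots__ = ("mz",)

        def __init__(self, mz):
            self.mz = mz

    inter = len(_match_peaks([_L(x) for x in nl_a], [_L(x) for x in nl_b], mz_tol))
    union = len(nl_a) + len(nl_b) - inter
    return inter / union if union else 0.0


def combined_similarity(
    sim_fragment: float,
    sim_neutral_loss: float,
    weights: SimilarityWeights = DEFAULT_WEIGHTS,
) -> float:
    return weights.alpha * sim_fragment + weights.beta * sim_neutral_loss


def pair_similarity(
    a: Ms2Spectrum,
    b: Ms2Spectrum,
    weights: SimilarityWeights = DEFAULT_WEIGHTS,
    mz_tol: float = DEFAULT_MZ_TOL,
    top_k: int = TOP_K,
) -> tuple[float, float, float]:
    """(Sim_fragment, Sim_neutral_loss, combined) for one spectrum pair."""
    sf = fragment_similarity(a, b, mz_tol=mz_tol, top_k=top_k)
    snl = neutral_loss_similarity(
        spectrum_neutral_losses(a, top_k=top_k, mz_tol=mz_tol),
        spectrum_neutral_losses(b, top_k=top_k, mz_tol=mz_tol),
        mz_tol=mz_tol,
    )
    return sf, snl, combined_similarity(sf, snl, weights)


def build_network(
    features: Sequence[Feature],
    threshold: float = DEFAULT_THRESHOLD,
    weights: SimilarityWeights = DEFAULT_WEIGHTS,
    mz_tol: float = DEFAULT_MZ_TOL,
    top_k: int = TOP_K,
    node_attrs: dict[str, dict] | None = None,
) -> nx.Graph:
    """Score all unordered pairs of MS2-bearing features; keep edges with
    combined similarity strictly above ``threshold``.

    ``node_attrs`` maps feature id -> extra attributes (name, class, tier)
    carried into the exported graph.
    """
    g = nx.Graph(threshold=threshold, alpha=weights.alpha, beta=weights.beta)
    with_ms2 = [f for f in features if f.ms2 is not None and len(f.ms2) > 0]
    for f in with_ms2:
        attrs = dict(id=f.id, mz=f.mz, rt=f.rt)
        if node_attrs and f.id in node_attrs:
            attrs.update(node_attrs[f.id])
        g.add_node(f.id, **attrs)
    losses = {
        f.id: spectrum_neutral_losses(f.ms2, top_k=top_k, mz_tol=mz_tol)
        for f in with_ms2
    }
    for i, fa in enumerate(with_ms2):
        for fb in with_ms2[i + 1:]:
            sf = fragment_similarity(fa.ms2, fb.ms2, mz_tol=mz_tol, top_k=top_k)
            snl = neutral_loss_similarity(losses[fa.id], losses[fb.id], mz_tol=mz_tol)
            sim = combined_similarity(sf, snl, weights)
            if sim > threshold:
                g.add_edge(
                    fa.id,
                    fb.id,
                    sim_fragment=sf,
                    sim_nl=snl,
                    similarity=sim,
                )
    return g


def network_stats(g: nx.Graph) -> dict:
    """Node/edge/component counts and same-class edge purity.

    Purity is the fraction of edges joining two nodes of the same assigned
    class, over edges whose both endpoints carry a class attribute.
    """
    classed = {n: d["class"] for n, d in g.nodes(data=True) if d.get("class")}
    both = [(u, v) for u, v in g.edges if u in classed and v in classed]
    same = sum(1 for u, v in both if classed[u] == classed[v])
    return {
        "nodes": g.number_of_nodes(),
        "edges": g.number_of_edges(),
        "components": nx.number_connected_components(g) if len(g) else 0,
        "class_purity": same / len(both) if both else float("nan"),
    }


def alpha_scan(
    features: Sequence[Feature],
    alphas: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    threshold: float = DEFAULT_THRESHOLD,
    mz_tol: float = DEFAULT_MZ_TOL,
    top_k: int = TOP_K,
):
    """Network node/edge counts as the fragment weight alpha varies.

    Returns a DataFrame with one row per (alpha, beta=1-alpha) pair --
    the harness used to choose the weight pair that retains the most
    network structure at a fixed threshold.
    """
    import pandas as pd

    rows = []
    for alpha in alphas:
        w = SimilarityWeights(alpha=alpha, beta=round(1.0 - alpha, 12))
        g = build_network(features, threshold=threshold, weights=w,
                         mz_tol=mz_tol, top_k=top_k)
        stats = network_stats(g)
        rows.append({"alpha": alpha, "beta": round(1.0 - alpha, 12), **stats})
    return pd.DataFrame(rows)


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, str(path))


def write_edge_list(g: nx.Graph, path) -> None:
    import pandas as pd

    rows = [
        {
            "source": u,
            "target": v,
            "sim_fragment": d["sim_fragment"],
            "sim_nl": d["sim_nl"],
            "similarity": d["similarity"],
        }
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "sim_fragment", "sim_nl", "similarity"]).to_csv(
        path, index=False
    )
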