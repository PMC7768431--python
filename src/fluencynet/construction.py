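"""Estimating a group semantic network from a binary incidence matrix.

The pipeline is: participant x word incidence matrix -> word x word cosine
similarity -> Triangulated Maximally Filtered Graph (TMFG) -> binarized
(unweighted, undirected) network.

Cosine similarity between two word columns A and B over participants j is

    cos(a, b) = sum_j A_j B_j / (sqrt(sum_j A_j^2) * sqrt(sum_j B_j^2)),

which for binary data is the co-production count normalized by the geometric
mean of the production counts, hence always in [0, 1].

The TMFG is a greedy planar filter: seed with the 4-clique of maximum total
pairwise similarity, then repeatedly insert the remaining node that gains the
most total similarity to one of the current triangular faces, connecting it to
that face's three vertices.  The result is a maximal planar graph with exactly
3n - 6 edges, connected, with minimum degree 3; it keeps the strongest
associations while discarding spurious weak ones.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Above this many nodes the seed 4-clique is chosen greedily instead of by
#: exhaustive enumeration of all 4-subsets.
EXACT_SEED_LIMIT = 25


def cosine_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Word-by-word cosine similarity of a binary incidence matrix.

    Parameters
    ----------
    matrix
        Participants x words DataFrame with cells in {0, 1}.  Every word
        column must have at least one producer (guaranteed by equating).

    Returns
    -------
    DataFrame
        Symmetric words x words similarity with unit diagonal, entries in [0, 1].
    """
    if matrix.shape[1] < 2:
        raise ValidationError("cosine similarity needs at least 2 word columns")
    a = matrix.to_numpy(dtype=float)
    norms = np.sqrt((a * a).sum(axis=0))
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValidationError(
            f"word column(s) with no producers: {', '.join(matrix.columns[zero[:5]])}"
        )
    sim = (a.T @ a) / np.outer(norms, norms)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip(sim, 0.0, 1.0)
    return pd.DataFrame(sim, index=matrix.columns, columns=matrix.columns)


def _seed_clique(w: np.ndarray) -> list[int]:
    """Best 4-clique: exact enumeration for small n, weighted-degree greedy above."""
    n = w.shape[0]
    if n <= EXACT_SEED_LIMIT:
        quads = np.fromiter(
            (i for quad in combinations(range(n), 4) for i in quad),
            dtype=np.intp,
        ).reshape(-1, 4)
        score = np.zeros(len(quads))
        for a, b in combinations(range(4), 2):
            score += w[quads[:, a], quads[:, b]]
        # argmax returns the first maximum; combinations() is lexicographic,
        # so ties resolve to the least 4-subset
        return quads[int(np.argmax(score))].tolist()
    degree = w.sum(axis=1)
    # stable sort on (-degree, index) keeps ties in index order
    order = np.lexsort((np.arange(n), -degree))
    return sorted(int(i) for i in order[:4])


def tmfg_filter(sim: pd.DataFrame) -> nx.Graph:
    """Triangulated Maximally Filtered Graph of a similarity matrix.

    Greedy construction: (i) seed with the 4-clique maximizing total pairwise
    similarity; (ii) while uninserted nodes remain, insert the (node, face)
    pair maximizing the node's summed similarity to the face's three vertices,
    adding those three edges and replacing the face with three new faces.
    Ties are broken by node order (lexicographic in the matrix's labels), so
    the output is reproducible across runs and platforms.

    Returns a weighted :class:`networkx.Graph` whose edge ``weight`` attributes
    are the original similarities; exactly ``3n - 6`` edges, planar, connected,
    minimum degree 3.

    Raises
    ------
    ValidationError
        For fewer than 4 nodes, an asymmetric matrix, or negative entries.
    """
    labels = list(sim.index)
    w = sim.to_numpy(dtype=float).copy()
    n = w.shape[0]
    if n < 4:
        raise ValidationError(f"TMFG needs at least 4 nodes, got {n}")
    if w.shape[0] != w.shape[1] or not np.allclose(w, w.T, atol=1e-12):
        raise ValidationError("similarity matrix must be square and symmetric")
    if (w < 0).any():
        raise ValidationError("similarity matrix must be non-negative")
    np.fill_diagonal(w, 0.0)

    seed = _seed_clique(w)
    edges: list[tuple[int, int]] = [tuple(sorted(p)) for p in combinations(seed, 2)]
    a, b, c, d = seed
    faces: list[tuple[int, int, int]] = [(a, b, c), (a, b, d), (a, c, d), (b, c, d)]

    # gains[v, f] = summed similarity of node v to face f's three vertices;
    # rows of inserted nodes are masked with -1 (similarities are non-negative).
    n_faces_final = 2 * n - 4  # 4 seed faces + 2 per insertion
    gains = np.full((n, n_faces_final), -1.0)
    inserted = np.zeros(n, dtype=bool)
    inserted[seed] = True
    for fi, f in enumerate(faces):
        gains[:, fi] = w[:, f].sum(axis=1)
    gains[inserted, :] = -1.0
    n_faces = 4
    for _ in range(n - 4):
        # first flat argmax = least (node, face-slot) pair: deterministic ties
        flat = int(np.argmax(gains[:, :n_faces]))
        v, fi = divmod(flat, n_faces)
        face = faces[fi]
        inserted[v] = True
        gains[v, :] = -1.0
        for u in face:
            edges.append(tuple(sorted((u, v))))
        x, y, z = face
        # the removed face's slot is reused by one child face; two are appended
        for slot, child in zip((fi, n_faces, n_faces + 1),
                               ((x, y, v), (x, z, v), (y, z, v))):
            child = tuple(sorted(child))
            if slot == fi:
                faces[fi] = child
            else:
                faces.append(child)
            gains[:, slot] = w[:, child].sum(axis=1)
            gains[inserted, slot] = -1.0
        n_faces += 2

    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, j in edges:
        g.add_edge(labels[i], labels[j], weight=float(sim.iat[i, j]))
    return g


def binarize(g: nx.Graph) -> nx.Graph:
    """Drop edge weights, keeping the edge set: the unweighted network.

    Adjacency is defined by edge *presence*; a zero-weight edge retained by
    the planar filter stays in the binarized graph.
    """
    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    out.add_edges_from(g.edges())
    return out


def estimate_network(matrix: pd.DataFrame) -> nx.Graph:
    """Incidence matrix -> cosine similarity -> TMFG -> unweighted network."""
    return binarize(tmfg_filter(cosine_similarity(matrix)))
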