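"""Independent brute-force reference for directed message passing.

Plain Python loops over every atom and directed bond -- no segment sums, no
index tricks -- so it can serve as the oracle the vectorized encoder is
checked against.  Also builds random small molecular graphs directly
(without a chemistry toolkit) for property tests.
"""

import numpy as np

from cpifuse.featurize import ATOM_FDIM, BOND_FDIM, MolGraph


def relu(x):
    return np.maximum(x, 0.0)


def dense_dmpnn(graph: MolGraph, weights: dict, depth: int) -> np.ndarray:
    """Reference O_Gs for one graph given the encoder's weight arrays.

    weights: W_in, b_in, A_W, A_b (atom projection), W_m, b_m.
    """
    nb = graph.n_directed_bonds
    na = graph.n_atoms
    H = weights["b_in"].shape[0]

    h0 = {}
    for b in range(nb):
        x = graph.atom_feats[graph.src[b]]
        e = graph.bond_feats[b]
        h0[b] = relu(np.concatenate([x, e]) @ weights["W_in"] + weights["b_in"])
    xt = {a: graph.atom_feats[a] @ weights["A_W"] + weights["A_b"]
          for a in range(na)}

    h = dict(h0)
    for _ in range(depth):
        m = {}
        for b in range(nb):
            v = graph.src[b]
            acc = np.zeros(H)
            for kb in range(nb):
                # bonds k -> v, excluding the reverse of b (no backtracking)
                if graph.dst[kb] == v and kb != graph.rev[b]:
                    k = graph.src[kb]
                    acc = acc + (xt[v] + xt[k] + h[kb]) / 3.0
            m[b] = acc
        h = {b: relu(h0[b] + m[b] @ weights["W_m"] + weights["b_m"])
             for b in range(nb)}

    atom_vecs = []
    for a in range(na):
        incoming = [b for b in range(nb) if graph.dst[b] == a]
        if incoming:
            atom_vecs.append(np.mean([h[b] for b in incoming], axis=0))
        else:
            atom_vecs.append(np.zeros(H))
    return np.mean(atom_vecs, axis=0) if na else np.zeros(H)


def encoder_weights(encoder) -> dict:
    return {
        "W_in": encoder.W_in.W.data, "b_in": encoder.W_in.b.data,
        "A_W": encoder.atom_proj.W.data, "A_b": encoder.atom_proj.b.data,
        "W_m": encoder.W_m.W.data, "b_m": encoder.W_m.b.data,
    }


def random_molgraph(rng: np.random.Generator, max_atoms: int = 6) -> MolGraph:
    """Random connected undirected graph with random feature vectors."""
    n = int(rng.integers(1, max_atoms + 1))
    edges = set()
    for a in range(1, n):  # random spanning tree keeps it connected
        b = int(rng.integers(0, a))
        edges.add((b, a))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.add((min(a, b), max(a, b)))

    atom_feats = rng.normal(size=(n, ATOM_FDIM))
    src, dst, rev, bfeats = [], [], [], []
    for (a, b) in sorted(edges):
        e = rng.normal(size=BOND_FDIM)
        i = len(src)
        src += [a, b]
        dst += [b, a]
        rev += [i + 1, i]
        bfeats += [e, e]
    nb = len(src)
    incoming = [[] for _ in range(n)]
    for bidx, a in enumerate(dst):
        incoming[a].append(bidx)
    return MolGraph(
        n_atoms=n, n_directed_bonds=nb, atom_feats=atom_feats,
        bond_feats=np.asarray(bfeats) if bfeats else np.zeros((0, BOND_FDIM)),
        src=np.asarray(src, dtype=np.intp), dst=np.asarray(dst, dtype=np.intp),
        rev=np.asarray(rev, dtype=np.intp), incoming=incoming,
    )


def permute_molgraph(graph: MolGraph, perm: np.ndarray) -> MolGraph:
    """Relabel atoms by ``perm`` (atom i -> perm[i])."""
    n = graph.n_atoms
    inv = np.empty(n, dtype=np.intp)
    inv[perm] = np.arange(n)
    atom_feats = graph.atom_feats[inv]
    src = perm[graph.src]
    dst = perm[graph.dst]
    incoming = [[] for _ in range(n)]
    for b, a in enumerate(dst):
        incoming[a].append(b)
    return MolGraph(
        n_atoms=n, n_directed_bonds=graph.n_directed_bonds,
        atom_feats=atom_feats, bond_feats=graph.bond_feats,
        src=src, dst=dst, rev=graph.rev, incoming=incoming,
    )
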