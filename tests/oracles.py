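"""Independent reference implementations used by several test modules.

These deliberately avoid the package's own data structures and
shortcuts (k-mer indexes, pruned searches) so they can serve as oracles.
"""

import numpy as np


def brute_force_recruit(query, spots, params):
    """Recruitment oracle: test every seed position pair explicitly."""
    from Bio.Seq import Seq

    def translations(nt):
        out = []
        for s in (nt, str(Seq(nt).reverse_complement())):
            for f in range(3):
                sub = s[f:]
                sub = sub[: len(sub) - len(sub) % 3]
                if sub:
                    out.append(str(Seq(sub).translate()))
        return out

    hits = set()
    if query.alphabet == "protein":
        k = params.aa_seed_length
        q = query.residues.upper()
        for spot in spots:
            for mi, mate in enumerate(spot.mates):
                for t in translations(mate.upper()):
                    for i in range(len(t) - k + 1):
                        if t[i : i + k] in q:
                            hits.add((spot.spot_id, mi))
    else:
        k = params.nt_seed_length
        q = query.residues.upper()
        qr = str(Seq(q).reverse_complement())
        for spot in spots:
            for mi, mate in enumerate(spot.mates):
                m = mate.upper()
                for i in range(len(m) - k + 1):
                    if m[i : i + k] in q or m[i : i + k] in qr:
                        hits.add((spot.spot_id, mi))
    return hits


def random_additive_tree(n, rng):
    """Random edge-weighted binary tree and its exact leaf path metric."""
    import networkx as nx

    G = nx.Graph()
    G.add_edge("L0", "L1", weight=float(rng.uniform(0.5, 2)))
    inner = 0
    for k in range(2, n):
        edges = list(G.edges(data=True))
        u, v, dat = edges[rng.integers(len(edges))]
        G.remove_edge(u, v)
        inner += 1
        mid = f"I{inner}"
        f = float(rng.uniform(0.2, 0.8))
        G.add_edge(u, mid, weight=dat["weight"] * f)
        G.add_edge(mid, v, weight=dat["weight"] * (1 - f))
        G.add_edge(mid, f"L{k}", weight=float(rng.uniform(0.5, 2)))
    leaves = [f"L{i}" for i in range(n)]
    dd = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
    mat = np.array([[dd[a][b] for b in leaves] for a in leaves])
    mat = (mat + mat.T) / 2  # exact symmetry despite float summation order
    np.fill_diagonal(mat, 0.0)
    return leaves, mat
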