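"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimized code paths: formula
candidates come from a full element-grid sweep, peak clustering from an
explicit pairwise graph, and modularity from exhaustive set-partition
enumeration.
"""

import itertools

import networkx as nx
import numpy as np

from deepdom.formulas import ELEMENT_MASS, MolecularFormula

_mC, _mH, _mN, _mO, _mS, _mP = (ELEMENT_MASS[e] for e in "CHNOSP")

# full C x H x O mass grid, shared across queries
_C = np.arange(1, 101)
_H = np.arange(1, 101)
_O = np.arange(0, 71)
_CHO_MASS = (_C[:, None, None] * _mC + _H[None, :, None] * _mH
             + _O[None, None, :] * _mO)


def brute_force_candidates(neutral_mass, tol_ppm=0.5, o_le_c_plus_2=True):
    """Every valid CHNOSP formula within tol_ppm, by full grid sweep,
    sorted by (|ppm error|, heteroatoms, atom count, formula string)."""
    tol_da = neutral_mass * tol_ppm * 1e-6
    found = []
    for n in range(5):
        for s in range(3):
            for p in range(2):
                m = _CHO_MASS + (n * _mN + s * _mS + p * _mP)
                ci, hi, oi = np.nonzero(np.abs(m - neutral_mass) <= tol_da)
                for a, b, c in zip(ci, hi, oi):
                    f = MolecularFormula(c=int(a + 1), h=int(b + 1), n=n,
                                         o=int(c), s=s, p=p)
                    if f.is_valid(o_le_c_plus_2=o_le_c_plus_2):
                        found.append(f)

    def key(f):
        err = abs((f.mass - neutral_mass) / neutral_mass * 1e6)
        return (err, f.heteroelements, f.n_atoms, str(f))

    found.sort(key=key)
    return found


def brute_force_heteroelement_rule(f, max_hetero=3):
    return f.heteroelements <= max_hetero or (f.s == 0 and f.p == 0 and f.n <= 4)


def brute_force_clusters(mz, tol_ppm, max_span_ppm):
    """Single-linkage clustering of masses from the explicit pairwise
    <=tol graph (ppm relative to the smaller mass), each connected
    component then greedily split so no piece spans more than
    max_span_ppm. Returns a list of index arrays."""
    mz = np.asarray(mz, float)
    g = nx.Graph()
    g.add_nodes_from(range(len(mz)))
    for i, j in itertools.combinations(range(len(mz)), 2):
        lo, hi = sorted((mz[i], mz[j]))
        if (hi - lo) / lo * 1e6 <= tol_ppm:
            g.add_edge(i, j)
    pieces = []
    for comp in nx.connected_components(g):
        order = sorted(comp, key=lambda k: (mz[k], k))
        start = None
        for idx in order:
            if start is None or (mz[idx] - mz[start]) / mz[start] * 1e6 > max_span_ppm:
                pieces.append([idx])
                start = idx
            else:
                pieces[-1].append(idx)
    return [np.array(p) for p in pieces]


def _set_partitions(items):
    """All partitions of a list (Bell-number many; keep len(items) small)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def exhaustive_best_modularity(graph):
    """Max Newman-Girvan modularity over all node partitions."""
    nodes = sorted(graph.nodes, key=str)
    best_q, best_part = -np.inf, None
    for part in _set_partitions(nodes):
        q = nx.community.modularity(graph, [set(b) for b in part], weight=None)
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part
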