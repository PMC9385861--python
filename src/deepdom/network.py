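"""Microbe-metabolite proportionality network.

Molecular formulas (MFs) and amplicon sequence variants (ASVs) are linked
through the proportionality measure rho computed on centered log-ratio
(clr) transformed profiles, with each compositional block transformed
separately. The |rho| cutoff for network construction is chosen by a
permutation estimate of the false-discovery rate; modules come from
fast-greedy modularity maximization and nodes are classified by
within-module degree z-score and among-module participation coefficient P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ClrMatrix",
    "InterdomainNetwork",
    "FdrResult",
    "prevalence_filter",
    "replace_zeros",
    "clr_transform",
    "stack_blocks",
    "proportionality_rho",
    "fdr_cutoff",
    "build_network",
    "greedy_modularity",
    "node_roles",
    "module_summary",
    "interdomain_network",
    "write_graphml",
    "write_edgelist",
]

ROLE_THRESH_Z = 2.5
ROLE_THRESH_P = 0.62


@dataclass
class ClrMatrix:
    """clr-transformed features x samples block(s).

    ``blocks`` labels each feature row with its source block (e.g. "MF" or
    "ASV"); each block's sample columns sum to zero separately.
    """

    values: pd.DataFrame
    blocks: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.blocks) != len(self.values):
            raise ValueError("blocks must label every feature row")


def prevalence_filter(mf_matrix: pd.DataFrame, asv_table: pd.DataFrame,
                      min_samples: int = 5, min_abundance: float = 0.001
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep MFs/ASVs present in >= ``min_samples`` samples and drop ASVs
    whose maximum relative abundance is below ``min_abundance``.

    Both tables are features x samples over an identical sample set (any
    non-numeric ``taxonomy`` column of the ASV table is carried along).
    """
    tax = asv_table["taxonomy"] if "taxonomy" in asv_table.columns else None
    asv_num = asv_table.drop(columns=["taxonomy"], errors="ignore")
    if sorted(map(str, mf_matrix.columns)) != sorted(map(str, asv_num.columns)):
        raise ValueError("MF matrix and ASV table must share the same sample set")
    asv_num = asv_num[mf_matrix.columns]
    mf_keep = (mf_matrix > 0).sum(axis=1) >= min_samples
    asv_keep = ((asv_num > 0).sum(axis=1) >= min_samples) & (asv_num.max(axis=1) >= min_abundance)
    mf_out = mf_matrix.loc[mf_keep]
    asv_out = asv_num.loc[asv_keep]
    if tax is not None:
        asv_out = asv_out.assign(taxonomy=tax.loc[asv_keep])
    return mf_out, asv_out


def replace_zeros(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace zeros in each feature row by that row's minimum nonzero
    value divided by 10 (a multiplicative pseudo-count for clr)."""
    x = matrix.to_numpy(float).copy()
    allzero = ~(x > 0).any(axis=1)
    if allzero.any():
        bad = [str(matrix.index[i]) for i in np.flatnonzero(allzero)]
        raise ValueError(f"all-zero features cannot be zero-replaced: {bad}")
    mins = np.where(x > 0, x, np.inf).min(axis=1)
    x = np.where(x == 0, mins[:, None] / 10.0, x)
    return pd.DataFrame(x, index=matrix.index, columns=matrix.columns)


def clr_transform(matrix: pd.DataFrame, block: str = "", provenance: str = "") -> ClrMatrix:
    """Centered log-ratio transform per sample column: log(x) minus the
    mean log over this block's features."""
    x = matrix.to_numpy(float)
    if (x <= 0).any():
        raise ValueError("clr requires strictly positive entries (run replace_zeros first)")
    logs = np.log(x)
    out = logs - logs.mean(axis=0, keepdims=True)
    values = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    blocks = pd.Series(block or "block", index=matrix.index)
    return ClrMatrix(values=values, blocks=blocks, provenance=provenance)


def stack_blocks(*blocks: ClrMatrix) -> ClrMatrix:
    """Stack separately transformed blocks into one combined clr matrix."""
    cols = list(blocks[0].values.columns)
    for b in blocks[1:]:
        if list(b.values.columns) != cols:
            raise ValueError("blocks must share the same sample columns in order")
    values = pd.concat([b.values for b in blocks], axis=0)
    labels = pd.concat([b.blocks for b in blocks], axis=0)
    if values.index.duplicated().any():
        raise ValueError("duplicate feature ids across blocks")
    return ClrMatrix(values=values, blocks=labels,
                     provenance="; ".join(filter(None, (b.provenance for b in blocks))))


def proportionality_rho(combined: ClrMatrix) -> pd.DataFrame:
    """Proportionality rho between all feature pairs.

    rho(i, j) = 1 - var(g_i - g_j) / (var g_i + var g_j) over samples,
    equivalently 2 cov(g_i, g_j) / (var g_i + var g_j); unit diagonal.
    Pairs involving a zero-variance feature get rho = 0 (flagged).
    """
    g = combined.values.to_numpy(float)
    n = g.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for proportionality")
    gc = g - g.mean(axis=1, keepdims=True)
    cov = gc @ gc.T / (n - 1)
    var = np.diag(cov).copy()
    denom = var[:, None] + var[None, :]
    zerovar = var <= 0
    if zerovar.any():
        warnings.warn(f"{int(zerovar.sum())} zero-variance features; their rho set to 0",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, 2.0 * cov / denom, 0.0)
    rho[zerovar, :] = 0.0
    rho[:, zerovar] = 0.0
    np.fill_diagonal(rho, 1.0)
    idx = combined.values.index
    return pd.DataFrame(rho, index=idx, columns=idx)


@dataclass
class FdrResult:
    cutoff: float
    target_fdr: float
    achieved: bool
    table: pd.DataFrame  # columns: cutoff, n_observed, mean_n_permuted, fdr
    n_permutations: int
    seed: int | None


def fdr_cutoff(combined: ClrMatrix, n_perm: int = 100, target_fdr: float = 0.05,
               grid: np.ndarray | None = None, seed: int | None = None,
               permute_block: str | None = None) -> FdrResult:
    """Choose the |rho| cutoff by permutation false-discovery rate.

    Only between-block pairs are counted. Permutations shuffle the sample
    labels of one block (the last block by default), preserving each
    block's internal covariance. FDR(c) is the permutation-mean count of
    |rho| >= c divided by the observed count (0 when nothing is observed
    at c); the smallest grid cutoff with FDR < ``target_fdr`` is returned,
    or the grid maximum with a warning when no cutoff reaches the target.
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    labels = combined.blocks.unique()
    if len(labels) != 2:
        raise ValueError(f"fdr_cutoff expects exactly two blocks, got {list(labels)}")
    if grid is None:
        grid = np.round(np.arange(0.30, 0.991, 0.01), 2)
    grid = np.sort(np.asarray(grid, float))
    if permute_block is None:
        permute_block = labels[-1]

    a_mask = (combined.blocks == permute_block).to_numpy()
    g = combined.values.to_numpy(float)
    n = g.shape[1]
    gc = g - g.mean(axis=1, keepdims=True)
    var = (gc ** 2).sum(axis=1) / (n - 1)
    fixed, moving = gc[~a_mask], gc[a_mask]
    vfixed, vmoving = var[~a_mask], var[a_mask]
    denom = vfixed[:, None] + vmoving[None, :]
    denom[denom <= 0] = np.inf

    def cross_abs_rho(mov: np.ndarray) -> np.ndarray:
        cov = fixed @ mov.T / (n - 1)
        return np.abs(2.0 * cov / denom)

    obs = cross_abs_rho(moving)
    n_obs = np.array([(obs >= c).sum() for c in grid], dtype=float)

    rng = np.random.default_rng(seed)
    perm_counts = np.zeros_like(n_obs)
    for _ in range(n_perm):
        perm = cross_abs_rho(moving[:, rng.permutation(n)])
        perm_counts += np.array([(perm >= c).sum() for c in grid], dtype=float)
    mean_perm = perm_counts / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_obs > 0, mean_perm / n_obs, 0.0)

    table = pd.DataFrame({"cutoff": grid, "n_observed": n_obs,
                          "mean_n_permuted": mean_perm, "fdr": fdr})
    ok = np.flatnonzero(fdr < target_fdr)
    if len(ok):
        cutoff, achieved = float(grid[ok[0]]), True
    else:
        cutoff, achieved = float(grid[-1]), False
        warnings.warn(f"no cutoff on the grid achieves FDR < {target_fdr}; "
                      f"returning the grid maximum {cutoff}", stacklevel=2)
    return FdrResult(cutoff=cutoff, target_fdr=target_fdr, achieved=achieved,
                     table=table, n_permutations=n_perm, seed=seed)


def build_network(rho: pd.DataFrame, cutoff: float = 0.85,
                  node_metadata: pd.DataFrame | None = None) -> nx.Graph:
    """Graph of all feature pairs with |rho| >= cutoff.

    Nodes are features with at least one passing edge; edges carry ``rho``
    and ``sign``. ``node_metadata`` (indexed by feature id) columns are
    attached as node attributes (e.g. kind, taxonomy, formula).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    r = rho.to_numpy(float)
    ids = list(rho.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    hit = np.abs(r[iu, ju]) >= cutoff
    g = nx.Graph()
    for i, j in zip(iu[hit], ju[hit]):
        val = float(r[i, j])
        g.add_edge(ids[i], ids[j], rho=val, sign=1 if val >= 0 else -1)
    if g.number_of_nodes() == 0:
        warnings.warn("no edge reaches the cutoff; network is empty", stacklevel=2)
    if node_metadata is not None:
        for node in g.nodes:
            if node in node_metadata.index:
                for col, val in node_metadata.loc[node].items():
                    if pd.notna(val):
                        g.nodes[node][col] = val
    return g


def greedy_modularity(net: nx.Graph) -> tuple[dict, float]:
    """Fast-greedy (agglomerative) modularity maximization on the
    unweighted edge set.

    Returns (node -> module id, Q). Module ids are assigned by decreasing
    module size with the smallest member node breaking ties, so the
    labeling is deterministic.
    """
    if net.number_of_edges() == 0:
        raise ValueError("modularity needs at least one edge")
    communities = nx.community.greedy_modularity_communities(net, weight=None)
    communities = sorted((sorted(c, key=str) for c in communities),
                         key=lambda c: (-len(c), str(c[0])))
    partition = {node: i for i, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(net, communities, weight=None)
    return partition, float(q)


def node_roles(net: nx.Graph, partition: dict, scheme: str = "canonical") -> pd.DataFrame:
    """Classify nodes by within-module degree z-score and participation P.

    z is the node's within-module degree standardized against its module
    (population sd; z = 0 for sd 0 or singleton modules); P = 1 - sum over
    modules of (fraction of the node's edges into that module)^2, with
    P = 0 for isolated nodes. The canonical scheme labels peripheral
    (z <= 2.5, P <= 0.62), connector (z <= 2.5, P > 0.62), module hub
    (z > 2.5, P <= 0.62) and network hub (z > 2.5, P > 0.62). The
    ``"printed"`` variant applies the overlapping published thresholds in
    order and labels the z > 2.5, P < 0.62 corner "unclassified".
    """
    missing = [n for n in net.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    modules: dict[int, list] = {}
    for node, m in partition.items():
        if node in net:
            modules.setdefault(m, []).append(node)

    within = {}
    for m, members in modules.items():
        mset = set(members)
        kappa = {v: sum(1 for u in net.neighbors(v) if u in mset) for v in members}
        vals = np.array(list(kappa.values()), float)
        mu, sd = vals.mean(), vals.std(ddof=0)
        for v in members:
            within[v] = (kappa[v] - mu) / sd if sd > 0 else 0.0

    rows = []
    for v in net.nodes:
        k = net.degree(v)
        if k == 0:
            pcoef = 0.0
        else:
            counts: dict[int, int] = {}
            for u in net.neighbors(v):
                counts[partition[u]] = counts.get(partition[u], 0) + 1
            pcoef = 1.0 - sum((c / k) ** 2 for c in counts.values())
        z = within[v]
        if scheme == "canonical":
            if z <= ROLE_THRESH_Z:
                role = "peripheral" if pcoef <= ROLE_THRESH_P else "connector"
            else:
                role = "module hub" if pcoef <= ROLE_THRESH_P else "network hub"
        elif scheme == "printed":
            if z <= ROLE_THRESH_Z and pcoef <= ROLE_THRESH_P:
                role = "peripheral"
            elif z <= ROLE_THRESH_Z:
                role = "connector"
            elif pcoef >= ROLE_THRESH_P:
                role = "module hub" if pcoef == ROLE_THRESH_P else "network hub"
            else:
                role = "unclassified"
        else:
            raise ValueError(f"unknown role scheme {scheme!r}")
        rows.append({"node": v, "module": partition[v], "degree": k,
                     "z": z, "p": pcoef, "role": role})
    return pd.DataFrame(rows).set_index("node")


@dataclass
class InterdomainNetwork:
    """Bipartite-domain association network with modules and node roles."""

    graph: nx.Graph
    cutoff: float
    partition: dict = field(default_factory=dict)
    modularity: float = float("nan")
    roles: pd.DataFrame | None = None
    rho: pd.DataFrame | None = None
    fdr: FdrResult | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_modules(self) -> int:
        return len(set(self.partition.values()))

    def node_kinds(self) -> pd.Series:
        return pd.Series({n: self.graph.nodes[n].get("kind", "?") for n in self.graph.nodes})


def module_summary(net: InterdomainNetwork) -> pd.DataFrame:
    """Per-module node counts by kind and compound-class composition."""
    rows = []
    for m in sorted(set(net.partition.values())):
        members = [n for n, mm in net.partition.items() if mm == m and n in net.graph]
        kinds = [net.graph.nodes[n].get("kind", "?") for n in members]
        classes = [net.graph.nodes[n].get("compound_class") for n in members
                   if net.graph.nodes[n].get("kind") == "MF"]
        classes = [c for c in classes if c]
        top = max(set(classes), key=classes.count) if classes else ""
        rows.append({"module": m, "n_nodes": len(members),
                     "n_mf": kinds.count("MF"), "n_asv": kinds.count("ASV"),
                     "dominant_class": top})
    return pd.DataFrame(rows)


def interdomain_network(mf_matrix: pd.DataFrame, asv_table: pd.DataFrame,
                        min_samples: int = 5, min_abundance: float = 0.001,
                        cutoff: float | None = 0.85, n_perm: int = 100,
                        target_fdr: float = 0.05, seed: int | None = None,
                        node_metadata: pd.DataFrame | None = None,
                        role_scheme: str = "canonical") -> InterdomainNetwork:
    """Full chain: prevalence filter -> zero replacement -> separate clr ->
    rho -> cutoff (given, or permutation-FDR when ``cutoff`` is None) ->
    graph -> fast-greedy modules -> z/P roles."""
    mf, asv = prevalence_filter(mf_matrix, asv_table, min_samples, min_abundance)
    tax = asv["taxonomy"] if "taxonomy" in asv.columns else None
    asv = asv.drop(columns=["taxonomy"], errors="ignore")
    if mf.empty or asv.empty:
        raise ValueError("prevalence filter removed an entire block")
    mf_clr = clr_transform(replace_zeros(mf), block="MF", provenance="mf: min/10 zero replacement")
    asv_clr = clr_transform(replace_zeros(asv), block="ASV", provenance="asv: min/10 zero replacement")
    combined = stack_blocks(mf_clr, asv_clr)
    rho = proportionality_rho(combined)
    fdr = None
    if cutoff is None:
        fdr = fdr_cutoff(combined, n_perm=n_perm, target_fdr=target_fdr, seed=seed,
                         permute_block="ASV")
        cutoff = fdr.cutoff

    meta = pd.DataFrame({"kind": combined.blocks})
    if tax is not None:
        meta.loc[tax.index, "taxonomy"] = tax
    if node_metadata is not None:
        meta = meta.join(node_metadata, how="left")
    g = build_network(rho, cutoff=cutoff, node_metadata=meta)
    if g.number_of_edges():
        partition, q = greedy_modularity(g)
        roles = node_roles(g, partition, scheme=role_scheme)
        for node in g.nodes:
            g.nodes[node]["module"] = int(partition[node])
            g.nodes[node]["z"] = float(roles.loc[node, "z"])
            g.nodes[node]["p"] = float(roles.loc[node, "p"])
            g.nodes[node]["role"] = str(roles.loc[node, "role"])
    else:
        partition, q, roles = {}, float("nan"), None
    return InterdomainNetwork(graph=g, cutoff=float(cutoff), partition=partition,
                              modularity=q, roles=roles, rho=rho, fdr=fdr)


def write_graphml(net: InterdomainNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_edgelist(net: InterdomainNetwork, path: str | Path) -> None:
    rows = [{"source": u, "target": v, "rho": d["rho"], "sign": d["sign"]}
            for u, v, d in net.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "rho", "sign"]).to_csv(
        path, sep="\t", index=False)
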