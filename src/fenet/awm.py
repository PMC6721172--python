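"""Association weight matrix (AWM) and PCIT co-association network.

The AWM collects, for the SNPs surviving a multi-trait selection rule, the
signed z-scores of their allele-substitution effects across the nine
analysed traits. Column-wise correlations recover trait relationships from
SNP effects; row-wise correlations between SNP profiles feed the PCIT
(partial correlation and information theory) algorithm, which keeps an edge
only when its correlation cannot be explained through any third node.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from fenet.simdata import SnpAnnotation

__all__ = [
    "AWMatrix",
    "CoAssocNetwork",
    "select_awm_snps",
    "trait_structure",
    "pcit",
    "pcit_reference",
    "partial_correlation",
    "hub_ranking",
    "linkage_to_newick",
]


@dataclass
class AWMatrix:
    """Retained-SNP x trait z-score matrix with selection provenance."""

    z: pd.DataFrame            # index snp, columns traits
    provenance: pd.DataFrame   # per snp: key_significant, n_other_significant,
                               # gene, distance, tf

    @property
    def snps(self) -> list[str]:
        return list(self.z.index)

    @property
    def traits(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class CoAssocNetwork:
    """Undirected weighted network of AWM rows surviving PCIT."""

    nodes: list[str]
    edges: pd.DataFrame        # node_a, node_b, weight (raw correlation)
    aggregation: str = "any"
    labels: dict[str, str] = field(default_factory=dict)  # snp -> gene label

    def degree(self) -> pd.Series:
        counts = pd.Series(0, index=self.nodes, dtype=int)
        for col in ("node_a", "node_b"):
            vc = self.edges[col].value_counts()
            counts = counts.add(vc, fill_value=0)
        return counts.astype(int)

    def neighbors(self, node: str) -> set[str]:
        e = self.edges
        out = set(e.loc[e["node_a"] == node, "node_b"])
        out |= set(e.loc[e["node_b"] == node, "node_a"])
        return out


def select_awm_snps(
    scans: dict[str, pd.DataFrame],
    annotation: SnpAnnotation,
    key_trait: str = "RFI",
    p_thresh: float = 0.05,
    min_other: int = 3,
    max_dist: int = 10_000,
) -> AWMatrix:
    """Apply the AWM retention rule and assemble the z-score matrix.

    A SNP is retained iff it is nominally associated (p < ``p_thresh``) with
    the key trait OR with at least ``min_other`` of the remaining traits,
    AND it lies within ``max_dist`` bp of its nearest annotated gene. Cells
    hold signed z-scores for *all* traits, significant or not.
    """
    if key_trait not in scans:
        raise ValueError(f"key trait {key_trait!r} missing from scans")
    traits = [key_trait] + [t for t in scans if t != key_trait]
    universe = scans[key_trait]["snp"].to_numpy()
    for t, df in scans.items():
        if not np.array_equal(df["snp"].to_numpy(), universe):
            raise ValueError(f"scan for {t!r} does not share the SNP universe")

    pmat = pd.DataFrame(
        {t: scans[t]["p"].to_numpy() for t in traits}, index=universe
    )
    zmat = pd.DataFrame(
        {t: scans[t]["z"].to_numpy() for t in traits}, index=universe
    )
    key_sig = pmat[key_trait] < p_thresh
    n_other = (pmat.drop(columns=key_trait) < p_thresh).sum(axis=1)
    rule = key_sig | (n_other >= min_other)

    ann = annotation.snp_genes.set_index("snp").reindex(universe)
    near = ann["distance"].notna() & (ann["distance"] <= max_dist)
    keep = rule & near.to_numpy()

    z = zmat.loc[keep]
    prov = pd.DataFrame({
        "key_significant": key_sig.loc[keep],
        "n_other_significant": n_other.loc[keep],
        "gene": ann.loc[keep.to_numpy(), "gene"],
        "distance": ann.loc[keep.to_numpy(), "distance"],
        "tf": ann.loc[keep.to_numpy(), "tf"].fillna(False).astype(bool),
    })
    return AWMatrix(z=z, provenance=prov)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def trait_structure(awm: AWMatrix) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Trait correlation matrix and complete-linkage dendrogram (1 - r).

    Returns the trait x trait Pearson correlation matrix of AWM columns, the
    scipy linkage matrix, and the dendrogram serialized as Newick.
    """
    if len(awm.z) < 3:
        raise ValueError("need at least 3 AWM rows to compute trait structure")
    const = awm.z.std(ddof=0) == 0
    if const.any():
        warnings.warn(
            f"constant AWM columns (correlation undefined): {list(awm.z.columns[const])}",
            stacklevel=2,
        )
    corr = awm.z.corr()
    # NA correlations (constant columns) enter clustering at maximal distance
    dist = 1.0 - np.nan_to_num(corr.to_numpy(), nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    newick = linkage_to_newick(link, list(corr.columns))
    return corr, link, newick


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z, with degenerate denominators
    clamped."""
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 1e-24:
        denom = 1e-24
    return (r_xy - r_xz * r_yz) / np.sqrt(denom)


def _row_correlations(z: pd.DataFrame) -> np.ndarray:
    profiles = z.to_numpy(float)
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(profiles)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def pcit(
    awm: AWMatrix | pd.DataFrame,
    aggregation: str = "any",
    labels: dict[str, str] | None = None,
) -> CoAssocNetwork:
    """PCIT co-association network from AWM row profiles.

    For every trio (x, y, z) the three first-order partial correlations are
    computed; the trio tolerance is their mean ratio to the raw
    correlations, eps = (r_xy.z/r_xy + r_xz.y/r_xz + r_yz.x/r_yz)/3. Within
    the trio, edge x-y is flagged non-significant when
    |r_xy| <= |eps * r_xz| and |r_xy| <= |eps * r_yz|. With
    ``aggregation='any'`` (the reference behaviour) an edge is discarded as
    soon as one trio flags it; with ``'all'`` it is discarded only when
    every evaluated trio flags it. Trios with a near-zero correlation in a
    tolerance denominator contribute nothing. Surviving edges carry the raw
    correlation as weight.

    Note: with 9-trait profiles each correlation rests on 9 points; its
    sampling significance is not tested — PCIT replaces that test.
    """
    if aggregation not in ("any", "all"):
        raise ValueError("aggregation must be 'any' or 'all'")
    z = awm.z if isinstance(awm, AWMatrix) else awm
    n = len(z)
    if n < 3:
        raise ValueError("PCIT needs at least 3 rows")
    if z.shape[1] <= 12:
        warnings.warn(
            f"row correlations use only n={z.shape[1]} trait points; their "
            "sampling significance is not tested (PCIT replaces it)",
            stacklevel=2,
        )
    R = _row_correlations(z)
    flagged = np.zeros((n, n), dtype=bool)
    evaluated = np.zeros((n, n), dtype=bool)
    surviving = np.ones((n, n), dtype=bool)
    eps_guard = 1e-12
    idx = np.arange(n)
    for k in range(n):
        rz = R[:, k]                             # r_xz for all x
        # partials given the third node, vectorized over the pair (x, y)
        den_z = np.sqrt(np.maximum(np.outer(1 - rz**2, 1 - rz**2), 1e-24))
        P_z = (R - np.outer(rz, rz)) / den_z     # r_xy.z
        # r_xz.y = (r_xz - r_xy r_yz) / sqrt((1-r_xy^2)(1-r_yz^2))
        r_xz = rz[:, None] * np.ones(n)[None, :]   # (x, y) -> r_xz
        r_yz = rz[None, :] * np.ones(n)[:, None]   # (x, y) -> r_yz
        den_xy = np.sqrt(np.maximum((1 - R**2) * (1 - r_yz**2), 1e-24))
        P_xz_y = (r_xz - R * r_yz) / den_xy
        den_yx = np.sqrt(np.maximum((1 - R**2) * (1 - r_xz**2), 1e-24))
        P_yz_x = (r_yz - R * r_xz) / den_yx
        # tolerance: skip trios with near-zero denominators
        valid = (
            (np.abs(R) > eps_guard)
            & (np.abs(r_xz) > eps_guard)
            & (np.abs(r_yz) > eps_guard)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            eps = (P_z / R + P_xz_y / r_xz + P_yz_x / r_yz) / 3.0
        cond = (np.abs(R) <= np.abs(eps * r_xz)) & (np.abs(R) <= np.abs(eps * r_yz))
        cond &= valid
        cond[idx == k] = False
        cond[:, idx == k] = False
        cond[np.eye(n, dtype=bool)] = False
        flagged |= cond
        evaluated |= valid & ~np.eye(n, dtype=bool) & (idx[:, None] != k) & (idx[None, :] != k)
        if aggregation == "any":
            surviving &= ~cond
    if aggregation == "any":
        keep = surviving
    else:
        # discarded only if every evaluated trio flags it; here we need the
        # per-edge count of non-flagging trios, so rerun the accumulation
        keep = _pcit_all_mode(R, eps_guard)
    keep = keep & ~np.eye(n, dtype=bool)
    keep = keep & keep.T
    names = list(z.index)
    ii, jj = np.where(np.triu(keep, 1))
    edges = pd.DataFrame({
        "node_a": [names[i] for i in ii],
        "node_b": [names[j] for j in jj],
        "weight": R[ii, jj],
    })
    return CoAssocNetwork(nodes=names, edges=edges, aggregation=aggregation,
                          labels=labels or {})


def _pcit_all_mode(R: np.ndarray, eps_guard: float) -> np.ndarray:
    """Edge kept unless *every* evaluated trio flags it."""
    n = len(R)
    any_keep = np.zeros((n, n), dtype=bool)
    any_eval = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for k in range(n):
        rz = R[:, k]
        r_xz = rz[:, None] * np.ones(n)[None, :]
        r_yz = rz[None, :] * np.ones(n)[:, None]
        P_z = (R - np.outer(rz, rz)) / np.sqrt(
            np.maximum(np.outer(1 - rz**2, 1 - rz**2), 1e-24)
        )
        P_xz_y = (r_xz - R * r_yz) / np.sqrt(np.maximum((1 - R**2) * (1 - r_yz**2), 1e-24))
        P_yz_x = (r_yz - R * r_xz) / np.sqrt(np.maximum((1 - R**2) * (1 - r_xz**2), 1e-24))
        valid = (
            (np.abs(R) > eps_guard)
            & (np.abs(r_xz) > eps_guard)
            & (np.abs(r_yz) > eps_guard)
        )
        valid &= (idx[:, None] != k) & (idx[None, :] != k) & ~np.eye(n, dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            eps = (P_z / R + P_xz_y / r_xz + P_yz_x / r_yz) / 3.0
        cond = (np.abs(R) <= np.abs(eps * r_xz)) & (np.abs(R) <= np.abs(eps * r_yz))
        any_keep |= valid & ~cond
        any_eval |= valid
    # edges never evaluated by any trio (all guarded) are kept
    return any_keep | ~any_eval


def pcit_reference(
    z: pd.DataFrame, aggregation: str = "any"
) -> pd.DataFrame:
    """Naive triple-loop PCIT used as the independent oracle in tests."""
    R = _row_correlations(z)
    n = len(R)
    flag_any = np.zeros((n, n), dtype=bool)
    keep_any = np.zeros((n, n), dtype=bool)
    evaluated = np.zeros((n, n), dtype=bool)
    guard = 1e-12
    for x, y, k in itertools.combinations(range(n), 3):
        r_xy, r_xk, r_yk = R[x, y], R[x, k], R[y, k]
        if min(abs(r_xy), abs(r_xk), abs(r_yk)) <= guard:
            continue
        p_xy = partial_correlation(r_xy, r_xk, r_yk)
        p_xk = partial_correlation(r_xk, r_xy, r_yk)
        p_yk = partial_correlation(r_yk, r_xy, r_xk)
        for (a, b, r_ab, p_ab, r_ac, r_bc) in (
            (x, y, r_xy, p_xy, r_xk, r_yk),
            (x, k, r_xk, p_xk, r_xy, r_yk),
            (y, k, r_yk, p_yk, r_xy, r_xk),
        ):
            eps = (p_xy / r_xy + p_xk / r_xk + p_yk / r_yk) / 3.0
            evaluated[a, b] = evaluated[b, a] = True
            if abs(r_ab) <= abs(eps * r_ac) and abs(r_ab) <= abs(eps * r_bc):
                flag_any[a, b] = flag_any[b, a] = True
            else:
                keep_any[a, b] = keep_any[b, a] = True
    if aggregation == "any":
        keep = ~flag_any
    else:
        keep = keep_any | ~evaluated
    names = list(z.index)
    ii, jj = np.where(np.triu(keep & ~np.eye(n, dtype=bool), 1))
    return pd.DataFrame({
        "node_a": [names[i] for i in ii],
        "node_b": [names[j] for j in jj],
        "weight": R[ii, jj],
    })


def hub_ranking(
    net: CoAssocNetwork, annotation: SnpAnnotation | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Node degree table, its TF subset ranked by degree, and the mean degree."""
    deg = net.degree()
    table = pd.DataFrame({"node": deg.index, "degree": deg.to_numpy()})
    if annotation is not None:
        ann = annotation.snp_genes.set_index("snp")
        table["gene"] = [
            ann.loc[s, "gene"] if s in ann.index else "" for s in table["node"]
        ]
        table["tf"] = [
            bool(ann.loc[s, "tf"]) if s in ann.index else False for s in table["node"]
        ]
    else:
        table["gene"] = ""
        table["tf"] = False
    table = table.sort_values(["degree", "node"], ascending=[False, True]).reset_index(drop=True)
    tf_table = table[table["tf"]].reset_index(drop=True)
    mean_degree = float(table["degree"].mean()) if len(table) else 0.0
    return table, tf_table, mean_degree
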