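"""Distance-based phylogenetics: p/JC69/K2P distances, neighbor-joining,
bootstrap supports and per-species monophyly assessment.

Distances use pairwise deletion (columns gapped or ambiguous in either
member are excluded).  The Kimura 2-parameter distance separates the
transition proportion P (purine↔purine, pyrimidine↔pyrimidine) from the
transversion proportion Q:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

and is undefined (saturated) when any log argument is non-positive; such
pairs are flagged rather than silently patched.

Neighbor-joining follows the classic Q-criterion formulation with the
standard branch-length and matrix-reduction updates.  Ties in the Q matrix
are broken by the lexicographically smallest active index pair, so output is
deterministic given input order.  Negative branch lengths are clamped to
zero with a warning.

Bootstrap support of an internal edge is the percentage of column-resampled
replicate trees whose bipartition set contains the edge's bipartition.
Trees are :class:`dendropy.Tree` objects; supports live in internal node
labels, so they survive Newick round trips.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import dendropy
import numpy as np

from .alignment import Alignment, StrainTable

Tree = dendropy.Tree

MODELS = ("p", "jc69", "k2p")


# ---------------------------------------------------------------------------
# pairwise distances

def _encode(seq: str) -> np.ndarray:
    lut = np.full(128, 255, dtype=np.uint8)
    for i, ch in enumerate("ACGT"):
        lut[ord(ch)] = i
    arr = lut[np.frombuffer(seq.upper().replace("U", "T").encode(), dtype=np.uint8)]
    return arr


def _pair_counts(a: str, b: str) -> Tuple[int, int, int]:
    """(comparable, transitions, transversions) under pairwise deletion."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    ca, cb = _encode(a), _encode(b)
    both = (ca < 4) & (cb < 4)
    diff = both & (ca != cb)
    # A=0,C=1,G=2,T=3: purines have even code, pyrimidines odd
    ts = diff & ((ca % 2) == (cb % 2))
    return int(both.sum()), int(ts.sum()), int(diff.sum() - ts.sum())


def p_distance(a: str, b: str) -> float:
    c, ts, tv = _pair_counts(a, b)
    if c == 0:
        raise ValueError("no comparable columns")
    return (ts + tv) / c


def jc69_distance(a: str, b: str) -> float:
    p = p_distance(a, b)
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise ValueError(f"JC69 saturated: p={p:.4f}")
    return -0.75 * math.log(arg)


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance in substitutions/site."""
    c, ts, tv = _pair_counts(a, b)
    if c == 0:
        raise ValueError("no comparable columns")
    P, Q = ts / c, tv / c
    return _k2p_from_pq(P, Q)


def _k2p_from_pq(P: float, Q: float) -> float:
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        raise ValueError(f"K2P saturated: P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(a1 * math.sqrt(a2))


@dataclass
class DistanceMatrix:
    """Symmetric substitution-distance matrix; NaN marks undefined pairs."""

    ids: list
    d: np.ndarray
    model: str

    @property
    def undefined_pairs(self) -> list:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.d[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def write_tsv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        with open(path, "w") as fh:
            fh.write(f"# {self.model} distance, substitutions/site, pairwise deletion\n")
            pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(
                fh, sep="\t", float_format="%.6f"
            )


def _site_classes(aln: Alignment) -> np.ndarray:
    """Per-pair per-column class codes for fast (re)computation of distances.

    0 = incomparable, 1 = match, 2 = transition, 3 = transversion; shape
    (n_pairs, length) with pairs in row-major (i < j) order.
    """
    codes = aln.to_codes()
    n, L = codes.shape
    out = np.zeros((n * (n - 1) // 2, L), dtype=np.int8)
    k = 0
    for i in range(n):
        a = codes[i]
        for j in range(i + 1, n):
            b = codes[j]
            both = (a < 4) & (b < 4)
            eq = both & (a == b)
            diff = both & ~eq
            ts = diff & ((a % 2) == (b % 2))
            row = out[k]
            row[eq] = 1
            row[ts] = 2
            row[diff & ~ts] = 3
            k += 1
    return out


def _distances_from_classes(
    classes: np.ndarray, n: int, model: str, cols: Optional[np.ndarray] = None
) -> np.ndarray:
    sub = classes if cols is None else classes[:, cols]
    c = (sub > 0).sum(axis=1).astype(float)
    ts = (sub == 2).sum(axis=1)
    tv = (sub == 3).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = ts / c
        Q = tv / c
        p = P + Q
        if model == "p":
            dvec = p
        elif model == "jc69":
            arg = 1.0 - 4.0 * p / 3.0
            dvec = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), np.nan)
        elif model == "k2p":
            a1 = 1.0 - 2.0 * P - Q
            a2 = 1.0 - 2.0 * Q
            ok = (a1 > 0) & (a2 > 0)
            dvec = np.where(
                ok,
                -0.5 * np.log(np.maximum(a1, 1e-300) * np.sqrt(np.maximum(a2, 1e-300))),
                np.nan,
            )
        else:
            raise ValueError(f"unknown model {model!r}")
    dvec = np.where(c > 0, dvec, np.nan)
    D = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    D[iu] = dvec
    D[(iu[1], iu[0])] = dvec
    return D


def distance_matrix(aln: Alignment, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix under the chosen correction."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    classes = _site_classes(aln)
    D = _distances_from_classes(classes, aln.n_sequences, model)
    return DistanceMatrix(list(aln.ids), D, model)


# ---------------------------------------------------------------------------
# neighbor-joining

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a distance matrix.

    Deterministic: Q-matrix ties are broken by the smallest active index
    pair in input/creation order.  Negative branch lengths are clamped to
    zero (with a warning).  Raises if any pairwise distance is undefined.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    undef = dm.undefined_pairs
    if undef:
        raise ValueError(f"undefined distances for pairs: {undef}")
    return _nj_from_matrix(dm.ids, dm.d)


def _clamp(length: float) -> float:
    if length < 0:
        warnings.warn(
            f"negative NJ branch length {length:.6g} clamped to 0", stacklevel=3
        )
        return 0.0
    return length


def _nj_from_matrix(ids: list, d0: np.ndarray) -> Tree:
    tns = dendropy.TaxonNamespace(ids)
    nodes = [dendropy.Node(taxon=tns.get_taxon(label=i)) for i in ids]
    D = np.array(d0, dtype=float)
    m = len(nodes)
    while m > 3:
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin = lexicographically smallest (i, j) among ties
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = _clamp(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = _clamp(lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        Dn = np.empty((m - 1, m - 1))
        Dn[:-1, :-1] = D[np.ix_(keep, keep)]
        Dn[-1, :-1] = dnew[keep]
        Dn[:-1, -1] = dnew[keep]
        Dn[-1, -1] = 0.0
        D = Dn
        nodes = [nodes[k] for k in keep] + [parent]
        m -= 1
    # connect the last three through a central (unrooted degree-3) node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    central = dendropy.Node()
    for node, length in zip(nodes, lengths):
        central.add_child(node)
        node.edge.length = _clamp(length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=central)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, monophyly

def leaf_labels(tree: Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _node_side(node, leaves: frozenset, ref: str) -> frozenset:
    side = frozenset(lf.taxon.label for lf in node.leaf_iter())
    return leaves - side if ref in side else side


def bipartitions(tree: Tree, include_trivial: bool = False) -> set:
    """Bipartitions as frozensets of leaf labels.

    Each bipartition is represented by the side *not* containing the
    lexicographically smallest leaf.  Non-trivial bipartitions (both sides
    with >= 2 leaves) only, unless `include_trivial`.
    """
    leaves = leaf_labels(tree)
    ref = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = _node_side(node, leaves, ref)
        if include_trivial or 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(
    aln: Alignment, model: str = "k2p", B: int = 100, seed: int = 0
) -> Tree:
    """Point-estimate NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement (same length) B times; each
    replicate is re-distanced and re-joined.  A replicate whose distance
    matrix contains undefined entries is skipped and counted; more than 50%
    skipped is an error.  Support = percentage of successful replicates
    containing the bipartition; reproducible for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    classes = _site_classes(aln)
    n, L = aln.n_sequences, aln.length
    D = _distances_from_classes(classes, n, model)
    point = _nj_from_matrix(list(aln.ids), _require_defined(D, aln.ids))
    rng = np.random.default_rng(seed)
    counts: dict = {}
    n_skipped = 0
    n_ok = 0
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        Db = _distances_from_classes(classes, n, model, cols)
        if np.isnan(Db[np.triu_indices(n, 1)]).any():
            n_skipped += 1
            continue
        with warnings.catch_warnings():
            # tiny negative branches are routine in resampled replicates
            warnings.simplefilter("ignore")
            rep = _nj_from_matrix(list(aln.ids), Db)
        n_ok += 1
        for bp in bipartitions(rep):
            counts[bp] = counts.get(bp, 0) + 1
    if n_skipped > B / 2:
        raise ValueError(
            f"{n_skipped}/{B} bootstrap replicates had undefined distances"
        )
    leaves = leaf_labels(point)
    ref = min(leaves)
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _node_side(node, leaves, ref)
        if not 2 <= len(side) <= len(leaves) - 2:
            continue
        support = 100.0 * counts.get(side, 0) / n_ok if n_ok else 0.0
        node.label = _format_support(support)
    point.bootstrap_replicates = B
    point.bootstrap_skipped = n_skipped
    return point


def _format_support(support: float) -> str:
    rounded = round(support, 1)
    return str(int(rounded)) if rounded == int(rounded) else f"{rounded:.1f}"


def _require_defined(D: np.ndarray, ids: list) -> np.ndarray:
    n = len(ids)
    iu = np.triu_indices(n, 1)
    if np.isnan(D[iu]).any():
        bad = [
            (ids[i], ids[j])
            for i, j in zip(*iu)
            if np.isnan(D[i, j])
        ]
        raise ValueError(f"undefined distances for pairs: {bad}")
    return D


def node_support(node) -> Optional[float]:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


@dataclass(frozen=True)
class SpeciesClusterResult:
    species: str
    n_strains: int
    is_monophyletic: Optional[bool]   # None for single-strain species
    support: Optional[float]
    outliers: tuple


def species_cluster_report(tree: Tree, table: StrainTable) -> dict:
    """Per-species monophyly: does some edge separate exactly that species'
    strains from all other *labeled* strains?

    Unassigned leaves may fall on either side.  `outliers` lists strains of
    a species outside its largest single-edge "pure" core — candidates for
    misclassification.  When several pure cores tie in size, a core
    containing the species' type strain is preferred (clusters are anchored
    at nomenclatural reference strains, as in taxonomic practice).
    Single-strain species get ``is_monophyletic=None``.
    """
    leaves = leaf_labels(tree)
    labeled = frozenset(s for s in leaves if s in table.entries and table.is_labeled(s))
    ref = min(leaves)
    # (labeled side content, support) for every edge, both orientations
    sides = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        sub = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sup = node_support(node) if not node.is_leaf() else None
        sides.append((sub & labeled, sup))
        sides.append(((leaves - sub) & labeled, sup))
    report = {}
    for species in table.species_labels():
        members = frozenset(s for s in table.strains_of(species) if s in leaves)
        if not members:
            continue
        if len(members) == 1:
            report[species] = SpeciesClusterResult(species, 1, None, None, ())
            continue
        type_strains = frozenset(
            s for s in members if table.entries[s].is_type_strain
        )
        mono = False
        support = None
        best_core: frozenset = frozenset()
        best_score = (-1, -1)
        for content, sup in sides:
            if content == members:
                mono = True
                if sup is not None and (support is None or sup > support):
                    support = sup
            if content and content <= members:
                score = (len(content), int(bool(content & type_strains)))
                if score > best_score:
                    best_score = score
                    best_core = content
        outliers = tuple(sorted(members - best_core)) if not mono else ()
        report[species] = SpeciesClusterResult(
            species, len(members), mono, support, outliers
        )
    return report


# ---------------------------------------------------------------------------
# Newick I/O

def write_newick(tree: Tree, path: Union[str, Path]) -> None:
    """Standard Newick with branch lengths; supports as internal node labels."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path: Union[str, Path]) -> Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def newick_string(tree: Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
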