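"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive — per-column Python loops, explicit
set logic, exhaustive topology enumeration — and shares no code with the
package implementations it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"}, "-": set(),
}
BASES = "ACGT"


def brute_variable_count(rows):
    """Columns with >= 2 distinct concrete bases."""
    n = 0
    for col in zip(*rows):
        if len({c for c in col if c in BASES}) >= 2:
            n += 1
    return n


def brute_identity(a, b):
    """(percent, comparable) excluding columns gapped/ambiguous in either."""
    comparable = matches = 0
    for ca, cb in zip(a, b):
        if ca in BASES and cb in BASES:
            comparable += 1
            if ca == cb:
                matches += 1
    if comparable == 0:
        return None, 0
    return 100.0 * matches / comparable, comparable


def brute_identity_matrix(rows):
    n = len(rows)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            pct, _ = brute_identity(rows[i], rows[j])
            if pct is not None:
                out[i, j] = pct
    return out


def brute_diagnostics(rows_by_id, species_of, target, max_exceptions=0):
    """(column, state, n_background_carriers) per diagnostic column."""
    target_rows = [seq for sid, seq in rows_by_id.items()
                   if species_of.get(sid) == target]
    bkg_rows = [seq for sid, seq in rows_by_id.items()
                if sid in species_of and species_of[sid] != target]
    length = len(next(iter(rows_by_id.values())))
    found = []
    for c in range(length):
        tgt = {row[c] for row in target_rows}
        if len(tgt) != 1:
            continue
        (state,) = tgt
        if state not in BASES:
            continue
        carriers = sum(1 for row in bkg_rows if state in IUPAC[row[c]])
        if carriers <= max_exceptions:
            found.append((c + 1, state, carriers))
    return found


# ---------------------------------------------------------------------------
# unrooted tree enumeration + least-squares fit

def all_topologies(n):
    """Every unrooted binary topology on leaves 0..n-1, as edge lists.

    Internal node ids start at n.  Counts: 3 for n=4, 15 for n=5,
    105 for n=6, 10395 for n=8.
    """
    if n < 3:
        raise ValueError("need >= 3 leaves")

    def rec(k, edges, next_node):
        if k == n:
            yield list(edges)
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_node
            new = edges[:i] + edges[i + 1:] + [(u, w), (v, w), (k, w)]
            yield from rec(k + 1, new, next_node + 1)

    yield from rec(3, [(0, n), (1, n), (2, n)], n + 1)


def random_topology(n, rng):
    edges = [(0, n), (1, n), (2, n)]
    next_node = n + 1
    for k in range(3, n):
        i = rng.integers(0, len(edges))
        u, v = edges[i]
        edges = edges[:i] + edges[i + 1:] + [(u, next_node), (v, next_node),
                                             (k, next_node)]
        next_node += 1
    return edges


def _adjacency(edges):
    adj = {}
    for e, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, e))
        adj.setdefault(v, []).append((u, e))
    return adj


def path_edges(edges, n):
    """For each leaf pair (i<j), the set of edge indices on the path."""
    adj = _adjacency(edges)
    paths = {}
    for i in range(n):
        # DFS from leaf i recording the edge path to every node
        stack = [(i, None, [])]
        seen = {i}
        trail = {}
        while stack:
            node, _, p = stack.pop()
            trail[node] = p
            for nxt, e in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, p + [e]))
        for j in range(i + 1, n):
            paths[(i, j)] = trail[j]
    return paths


def additive_matrix(edges, lengths, n):
    D = np.zeros((n, n))
    for (i, j), p in path_edges(edges, n).items():
        D[i, j] = D[j, i] = sum(lengths[e] for e in p)
    return D


def ls_fit_sse(edges, n, D):
    """Least-squares branch-length fit of a topology to a distance matrix;
    returns the residual sum of squares."""
    pairs = list(combinations(range(n), 2))
    pe = path_edges(edges, n)
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for e in pe[(i, j)]:
            A[r, e] = 1.0
        d[r] = D[i, j]
    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = A @ x - d
    return float(resid @ resid)


def topology_bipartitions(edges, n, labels=None):
    """Non-trivial bipartitions as frozensets of leaf labels, normalized to
    the side not containing the smallest label."""
    labels = labels or [str(i) for i in range(n)]
    adj = _adjacency(edges)
    all_leaves = frozenset(labels[:n])
    ref = min(all_leaves)
    out = set()
    for cut in range(len(edges)):
        u, _ = edges[cut]
        comp = {u}
        stack = [u]
        while stack:
            node = stack.pop()
            for nxt, e in adj[node]:
                if e != cut and nxt not in comp:
                    comp.add(nxt)
                    stack.append(nxt)
        side = frozenset(labels[x] for x in comp if x < n)
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def random_alignment(rng, n_seqs, n_cols, gap_rate=0.05, amb_rate=0.05,
                     n_species=3):
    """Random gapped/ambiguous alignment with species labels, for oracle
    comparisons."""
    alphabet = list("ACGT")
    ambs = list("RYSWKMN")
    rows = []
    for i in range(n_seqs):
        chars = []
        for _ in range(n_cols):
            u = rng.random()
            if u < gap_rate:
                chars.append("-")
            elif u < gap_rate + amb_rate:
                chars.append(ambs[rng.integers(0, len(ambs))])
            else:
                chars.append(alphabet[rng.integers(0, 4)])
        rows.append("".join(chars))
    ids = [f"s{i}" for i in range(n_seqs)]
    species = {sid: f"sp{rng.integers(0, n_species)}" for sid in ids}
    return ids, rows, species
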