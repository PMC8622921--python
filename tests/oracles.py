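"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: direct enumeration and first
principles, sharing no code path with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

_CODON_TABLE = {}


def _build_codon_table():
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    for i, (a, b, c) in enumerate(itertools.product(bases, bases, bases)):
        _CODON_TABLE[a + b + c] = aas[i]


_build_codon_table()


def translate(dna: str) -> str:
    return "".join(
        _CODON_TABLE.get(dna[i : i + 3], "X") for i in range(0, len(dna) - 2, 3)
    )


def unit_ok(dna9: str) -> bool:
    """Is this 9-mer a classifiable tripeptide unit (non-OTHER)?"""
    aa = translate(dna9)
    return (
        len(aa) == 3
        and aa[0] in "TRK"
        and aa[1] in "AP"
        and aa[2] == "A"
        and not (aa[0] in "RK" and aa[1] == "P")
    )


def brute_force_best_run(cds: str, min_units: int = 4, max_other_frac: float = 0.1):
    """Enumerate every (start, n_units) tiling and apply the selection rule.

    Returns (start_nt, n_units) of the winning run or None. Selection:
    maximal count of classifiable units; ties by smallest start offset
    mod 9, then earliest unit index within that offset, then shortest run;
    runs must have classifiable first/last units and OTHER fraction at most
    ``max_other_frac``.
    """
    best = None
    n = len(cds)
    for start in range(0, n - 9 + 1):
        max_units = (n - start) // 9
        ok = [unit_ok(cds[start + 9 * k : start + 9 * k + 9])
              for k in range(max_units)]
        if not ok or not ok[0]:
            continue
        for length in range(min_units, max_units + 1):
            if not ok[length - 1]:
                continue
            n_other = length - sum(ok[:length])
            if n_other > max_other_frac * length:
                continue
            score = length - n_other
            key = (-score, start % 9, start // 9, length)
            if best is None or key < best[0]:
                best = (key, start, length)
    if best is None:
        return None
    return best[1], best[2]


def orf_spans_repeats(cds: str, repeat_start: int, repeat_end: int) -> bool:
    """Six-frame-style check: does an ORF run from a leading ATG through
    the repeat tract to a stop at the CDS end, in frame with the tract?"""
    if not cds.startswith("ATG") or len(cds) % 3:
        return False
    if repeat_start % 3:
        return False
    aa = translate(cds)
    return "*" not in aa[:-1] and aa.endswith("*")


# ---------------------------------------------------------------------------
# Exhaustive tree-topology search
# ---------------------------------------------------------------------------


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies as edge lists over internal ids.

    Leaves are the given labels; internal nodes are negative integers.
    Built by sequential leaf insertion into every edge (the standard
    (2n-5)!! construction).
    """
    labels = list(labels)
    if len(labels) < 4:
        raise ValueError("need at least 4 leaves")
    base = [(labels[0], -1), (labels[1], -1), (labels[2], -1)]
    trees = [base]
    next_internal = -2
    for leaf in labels[3:]:
        new_trees = []
        for edges in trees:
            for i, (a, b) in enumerate(edges):
                mid = next_internal
                new = [e for j, e in enumerate(edges) if j != i]
                new += [(a, mid), (b, mid), (leaf, mid)]
                new_trees.append(new)
        trees = new_trees
        next_internal -= 1
    return trees


def _path_edges(edges, labels):
    """Map each leaf pair to the set of edge indices on its path."""
    adj = {}
    for idx, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, idx))
        adj.setdefault(b, []).append((a, idx))

    def path(u, v):
        stack = [(u, None, [])]
        seen = {u}
        while stack:
            node, _, acc = stack.pop()
            if node == v:
                return acc
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, acc + [eidx]))
        raise RuntimeError("disconnected")

    return {
        (a, b): path(a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }


def best_topology_least_squares(labels, dmat):
    """Exhaustive search: the topology whose least-squares fit to the
    distance matrix has minimal residual. Returns (edges, residual)."""
    labels = list(labels)
    index = {l: i for i, l in enumerate(labels)}
    best = None
    for edges in enumerate_unrooted_topologies(labels):
        paths = _path_edges(edges, labels)
        pairs = sorted(paths)
        A = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for r, (a, b) in enumerate(pairs):
            for eidx in paths[(a, b)]:
                A[r, eidx] = 1.0
            y[r] = dmat[index[a], index[b]]
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(((A @ x - y) ** 2).sum())
        if best is None or resid < best[1] - 1e-12:
            best = (edges, resid)
    return best


def topology_splits(edges, labels):
    """Nontrivial bipartitions induced by an edge list (for comparison)."""
    label_set = frozenset(labels)
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    splits = set()
    for a, b in edges:
        # leaves on a's side when edge (a,b) is removed
        stack, seen = [a], {a, b}
        side = set()
        while stack:
            node = stack.pop()
            if not isinstance(node, int) or node >= 0:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        side = frozenset(side)
        other = label_set - side
        if 1 < len(side) < len(label_set) - 1:
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def newick_splits(newick: str, labels) -> set:
    """Nontrivial splits of a newick tree, parsed naively by bracket depth."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    label_set = frozenset(labels)
    out = set()
    for node in t.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = label_set - side
        if 1 < len(side) < len(label_set) - 1:
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def random_additive_tree(rng, n):
    """Random unrooted topology with positive lengths and its path metric."""
    labels = [f"L{i}" for i in range(n)]
    topos = None
    # grow a random topology by random leaf insertion (not enumeration)
    edges = [(labels[0], -1), (labels[1], -1), (labels[2], -1)]
    next_internal = -2
    for leaf in labels[3:]:
        i = int(rng.integers(0, len(edges)))
        a, b = edges.pop(i)
        mid = next_internal
        edges += [(a, mid), (b, mid), (leaf, mid)]
        next_internal -= 1
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    paths = _path_edges(edges, labels)
    d = np.zeros((n, n))
    for (a, b), eidxs in paths.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = sum(lengths[k] for k in eidxs)
    return labels, edges, d
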