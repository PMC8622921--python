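"""Gene-family trees from flanking sequence, orthology and expansion order.

The tripeptide-repeat coding tract diverges too fast (and too repetitively)
to align, so family relationships are read from the non-repetitive 5'
region and the proximal 3' flank. Distances come from p- or Jukes-Cantor
corrected mismatch fractions on pre-aligned (or equal-length, gap-free)
sequences; trees are built with neighbor joining; orthology across species
is called from shared cherries plus matching C-terminus signatures; the
order of family expansion is sketched from basal long-branch pseudogenes
and longest-shared-flank duplicon pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

MODELS = ("p", "JC69")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


@dataclass
class FamilyTree:
    """A gene-family tree held as newick; leaves are gene ids."""

    newick: str

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick,
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )

    @property
    def leaf_labels(self) -> set[str]:
        t = self.to_dendropy()
        return {leaf.taxon.label for leaf in t.leaf_node_iter()}


def _valid_columns(a: str, b: str) -> list[int]:
    return [
        i
        for i in range(len(a))
        if a[i] not in "-N" and b[i] not in "-N"
    ]


def pairwise_distance(
    seqs,
    model: str = "p",
    saturation_cap: float = 5.0,
) -> DistanceMatrix:
    """Pairwise p or JC69 distances on equal-length sequences.

    Gap ('-') and N columns are deleted pairwise. JC69 applies the usual
    correction d = -(3/4) ln(1 - 4p/3); saturated pairs (p >= 0.75) are
    reported at ``saturation_cap`` with a warning.
    """
    if isinstance(seqs, dict):
        items = list(seqs.items())
    else:
        items = list(seqs)
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    lengths = {len(s) for _, s in items}
    if len(lengths) > 1:
        raise ValueError("sequences must be equal length (pre-aligned)")
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cols = _valid_columns(items[i][1], items[j][1])
            if not cols:
                p = 0.0
            else:
                mism = sum(items[i][1][c] != items[j][1][c] for c in cols)
                p = mism / len(cols)
            if model == "p":
                dist = p
            else:
                if p >= 0.75:
                    warnings.warn(
                        f"JC69 saturated between {labels[i]} and {labels[j]} "
                        f"(p={p:.3f}); capped at {saturation_cap}"
                    )
                    dist = saturation_cap
                else:
                    dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "children", "rep")

    def __init__(self, label=None, children=None, rep=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)
        self.rep = rep if rep is not None else label

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{child.newick()}:{bl:.10g}" for child, bl in self.children
        )
        return f"({inner})"


def nj_tree(matrix: DistanceMatrix) -> FamilyTree:
    """Neighbor joining with a deterministic tie-break.

    Standard saitou-nei agglomeration; when the Q criterion ties, the
    joined pair is the lexicographically smallest (representative-label)
    pair, so the output is independent of input order. Fewer than three
    labels yield a degenerate tree rather than an error. The returned
    newick carries a trifurcating root (unrooted topology).
    """
    labels = matrix.labels
    n = len(labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return FamilyTree(f"{labels[0]};")
    if n == 2:
        h = matrix.d[0, 1] / 2.0
        return FamilyTree(f"({labels[0]}:{h:.10g},{labels[1]}:{h:.10g});")

    nodes = [_Node(label=lab) for lab in labels]
    D = {
        (a, b): float(matrix.d[i, j])
        for i, a in enumerate(nodes)
        for j, b in enumerate(nodes)
        if i != j
    }
    active = list(nodes)

    while len(active) > 3:
        m = len(active)
        r = {a: sum(D[(a, b)] for b in active if b is not a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * D[(a, b)] - r[a] - r[b]
                pair_key = tuple(sorted((a.rep, b.rep)))
                key = (q, pair_key)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = D[(a, b)]
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        u = _Node(children=[(a, la), (b, lb)], rep=min(a.rep, b.rep))
        for c in active:
            if c is a or c is b:
                continue
            duc = (D[(a, c)] + D[(b, c)] - dab) / 2.0
            D[(u, c)] = D[(c, u)] = duc
        active = [c for c in active if c is not a and c is not b] + [u]

    a, b, c = sorted(active, key=lambda x: x.rep)
    la = (D[(a, b)] + D[(a, c)] - D[(b, c)]) / 2.0
    lb = (D[(a, b)] + D[(b, c)] - D[(a, c)]) / 2.0
    lc = (D[(a, c)] + D[(b, c)] - D[(a, b)]) / 2.0
    inner = ",".join(
        f"{node.newick()}:{bl:.10g}" for node, bl in ((a, la), (b, lb), (c, lc))
    )
    return FamilyTree(f"({inner});")


def nj_tree_from_seqs(seqs, model: str = "JC69") -> FamilyTree:
    return nj_tree(pairwise_distance(seqs, model=model))


def robinson_foulds(t1: FamilyTree, t2: FamilyTree) -> int:
    """Unrooted symmetric (Robinson-Foulds) distance between two trees."""
    tns = dendropy.TaxonNamespace()
    a = t1.to_dendropy(tns)
    b = t2.to_dendropy(tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def bootstrap_support(
    seqs,
    model: str = "JC69",
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[FamilyTree, dict]:
    """NJ tree plus nonparametric bootstrap support over alignment columns.

    Returns the tree built on the full alignment and a map from each
    internal bipartition (frozenset of leaf labels on the smaller side) to
    the fraction of column-resampled replicates containing it.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    main = nj_tree_from_seqs(items, model=model)
    length = len(items[0][1])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    all_leaves = frozenset(lab for lab, _ in items)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [(lab, "".join(s[c] for c in cols)) for lab, s in items]
        rep = nj_tree_from_seqs(resampled, model=model)
        for bip in _bipartitions(rep, all_leaves):
            counts[bip] = counts.get(bip, 0) + 1
    support = {
        bip: counts.get(bip, 0) / n_replicates
        for bip in _bipartitions(main, all_leaves)
    }
    return main, support


def _bipartitions(tree: FamilyTree, all_leaves: frozenset) -> set[frozenset]:
    t = tree.to_dendropy()
    out = set()
    for node in t.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(leaves) < len(all_leaves) - 1:
            comp = all_leaves - leaves
            out.add(min(leaves, comp, key=lambda s: (len(s), sorted(s))))
    return out


# ---------------------------------------------------------------------------
# Orthology and expansion order
# ---------------------------------------------------------------------------


def default_species_of(leaf: str) -> str:
    """Species code from a species_gene leaf label (prefix before '_')."""
    return leaf.split("_", 1)[0]


def _cherries(tree: FamilyTree) -> set[frozenset]:
    t = tree.to_dendropy()
    out = set()
    for node in t.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            out.add(frozenset(k.taxon.label for k in kids))
    return out


def assign_orthologs(
    tree5: FamilyTree,
    tree3: FamilyTree,
    cterm: dict,
    species_of=default_species_of,
) -> list[tuple[str, str]]:
    """Cross-species ortholog pairs from two flanking-region trees.

    A pair is orthologous when the two genes are sisters (a cherry) in at
    least one tree, the other tree does not contradict it (neither gene
    sits in a cross-species cherry with a different partner there), and
    their characteristic C-terminus signatures match exactly. Genes absent
    from one tree (e.g. pseudogenes excluded for unalignable flanks) are
    judged on the remaining evidence. Output is sorted and deterministic.
    """
    leaves5, leaves3 = tree5.leaf_labels, tree3.leaf_labels
    cherries = {"5": _cherries(tree5), "3": _cherries(tree3)}
    cross = {
        side: {
            ch for ch in chs
            if len({species_of(l) for l in ch}) == 2
        }
        for side, chs in cherries.items()
    }
    partner = {
        side: {l: ch for ch in chs for l in ch} for side, chs in cross.items()
    }
    pairs = set()
    for side, other, other_leaves in (("5", "3", leaves3), ("3", "5", leaves5)):
        for ch in cross[side]:
            a, b = sorted(ch)
            if cterm.get(a) != cterm.get(b) or cterm.get(a) is None:
                continue
            contradicted = False
            for leaf in (a, b):
                if leaf in other_leaves and leaf in partner[other]:
                    if partner[other][leaf] != ch:
                        contradicted = True
            if not contradicted:
                pairs.add((a, b))
    return sorted(pairs)


@dataclass
class ExpansionOrder:
    """Partial order of duplication events: basal copies + duplicon edges."""

    basal: list[str] = field(default_factory=list)
    edges: list[dict] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.basal and not self.edges


def expansion_order(
    tree: FamilyTree,
    pseudogene_flags: dict,
    clusters: dict,
    shared_flank: dict,
    basal_factor: float = 2.0,
    duplicon_ratio: float = 2.0,
) -> ExpansionOrder:
    """Sketch the duplication history of a gene family.

    Two rules are applied: (i) pseudogenes whose terminal branch is at
    least ``basal_factor`` times the median terminal branch are flagged as
    candidate basal copies (relaxed selection lets substitutions pile up on
    the oldest, dead copies); (ii) for each pair of gene clusters, the
    cross-cluster gene pair sharing the longest flanking homology is
    emitted as an immediate-duplicon edge, provided its shared length
    dominates the runner-up by ``duplicon_ratio``. ``shared_flank`` maps
    frozenset({gene_a, gene_b}) to shared flank length (bp). Unresolvable
    inputs (uniform branch lengths, uniform flanks) give an empty order.
    """
    t = tree.to_dendropy()
    term = {
        leaf.taxon.label: (leaf.edge.length or 0.0)
        for leaf in t.leaf_node_iter()
    }
    med = float(np.median(list(term.values()))) if term else 0.0
    basal = sorted(
        g
        for g, bl in term.items()
        if pseudogene_flags.get(g) and med > 0 and bl >= basal_factor * med
    )

    edges = []
    cluster_ids = sorted(set(clusters.values()))
    for i, c1 in enumerate(cluster_ids):
        for c2 in cluster_ids[i + 1 :]:
            cross = sorted(
                (pair for pair in shared_flank
                 if {clusters.get(g) for g in pair} == {c1, c2}),
                key=lambda p: (-shared_flank[p], tuple(sorted(p))),
            )
            if not cross:
                continue
            best = cross[0]
            best_len = shared_flank[best]
            runner = shared_flank[cross[1]] if len(cross) > 1 else 0.0
            if best_len > 0 and best_len >= duplicon_ratio * max(runner, 1e-12):
                a, b = sorted(best, key=lambda g: (clusters[g], g))
                edges.append(
                    {
                        "from": a,
                        "to": b,
                        "shared_flank_bp": best_len,
                        "rationale": (
                            f"{a} ({clusters[a]}) and {b} ({clusters[b]}) share "
                            f"{best_len:g} bp of flanking homology vs "
                            f"{runner:g} bp for the next-best cross-cluster pair"
                        ),
                    }
                )
    return ExpansionOrder(basal=basal, edges=edges)
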