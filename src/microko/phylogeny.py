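"""16S amplicon phylogeny stage: quality trimming, dereplication,
Kimura 2-parameter distances, neighbor joining, and outgroup rooting.

The distance model distinguishes transitions (A<->G, C<->T) from
transversions:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

with P and Q the observed transition and transversion fractions over sites
where both sequences carry an unambiguous base (pairwise deletion by
default).  Trees are :class:`dendropy.Tree` objects throughout; the
neighbor-joining implementation is the Saitou-Nei agglomeration with the
Q-criterion and is exact on additive matrices.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import QualityRead

__all__ = [
    "DistanceMatrix",
    "SaturationWarning",
    "trim_reads",
    "dereplicate",
    "k2p_distance",
    "k2p_matrix",
    "nj_tree",
    "root_with_outgroup",
]

class SaturationWarning(UserWarning):
    """A pairwise distance is undefined (saturated) under the model."""


@dataclass
class DistanceMatrix:
    """Symmetric labeled distance matrix with zero diagonal.

    Saturated pairs are stored as ``+inf``; downstream tree building refuses
    infinite entries.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def has_saturation(self) -> bool:
        return bool(np.isinf(self.values).any())


def trim_reads(
    reads: Iterable[QualityRead],
    leading: int = 17,
    trailing: int = 17,
    avg_qual: float = 25.0,
    min_len: int = 200,
) -> list[QualityRead]:
    """Quality-trim reads: LEADING, TRAILING, AVGQUAL, MINLEN, in that order.

    Per read: strip leading bases with quality below ``leading``; strip
    trailing bases with quality below ``trailing``; drop the read if the mean
    quality of what remains is below ``avg_qual``; drop it if the remaining
    length is below ``min_len``.  Reads trimmed to nothing are dropped.
    """
    kept: list[QualityRead] = []
    for read in reads:
        start = 0
        end = len(read)
        while start < end and read.quals[start] < leading:
            start += 1
        while end > start and read.quals[end - 1] < trailing:
            end -= 1
        if end == start:
            continue
        quals = read.quals[start:end]
        if sum(quals) / len(quals) < avg_qual:
            continue
        if len(quals) < min_len:
            continue
        kept.append(QualityRead(read.read_id, read.bases[start:end], quals))
    return kept


def dereplicate(seqs: Iterable[str]) -> list[tuple[str, int]]:
    """Collapse identical sequences to (sequence, count), most abundant first.

    Ties are broken lexicographically by sequence so the output is fully
    deterministic; counts sum to the input size.  The head of the list is
    each sample's most abundant unique sequence.
    """
    counts = Counter(seqs)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance between two equal-length gapped sequences.

    Sites where either character is not in {A, C, G, T} are excluded
    (pairwise deletion).  Returns ``+inf`` when the observed P, Q fall
    outside the model's domain (saturation).  Raises ``ValueError`` on
    unequal lengths or zero comparable sites.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    xa = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    # map A,C,G,T -> purine/pyrimidine-aware codes; everything else is ignored
    code = np.full(256, -1, dtype=np.int8)
    for base, idx in zip(b"ACGT", (0, 1, 2, 3)):
        code[base] = idx
    ca, cb = code[xa], code[xb]
    usable = (ca >= 0) & (cb >= 0)
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no comparable sites (all gapped or ambiguous)")
    ca, cb = ca[usable], cb[usable]
    diff = ca != cb
    # transitions swap within {A(0), G(2)} or {C(1), T(3)}: same parity
    transitions = int((diff & ((ca & 1) == (cb & 1))).sum())
    transversions = int(diff.sum()) - transitions
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return d + 0.0  # normalize -0.0 for identical sequences


def k2p_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    """All pairwise K2P distances of an alignment (>= 3 sequences).

    Each pair is computed once, so the matrix is exactly symmetric.  If any
    pair is saturated the matrix is returned with ``+inf`` entries and a
    :class:`SaturationWarning`.
    """
    labels = list(alignment.keys())
    if len(labels) < 3:
        raise ValueError("need >= 3 sequences for a distance matrix")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(alignment[labels[i]], alignment[labels[j]])
    dm = DistanceMatrix(labels, d)
    if dm.has_saturation:
        warnings.warn(
            "distance matrix contains saturated (infinite) pairs",
            SaturationWarning,
            stacklevel=2,
        )
    return dm


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix (Saitou-Nei).

    Repeatedly joins the pair minimizing
    ``Q(i, j) = (n - 2) d(i, j) - r_i - r_j`` (row sums ``r``), with ties
    broken by the smallest index pair; branch lengths use the standard
    three-point formulas and negative lengths are retained as computed.
    The final three-way join closes the unrooted tree, whose seed node is
    the degree-3 internal node.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if dm.has_saturation:
        idx = np.argwhere(np.isinf(dm.values))
        i, j = idx[0]
        raise ValueError(
            f"infinite distance between {dm.labels[i]!r} and {dm.labels[j]!r}"
        )

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=tns.new_taxon(label))
        nodes.append(node)
    d = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        # subtract the symmetric sum r_i + r_j in one step so Q is exactly
        # symmetric in floating point
        q = (m - 2) * sub - (r[:, None] + r[None, :])
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) pair among minima, for determinism
        qmin = q.min()
        ties = np.argwhere(q == qmin)
        ti, tj = min((int(a), int(b)) for a, b in ties if a < b)
        dij = sub[ti, tj]
        limb_i = 0.5 * dij + (r[ti] - r[tj]) / (2.0 * (m - 2))
        limb_j = dij - limb_i
        gi, gj = active[ti], active[tj]

        parent = dendropy.Node()
        parent.add_child(nodes[gi])
        nodes[gi].edge.length = limb_i
        parent.add_child(nodes[gj])
        nodes[gj].edge.length = limb_j

        # reuse slot gi for the new node; distances to remaining taxa
        new_d = 0.5 * (d[gi, :] + d[gj, :] - dij)
        d[gi, :] = new_d
        d[:, gi] = new_d
        d[gi, gi] = 0.0
        nodes[gi] = parent
        active.remove(gj)

    # close with the unique unrooted 3-leaf join
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    center = tree.seed_node
    center.add_child(nodes[a])
    nodes[a].edge.length = 0.5 * (dab + dac - dbc)
    center.add_child(nodes[b])
    nodes[b].edge.length = 0.5 * (dab + dbc - dac)
    center.add_child(nodes[c])
    nodes[c].edge.length = 0.5 * (dac + dbc - dab)
    tree.is_rooted = False
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup: Iterable[str]) -> dendropy.Tree:
    """Root an unrooted tree on the edge separating the outgroup.

    If the outgroup is monophyletic the root is placed at the midpoint of
    the edge between the outgroup clade and the rest; a single-taxon
    outgroup is always usable.  A multi-taxon outgroup that is not
    monophyletic raises ``ValueError`` naming the offending split.
    """
    out = set(outgroup)
    if not out:
        raise ValueError("outgroup must be non-empty")
    rooted = tree.clone(depth=1)
    leaves = {lf.taxon.label for lf in rooted.leaf_node_iter()}
    if not out <= leaves:
        raise ValueError(f"outgroup taxa not in tree: {sorted(out - leaves)}")
    if out == leaves:
        raise ValueError("outgroup cannot contain every leaf")

    # find the edge whose child-side leaf set is exactly the outgroup
    target = None
    for node in rooted.postorder_node_iter():
        if node is rooted.seed_node:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == out or leaves - below == out:
            target = node
            break
    if target is None:
        if len(out) == 1:
            raise AssertionError("single leaf edge always exists")  # pragma: no cover
        raise ValueError(
            f"outgroup {sorted(out)} is not monophyletic in the unrooted tree"
        )
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    rooted.is_rooted = True
    return rooted
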