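"""Distance-based phylogenetics for 16S alignments.

Kimura 2-parameter (K2P) distances with pairwise deletion of gap/N sites,
Saitou-Nei neighbor joining with deterministic tie-breaking, column-resampled
bootstrap supports, and Newick round-tripping.  Trees are dendropy
:class:`~dendropy.Tree` objects, unrooted as built; midpoint rooting is
provided for display and for the Brownian-motion covariance used downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .seqio import Alignment

log = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Observed substitution proportions outside the K2P model's domain."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(rows: list[str]) -> np.ndarray:
    """Rows of aligned residues -> int codes (A,C,G,T = 0..3; gap/N = -1)."""
    mats = [
        _CODE[np.frombuffer(r.encode("ascii"), dtype=np.uint8)] for r in rows
    ]
    return np.vstack(mats)


def _k2p(P: float, Q: float, pair: str, cap: float | None) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        if cap is not None:
            return cap
        raise SaturationError(f"saturation: distance undefined for pair {pair}")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """Usable sites, transitions and transversions for one encoded pair."""
    valid = (a >= 0) & (b >= 0)
    n_valid = int(valid.sum())
    diff = valid & (a != b)
    purine_a = (a == 0) | (a == 2)
    purine_b = (b == 0) | (b == 2)
    tv = int((diff & (purine_a != purine_b)).sum())
    ts = int(diff.sum()) - tv
    return n_valid, ts, tv


def k2p_distance(a: str, b: str, cap: float | None = None) -> float:
    """K2P distance between two aligned sequences.

    Sites where either residue is a gap or N are excluded (pairwise
    deletion).  With transition proportion P and transversion proportion Q,
    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).  Raises
    :class:`SaturationError` outside the model's domain unless a ``cap``
    substitute is supplied.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal aligned lengths: {len(a)} vs {len(b)}")
    codes = _encode([a.upper().replace("U", "T"), b.upper().replace("U", "T")])
    n_valid, ts, tv = _pair_counts(codes[0], codes[1])
    if n_valid == 0:
        raise ValueError("zero usable sites after pairwise deletion")
    return _k2p(ts / n_valid, tv / n_valid, "a-b", cap)


def _dm_from_codes(
    codes: np.ndarray, labels: tuple[str, ...], cap: float | None
) -> DistanceMatrix:
    n = codes.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            n_valid, ts, tv = _pair_counts(codes[i], codes[j])
            if n_valid == 0:
                raise ValueError(
                    f"zero usable sites for pair {labels[i]}-{labels[j]}"
                )
            try:
                d = _k2p(ts / n_valid, tv / n_valid, f"{labels[i]}-{labels[j]}", cap)
            except SaturationError:
                raise SaturationError(
                    f"saturation: distance undefined for pair "
                    f"{labels[i]}-{labels[j]}"
                ) from None
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=labels, values=D)


def distance_matrix(alignment: Alignment, cap: float | None = None) -> DistanceMatrix:
    """All pairwise K2P distances of an alignment (>= 3 records)."""
    if len(alignment.records) < 3:
        raise ValueError("need at least 3 records for a distance matrix")
    labels = tuple(alignment.ids)
    codes = _encode([r.residues for r in alignment.records])
    return _dm_from_codes(codes, labels, cap)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Joins the active pair minimising Q(i,j) = (r-2) d(i,j) - R_i - R_j, with
    ties broken by the smallest (i, j) index pair in matrix order (new nodes
    are appended after the original labels).  Negative branch-length
    estimates are clamped to 0 with the deficit moved to the sister branch.
    Returns an unrooted tree (basal trifurcation).
    """
    m = len(dm.labels)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.values.astype(float).copy()
    tns = dendropy.TaxonNamespace(list(dm.labels))
    nodes = [dendropy.Node(taxon=tns.get_taxon(lbl)) for lbl in dm.labels]

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), r)  # row-major argmin: smallest (i,j)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        bi = 0.5 * dij + (R[i] - R[j]) / (2.0 * (r - 2))
        bj = dij - bi
        if bi < 0:
            bi, bj = 0.0, dij
        elif bj < 0:
            bi, bj = dij, 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = bi
        parent.add_child(nodes[j])
        nodes[j].edge.length = bj
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point attachment
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        max(0.0, 0.5 * (d01 + d02 - d12)),
        max(0.0, 0.5 * (d01 + d12 - d02)),
        max(0.0, 0.5 * (d02 + d12 - d01)),
    ]
    center = dendropy.Node()
    for node, length in zip(nodes, lens):
        center.add_child(node)
        node.edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def leaf_bipartitions(
    tree: dendropy.Tree, min_length: float | None = None
) -> dict[frozenset, dendropy.Node]:
    """Non-trivial leaf bipartitions keyed by the side not containing the
    lexicographically smallest leaf label.  ``min_length`` skips edges at or
    below that length (used to treat zero-length edges as unresolved)."""
    all_leaves = frozenset(
        lf.taxon.label for lf in tree.leaf_node_iter()
    )
    anchor = min(all_leaves)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([node.taxon.label])
            continue
        node._leafset = frozenset().union(*(c._leafset for c in node.child_nodes()))
        if node is tree.seed_node:
            continue
        side = node._leafset
        if not (2 <= len(side) <= len(all_leaves) - 2):
            continue
        if min_length is not None and (node.edge.length or 0.0) <= min_length:
            continue
        if anchor in side:
            side = all_leaves - side
        out[side] = node
    return out


def bootstrap_support(
    alignment: Alignment,
    B: int = 1000,
    seed: int = 0,
    cap: float | None = None,
) -> dendropy.Tree:
    """NJ tree of the full alignment with bootstrap supports.

    Columns are resampled with replacement ``B`` times; the support of each
    resolved internal bipartition of the full-data tree is the fraction of
    successful replicates containing it.  Replicates hitting K2P saturation
    are dropped with a warning and the denominator adjusted.  Supports are
    written to internal node labels and to ``tree.bipartition_supports``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels = tuple(alignment.ids)
    codes = _encode([r.residues for r in alignment.records])
    n_cols = codes.shape[1]
    tree = nj_tree(_dm_from_codes(codes, labels, cap))
    bips = leaf_bipartitions(tree, min_length=1e-12)
    counts = dict.fromkeys(bips, 0)
    rng = np.random.default_rng(seed)
    n_ok = 0
    n_dropped = 0
    for _ in range(B):
        cols = rng.integers(0, n_cols, n_cols)
        try:
            dm_b = _dm_from_codes(codes[:, cols], labels, cap)
        except SaturationError:
            n_dropped += 1
            continue
        rep_bips = leaf_bipartitions(nj_tree(dm_b), min_length=1e-12)
        n_ok += 1
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    if n_dropped:
        warnings.warn(
            f"{n_dropped}/{B} bootstrap replicates dropped (K2P saturation); "
            f"supports based on {n_ok} replicates"
        )
    supports: dict[frozenset, float] = {}
    for key, node in bips.items():
        s = counts[key] / n_ok if n_ok else float("nan")
        node.label = f"{s:.3f}"
        supports[key] = s
    tree.bipartition_supports = supports
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
    if n_missing:
        log.warning("%d branch(es) without length set to 0", n_missing)
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip() + "\n"


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree))


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-rooted deep copy (the NJ output itself stays unrooted)."""
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted
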