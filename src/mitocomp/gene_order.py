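"""Signed circular gene-order extraction and breakpoint-style comparison.

A mitogenome's gene order is modelled as a signed circular permutation over
the 37 canonical gene tokens (control region excluded by default).  Two
orders are compared through their conserved gene adjacencies: an adjacency
is the ordered, signed pair of neighbouring genes, and because circular DNA
has no intrinsic reading direction the pair (+x, +y) and its reflection
(-y, -x) encode the same physical junction and are canonicalised together.

The breakpoint distance between two orders on the same gene set is the
number of adjacencies of one order absent from the other — 0 iff the orders
coincide up to rotation (and reflection of the whole circle), and symmetric
by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genes import CR
from .mito_io import MitogenomeRecord

logger = logging.getLogger("mitocomp")

Signed = tuple[str, int]  # (canonical gene token, +1/-1)
Adjacency = tuple[str, int, str, int]


@dataclass(frozen=True)
class GeneOrder:
    record_id: str
    order: tuple[Signed, ...]
    normalized: bool  # rotated to start at cox1

    def __post_init__(self) -> None:
        names = [g for g, _ in self.order]
        if len(set(names)) != len(names):
            raise ValueError("gene tokens must be unique in an order")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.order)

    def restricted(self, genes: frozenset[str]) -> "GeneOrder":
        """Order induced on a gene subset (circular deletion of the rest)."""
        kept = tuple((g, s) for g, s in self.order if g in genes)
        return GeneOrder(self.record_id, kept, self.normalized)


def normalize_rotation(order: tuple[Signed, ...], anchor: str = "cox1"):
    """Rotate a circular order to start at ``anchor`` (sign untouched)."""
    names = [g for g, _ in order]
    if anchor not in names:
        return order, False
    i = names.index(anchor)
    return order[i:] + order[:i], True


def extract_order(record: MitogenomeRecord, include_cr: bool = False) -> GeneOrder:
    """Signed gene order of a record, by ascending start coordinate.

    Strand signs are retained (+1 majority / -1 minority); duplicated gene
    tokens collapse to their first occurrence with a warning; unknown
    ('?') features are dropped.  Orders are rotation-normalized to start at
    cox1 when present, otherwise flagged un-normalized.
    """
    seen: set[str] = set()
    order: list[Signed] = []
    for f in record.features:  # already sorted by start
        if f.canonical_name == "?":
            continue
        if f.kind == "CR" and not include_cr:
            continue
        if f.canonical_name in seen:
            logger.warning("%s: duplicate gene %s collapsed to first occurrence",
                           record.id, f.canonical_name)
            continue
        seen.add(f.canonical_name)
        sign = 1 if (f.strand in ("+", None)) else -1
        order.append((f.canonical_name, sign))
    rotated, ok = normalize_rotation(tuple(order))
    if not ok:
        logger.warning("%s: cox1 missing, rotation normalization skipped", record.id)
    return GeneOrder(record.id, rotated, normalized=ok)


def order_from_string(record_id: str, text: str) -> GeneOrder:
    """Parse a one-line order string like ``"cox1 trnL2 cox2 -trnK ..."``."""
    order = []
    for tok in text.split():
        if tok.startswith("-"):
            order.append((tok[1:], -1))
        else:
            order.append((tok.lstrip("+"), 1))
    rotated, ok = normalize_rotation(tuple(order))
    return GeneOrder(record_id, rotated, normalized=ok)


def order_to_string(order: GeneOrder) -> str:
    return " ".join(("-" if s < 0 else "") + g for g, s in order.order)


def _canonical_adjacency(a: Signed, b: Signed) -> Adjacency:
    """Canonical encoding of a junction.

    (a, b) and the reflected reading (-b, -a) describe the same physical
    junction; the encoding whose first gene sits on the majority strand is
    preferred, falling back to lexicographic order on ties.
    """
    fwd: Adjacency = (a[0], a[1], b[0], b[1])
    rev: Adjacency = (b[0], -b[1], a[0], -a[1])
    if fwd[1] != rev[1]:
        return fwd if fwd[1] > 0 else rev
    return min(fwd, rev)


def adjacency_set(order: GeneOrder) -> frozenset[Adjacency]:
    """All circular signed adjacencies of an order (canonicalised)."""
    n = len(order.order)
    if n < 2:
        return frozenset()
    return frozenset(
        _canonical_adjacency(order.order[i], order.order[(i + 1) % n])
        for i in range(n)
    )


def shared_adjacencies(a: GeneOrder, b: GeneOrder) -> frozenset[Adjacency]:
    """Signed adjacencies conserved between two orders (on their common genes)."""
    common = a.genes & b.genes
    if len(common) < 2:
        raise ValueError("orders share fewer than 2 genes")
    return adjacency_set(a.restricted(common)) & adjacency_set(b.restricted(common))


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` on the common gene set.

    Symmetric, non-negative, and 0 iff the two circular signed orders agree
    up to rotation/reflection; on equal gene sets it equals
    ``len(common genes) - len(shared_adjacencies)``.
    """
    common = a.genes & b.genes
    if len(common) < 2:
        raise ValueError("orders share fewer than 2 genes")
    adj_a = adjacency_set(a.restricted(common))
    adj_b = adjacency_set(b.restricted(common))
    return len(adj_a - adj_b)


def order_matrix(
    orders: list[GeneOrder],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise breakpoint-distance matrix + adjacency conservation table.

    The second frame lists every adjacency observed in any order with the
    fraction of orders containing it, sorted by descending frequency.
    """
    if len(orders) < 2:
        raise ValueError("need at least 2 orders")
    ids = [o.record_id for o in orders]
    n = len(orders)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = breakpoint_distance(orders[i], orders[j])
            mat[i, j] = mat[j, i] = d
    dist = pd.DataFrame(mat, index=ids, columns=ids)

    counts: dict[Adjacency, int] = {}
    for o in orders:
        for adj in adjacency_set(o):
            counts[adj] = counts.get(adj, 0) + 1
    rows = [
        {
            "adjacency": f"{'-' if s1 < 0 else ''}{g1}|{'-' if s2 < 0 else ''}{g2}",
            "n_orders": c,
            "frequency": c / n,
        }
        for (g1, s1, g2, s2), c in counts.items()
    ]
    freq = (
        pd.DataFrame(rows)
        .sort_values(["frequency", "adjacency"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return dist, freq


__all__ = [
    "GeneOrder",
    "extract_order",
    "order_from_string",
    "order_to_string",
    "adjacency_set",
    "shared_adjacencies",
    "breakpoint_distance",
    "order_matrix",
    "normalize_rotation",
]
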