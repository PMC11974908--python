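"""Occupancy binning, background-restricted enrichment and term clustering.

Proteins are split into four occupancy bins (<0.1%, 0.1-0.5%, 0.5-1%, >1%).
Each bin is tested for over-representation of user-supplied annotation
terms with a one-sided hypergeometric tail, against a *custom background*:
the full set of quantified (modified) proteins, not the whole genome — so
enrichment reflects occupancy class, not mere modifiability. Significant
-log10 P profiles over the four bins are then clustered (Euclidean
distance, single linkage).

An optional EASE mode reproduces the more conservative DAVID-style score
(tail computed with the overlap decremented by one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom

#: Bin labels, in increasing occupancy order. Boundaries are left-closed,
#: with the third bin closed at 1% so that ">1%" is strictly above 1.
BIN_LABELS = ("<0.1%", "0.1–0.5%", "0.5–1%", ">1%")

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class StoichBin:
    label: str
    members: frozenset


@dataclass(frozen=True)
class EnrichmentCell:
    term: str
    bin: str
    k: int  # overlap: term members inside the bin
    K: int  # term size within the background
    n: int  # bin size
    N: int  # background size
    p: float
    x: float  # -log10 p if p < alpha else 0


@dataclass
class ClusterResult:
    """Single-linkage dendrogram: merge order and ordered leaves."""

    merges: list  # (cluster_a, cluster_b, height); leaves 0..n-1, merge i -> n+i
    leaf_order: list  # term ids in dendrogram order
    terms: list  # term ids in leaf-index order


def assign_bin_label(stoich_pct: float) -> str:
    """Bin for an occupancy given in percent."""
    if math.isnan(stoich_pct) or stoich_pct < 0:
        raise ValueError(f"invalid occupancy {stoich_pct!r}%")
    if stoich_pct < 0.1:
        return BIN_LABELS[0]
    if stoich_pct < 0.5:
        return BIN_LABELS[1]
    if stoich_pct <= 1.0:
        return BIN_LABELS[2]
    return BIN_LABELS[3]


def assign_bins(stoich_pct_by_protein: dict) -> list:
    """Partition proteins into the four occupancy bins (input in percent)."""
    members: dict = {label: set() for label in BIN_LABELS}
    for pid, pct in stoich_pct_by_protein.items():
        members[assign_bin_label(pct)].add(pid)
    return [
        StoichBin(label=label, members=frozenset(members[label]))
        for label in BIN_LABELS
    ]


def hypergeom_enrich(
    bin_members,
    term_sets: dict,
    background,
    alpha: float = DEFAULT_ALPHA,
    ease: bool = False,
) -> list:
    """One-sided hypergeometric enrichment of each term in one bin.

    p = P(X >= k) for X ~ Hypergeom(N, K, n) with N the background size, K
    the term size within the background, n the bin size and k the observed
    overlap. In EASE mode the tail is computed at k - 1 (more conservative).
    Terms disjoint from the background are omitted; x = -log10 p when
    p < alpha, else 0.
    """
    background = set(background)
    bin_members = set(bin_members)
    if not bin_members <= background:
        extra = sorted(bin_members - background)[:5]
        raise ValueError(
            f"bin members outside background (e.g. {extra}); the background "
            "must contain every binned protein"
        )
    N, n = len(background), len(bin_members)
    cells = []
    for term in sorted(term_sets):
        in_bg = set(term_sets[term]) & background
        K = len(in_bg)
        if K == 0:
            continue
        k = len(in_bg & bin_members)
        k_eff = max(k - 1, 0) if ease else k
        # P(X >= k_eff) = sf(k_eff - 1)
        p = float(hypergeom.sf(k_eff - 1, N, K, n))
        p = min(max(p, 0.0), 1.0) or 5e-324  # clamp; keep p > 0
        x = -math.log10(p) if p < alpha else 0.0
        cells.append(
            EnrichmentCell(term=term, bin=None, k=k, K=K, n=n, N=N, p=p, x=x)
        )
    return cells


def enrichment_matrix(
    bins,
    term_sets: dict,
    background,
    alpha: float = DEFAULT_ALPHA,
    ease: bool = False,
):
    """Term-by-bin matrix of x = -log10 P for terms significant in >= 1 bin.

    Returns ``(terms, matrix, cells)`` with ``matrix`` an (n_terms, 4)
    array, rows ordered lexicographically by term id; non-significant
    entries are 0 (the minimal completion of the significant profile).
    """
    all_cells = []
    x_by_term: dict = {}
    for b in bins:
        for cell in hypergeom_enrich(
            b.members, term_sets, background, alpha=alpha, ease=ease
        ):
            cell = EnrichmentCell(**{**cell.__dict__, "bin": b.label})
            all_cells.append(cell)
            x_by_term.setdefault(cell.term, {})[b.label] = cell.x
    terms = sorted(t for t, xs in x_by_term.items() if any(v > 0 for v in xs.values()))
    matrix = np.array(
        [[x_by_term[t].get(label, 0.0) for label in BIN_LABELS] for t in terms],
        dtype=float,
    ).reshape(len(terms), len(BIN_LABELS))
    return terms, matrix, all_cells


def cluster_terms(terms, matrix) -> ClusterResult:
    """Single-linkage agglomeration of term profiles under Euclidean distance.

    Rows are sorted lexicographically by term id first, which makes the
    result invariant to input order and gives a deterministic tie-break.
    """
    terms = list(terms)
    matrix = np.asarray(matrix, dtype=float)
    if len(terms) != matrix.shape[0]:
        raise ValueError("terms and matrix rows disagree")
    order = sorted(range(len(terms)), key=lambda i: terms[i])
    terms = [terms[i] for i in order]
    matrix = matrix[order]

    if len(terms) < 2:
        return ClusterResult(merges=[], leaf_order=list(terms), terms=terms)

    Z = linkage(matrix, method="single", metric="euclidean")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    leaf_order = [terms[i] for i in leaves_list(Z)]
    return ClusterResult(merges=merges, leaf_order=leaf_order, terms=terms)
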