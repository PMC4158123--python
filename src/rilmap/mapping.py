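"""Linkage grouping, COUNT-based marker ordering and map construction.

The ordering objective is the COUNT criterion of the RECORD algorithm:
the total number of apparent recombination events, i.e. transitions
between consecutive non-missing homozygous calls along the marker order,
summed over all lines (heterozygous calls are treated as missing, the
standard RIL convention).  Orders are found by greedy sequential
insertion from multiple random starts, then locally refined by rippling:
exhaustive permutation of a sliding window (default 5 markers), keeping
a permutation only when it strictly lowers COUNT, sweeping until no
improvement remains.

Map construction is two-round: after the first ordering pass, singleton
calls (apparent double recombinants contradicted by agreeing flanks) are
corrected and missing genotypes re-imputed from flanks along the order,
then each group is re-ordered; per group the candidate order with the
shortest total Kosambi length wins.

Linkage groups are formed by single-linkage clustering at a
recombination-fraction cutoff (default 0.2).  Pairs with fewer informative
lines than ``min_informative`` (default 20) are treated as unlinked, a
guard against spurious joins from sparsely co-observed marker pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .binning import impute_along_order
from .mapfunc import kosambi_distance, ril_meiotic_rf
from .matrix import GenotypeMatrix

__all__ = [
    "PairwiseRF",
    "LinkageGroup",
    "OrderedMap",
    "pairwise_rf",
    "group_markers",
    "count_recombinations",
    "order_record",
    "ripple",
    "correct_singletons",
    "build_map",
]

#: adjacent recombination fractions are capped just below 0.5 so that the
#: Kosambi transform stays finite even for noisy adjacent pairs
MAX_ADJACENT_RF = 0.4999


@dataclass
class PairwiseRF:
    """Symmetric recombination-fraction estimates between marker pairs.

    ``rf`` is NaN where fewer than ``min_informative`` lines carry
    homozygous calls at both markers.
    """

    rf: pd.DataFrame
    n_informative: pd.DataFrame
    min_informative: int


@dataclass
class LinkageGroup:
    """One ordered linkage group with cumulative Kosambi positions."""

    label: str
    markers: list
    adjacent_rf: np.ndarray
    adjacent_cm: np.ndarray
    cum_cm: np.ndarray

    @property
    def length_cm(self) -> float:
        return float(self.cum_cm[-1]) if len(self.cum_cm) else 0.0

    def reversed(self) -> "LinkageGroup":
        adj_rf = self.adjacent_rf[::-1].copy()
        adj_cm = self.adjacent_cm[::-1].copy()
        return LinkageGroup(
            label=self.label,
            markers=list(reversed(self.markers)),
            adjacent_rf=adj_rf,
            adjacent_cm=adj_cm,
            cum_cm=np.concatenate([[0.0], np.cumsum(adj_cm)]),
        )


@dataclass
class OrderedMap:
    """A complete genetic map: ordered groups plus unplaced singletons."""

    groups: list
    unplaced: list = field(default_factory=list)

    @property
    def total_length_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))

    @property
    def n_markers(self) -> int:
        return int(sum(len(g.markers) for g in self.groups))

    def group(self, label: str) -> LinkageGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-marker table: group, rank, marker, adjacent rf/cM,
        cumulative cM."""
        rows = []
        for g in self.groups:
            for i, mk in enumerate(g.markers):
                rows.append(
                    (
                        g.label,
                        i + 1,
                        mk,
                        np.nan if i == 0 else g.adjacent_rf[i - 1],
                        np.nan if i == 0 else g.adjacent_cm[i - 1],
                        g.cum_cm[i],
                    )
                )
        return pd.DataFrame(
            rows, columns=["group", "rank", "marker", "adj_rf", "adj_cm", "cum_cm"]
        )


# ----------------------------------------------------------------------
# pairwise recombination fractions and grouping
# ----------------------------------------------------------------------

def pairwise_rf(matrix: GenotypeMatrix, min_informative: int = 20) -> PairwiseRF:
    """Estimate r between all marker pairs from opposite homozygous calls.

    r_hat = (# lines with opposite homozygotes) / (# lines homozygous at
    both markers).  H and U calls are excluded.  Pairs with fewer than
    ``min_informative`` informative lines are NaN.
    """
    if matrix.n_markers < 2:
        raise ValueError("need at least two markers")
    x = matrix.codes().astype(np.float64)
    informative = (x != 0).astype(np.float64)
    n_both = informative.T @ informative
    same = np.maximum(x, 0).T @ np.maximum(x, 0) + \
        np.maximum(-x, 0).T @ np.maximum(-x, 0)
    recomb = n_both - same
    with np.errstate(invalid="ignore", divide="ignore"):
        rf = np.where(n_both > 0, recomb / np.where(n_both > 0, n_both, 1), np.nan)
    rf = np.where(n_both < min_informative, np.nan, rf)
    np.fill_diagonal(rf, 0.0)
    markers = matrix.markers
    return PairwiseRF(
        rf=pd.DataFrame(rf, index=markers, columns=markers),
        n_informative=pd.DataFrame(
            n_both.astype(int), index=markers, columns=markers
        ),
        min_informative=min_informative,
    )


def group_markers(rf: PairwiseRF, cutoff: float = 0.2):
    """Single-linkage transitive closure at ``cutoff``.

    Markers i, j land in one group iff connected by a chain of defined
    pairwise r <= cutoff.  Returns ``(groups, singletons)`` with groups
    sorted by size descending (ties by first marker id); singleton
    groups are reported separately.
    """
    if not (0.0 < cutoff <= 0.5):
        raise ValueError("cutoff must lie in (0, 0.5]")
    r = rf.rf.to_numpy()
    markers = list(rf.rf.index)
    adj = np.nan_to_num(r, nan=np.inf) <= cutoff
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: dict = {}
    for mk, lab in zip(markers, labels):
        comps.setdefault(lab, []).append(mk)
    all_groups = sorted(comps.values(), key=lambda g: (-len(g), str(g[0])))
    groups = [g for g in all_groups if len(g) > 1]
    singletons = [g[0] for g in all_groups if len(g) == 1]
    return groups, singletons


# ----------------------------------------------------------------------
# COUNT and ordering
# ----------------------------------------------------------------------

def _count_codes(x: np.ndarray, order: np.ndarray) -> int:
    """COUNT for code matrix ``x`` (lines x markers, values -1/0/+1)
    along column order ``order`` (skip semantics: zeros are ignored)."""
    last = np.zeros(x.shape[0], dtype=np.int8)
    total = 0
    for j in order:
        c = x[:, j]
        nz = c != 0
        total += int(np.count_nonzero(nz & (last != 0) & (c != last)))
        last = np.where(nz, c, last)
    return total


def count_recombinations(matrix: GenotypeMatrix, order: list) -> int:
    """Total adjacent recombination events over all lines for ``order``.

    Transitions are counted between consecutive non-missing homozygous
    calls (H treated as missing).  ``order`` must be a permutation of
    the matrix's markers.
    """
    if sorted(map(str, order)) != sorted(map(str, matrix.markers)):
        raise ValueError("order must be a permutation of the matrix's markers")
    col = {mk: j for j, mk in enumerate(matrix.markers)}
    idx = np.array([col[mk] for mk in order], dtype=int)
    return _count_codes(matrix.codes(), idx)


def _prefix_suffix(x: np.ndarray, order: list) -> tuple[np.ndarray, np.ndarray]:
    """Per-line last non-zero call before each gap (P) and first non-zero
    call at/after each gap (S); shapes (n, L+1)."""
    n = x.shape[0]
    L = len(order)
    P = np.zeros((n, L + 1), dtype=np.int8)
    for k, j in enumerate(order):
        c = x[:, j]
        P[:, k + 1] = np.where(c != 0, c, P[:, k])
    S = np.zeros((n, L + 1), dtype=np.int8)
    for k in range(L - 1, -1, -1):
        c = x[:, order[k]]
        S[:, k] = np.where(c != 0, c, S[:, k + 1])
    return P, S


def _greedy_insertion(x: np.ndarray, perm: np.ndarray) -> list:
    """RECORD-style build-up: insert markers one by one at the COUNT-
    minimising position (first minimum on ties)."""
    order = [int(perm[0])]
    for j in perm[1:]:
        v = x[:, j][:, None]
        P, S = _prefix_suffix(x, order)
        nzv = v != 0
        t_new = (nzv & (P != 0) & (P != v)).sum(axis=0) + \
            (nzv & (S != 0) & (S != v)).sum(axis=0)
        t_old = (nzv & (P != 0) & (S != 0) & (P != S)).sum(axis=0)
        delta = t_new - t_old
        order.insert(int(np.argmin(delta)), int(j))
    return order


def _canonical(markers_in_order: list) -> list:
    """Orientation convention: first id lexicographically <= last."""
    if str(markers_in_order[0]) > str(markers_in_order[-1]):
        return list(reversed(markers_in_order))
    return list(markers_in_order)


def order_record(
    matrix: GenotypeMatrix,
    markers: list | None = None,
    seed: int = 0,
    n_starts: int = 30,
) -> list:
    """Order one linkage group by greedy insertion from random starts.

    Markers are added in a random sequence, each at the position that
    minimises COUNT; the best of ``n_starts`` shuffles is returned
    (ties keep the earlier candidate), canonically oriented.
    """
    markers = list(markers) if markers is not None else list(matrix.markers)
    if len(markers) < 2:
        raise ValueError("group must contain at least two markers")
    sub = matrix.subset(markers=markers)
    x = sub.codes()
    rng = np.random.default_rng(seed)
    best_order, best_count = None, None
    for _ in range(n_starts):
        perm = rng.permutation(len(markers))
        order = _greedy_insertion(x, perm)
        c = _count_codes(x, np.array(order))
        if best_count is None or c < best_count:
            best_order, best_count = order, c
    return _canonical([markers[j] for j in best_order])


def _local_count(prev: np.ndarray, cols: list, nxt: np.ndarray) -> int:
    """COUNT contribution of a window given flanking context calls."""
    last = prev.copy()
    total = 0
    for c in cols:
        nz = c != 0
        total += int(np.count_nonzero(nz & (last != 0) & (c != last)))
        last = np.where(nz, c, last)
    nz = nxt != 0
    total += int(np.count_nonzero(nz & (last != 0) & (nxt != last)))
    return total


def ripple(matrix: GenotypeMatrix, order: list, window: int = 5) -> list:
    """Refine ``order`` by exhaustive permutation of sliding windows.

    A window permutation is accepted only when it strictly lowers COUNT;
    full sweeps repeat until none improves.  The result's COUNT is never
    above the input's.  If ``window`` exceeds the group size, the whole
    group is permuted exhaustively when it has <= 8 markers; otherwise a
    ``ValueError`` is raised.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    order = list(order)
    L = len(order)
    sub = matrix.subset(markers=order)
    x = sub.codes()
    pos = {mk: j for j, mk in enumerate(order)}
    idx = [pos[mk] for mk in order]  # indices into x's columns

    if window > L:
        if L > 8:
            raise ValueError("window exceeds group size (> 8 markers)")
        best, best_count = idx, _count_codes(x, np.array(idx))
        for perm in itertools.permutations(range(L)):
            cand = [idx[p] for p in perm]
            c = _count_codes(x, np.array(cand))
            if c < best_count:
                best, best_count = cand, c
        return _canonical([order[j] for j in best])

    perms = [p for p in itertools.permutations(range(window))
             if p != tuple(range(window))]
    improved = True
    while improved:
        improved = False
        for s in range(L - window + 1):
            P, S = _prefix_suffix(x, idx)
            prev = P[:, s]
            nxt = S[:, s + window]
            win = idx[s:s + window]
            cols = [x[:, j] for j in win]
            base = _local_count(prev, cols, nxt)
            best_perm, best_c = None, base
            for p in perms:
                c = _local_count(prev, [cols[i] for i in p], nxt)
                if c < best_c:
                    best_perm, best_c = p, c
            if best_perm is not None:
                idx[s:s + window] = [win[i] for i in best_perm]
                improved = True
    return _canonical([order[j] for j in idx])


# ----------------------------------------------------------------------
# singleton correction and map building
# ----------------------------------------------------------------------

def correct_singletons(
    matrix: GenotypeMatrix, order: list
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Replace singleton calls by the flanking consensus along ``order``.

    A singleton is an interior homozygous call that differs from both
    nearest homozygous neighbours along the order while those two agree
    — an apparent double recombinant, usually a genotyping error.
    Heterozygous calls are treated as missing (never corrected, never
    used as flanks).  Boundary markers are never corrected.  Returns the
    corrected matrix and a log (line, marker, old, new).
    """
    df = matrix.calls.copy()
    cols = [mk for mk in order if mk in df.columns]
    sub = matrix.subset(markers=cols)
    x = sub.codes()
    records = []
    for i, line in enumerate(sub.lines):
        nz = np.nonzero(x[i])[0]
        if nz.size < 3:
            continue
        vals = x[i, nz]
        mid = vals[1:-1]
        single = (mid != vals[:-2]) & (mid != vals[2:]) & (vals[:-2] == vals[2:])
        for k in np.nonzero(single)[0]:
            j = nz[k + 1]
            new_call = "A" if vals[k] == 1 else "B"
            old_call = df.at[line, cols[j]]
            df.at[line, cols[j]] = new_call
            records.append((line, cols[j], old_call, new_call))
    log = pd.DataFrame(records, columns=["line", "marker", "old", "new"])
    return GenotypeMatrix(df, validate=False), log


def _adjacent_rf(matrix: GenotypeMatrix, order: list) -> np.ndarray:
    """Recombinant fraction between consecutive markers of ``order``.

    Uses the same skip semantics as COUNT: per line, each pair of
    consecutive non-missing homozygous calls spans one or more adjacent
    intervals; a junction (opposite calls) contributes 1/k recombinant
    weight to each of the k spanned intervals, and the line contributes
    one informative observation to each.  This keeps interval estimates
    unbiased when missingness is concentrated at recombination
    breakpoints — which flanking imputation guarantees, since it fills
    exactly the concordant (junction-free) runs.  Intervals with no
    spanning line get r = 0; estimates are capped at ``MAX_ADJACENT_RF``
    so the Kosambi transform stays defined.
    """
    x = matrix.subset(markers=order).codes()
    n, L = x.shape
    num = np.zeros(L - 1)
    den = np.zeros(L - 1)
    for i in range(n):
        nz = np.nonzero(x[i])[0]
        if nz.size < 2:
            continue
        vals = x[i, nz]
        for a, b, va, vb in zip(nz[:-1], nz[1:], vals[:-1], vals[1:]):
            den[a:b] += 1.0
            if va != vb:
                num[a:b] += 1.0 / (b - a)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
    return np.minimum(r, MAX_ADJACENT_RF)


def _rf_to_cm(r: np.ndarray, ril_correction: bool,
              generations: int | None = None) -> np.ndarray:
    """Adjacent r to Kosambi cM, optionally converting the accumulated
    RIL recombinant fraction back to meiotic r first (exact F_g
    inversion when ``generations`` is given, else the fixation-limit
    formula r = R / (2 - 2R))."""
    if ril_correction:
        r = ril_meiotic_rf(np.asarray(r, dtype=float), generations)
    return kosambi_distance(np.minimum(r, MAX_ADJACENT_RF))


def _map_length(matrix: GenotypeMatrix, order: list, ril_correction: bool,
                generations: int | None = None) -> float:
    return float(
        _rf_to_cm(_adjacent_rf(matrix, order), ril_correction, generations).sum()
    )


def _majority_chrom(markers: list, marker_info: pd.DataFrame | None):
    if marker_info is None or "chrom" not in getattr(marker_info, "columns", []):
        return None
    chroms = marker_info.reindex(markers)["chrom"].dropna()
    if chroms.empty:
        return None
    return chroms.mode().iloc[0]


def _split_at_gaps(order: list, cm: np.ndarray, max_gap: float) -> list:
    """Split an ordered group wherever an adjacent gap exceeds max_gap cM."""
    pieces, start = [], 0
    for i, d in enumerate(cm):
        if d > max_gap:
            pieces.append(order[start:i + 1])
            start = i + 1
    pieces.append(order[start:])
    return [p for p in pieces if p]


def build_map(
    matrix: GenotypeMatrix,
    marker_info: pd.DataFrame | None = None,
    *,
    cutoff: float = 0.2,
    min_informative: int = 20,
    window: int = 5,
    n_starts: int = 30,
    seed: int = 0,
    ril_correction: bool = False,
    generations: int | None = None,
    split_gap_cm: float | None = None,
) -> OrderedMap:
    """Two-round map construction from a QC'd, binned genotype matrix.

    Round 1 groups markers (single linkage at ``cutoff``), orders each
    group (greedy insertion + rippling), then corrects singletons and
    re-imputes missing calls from flanks along the order.  Round 2
    re-orders the corrected matrix; per group the candidate order with
    the shortest total Kosambi length is kept.  Groups are labelled by
    the majority physical chromosome of their markers when
    ``marker_info`` provides one, else LG1, LG2, ... by size.  Groups of
    one marker are emitted as unplaced.  Deterministic under ``seed``.
    """
    rf = pairwise_rf(matrix, min_informative=min_informative)
    groups, singletons = group_markers(rf, cutoff=cutoff)

    corrected = matrix
    round1_orders = []
    for gi, members in enumerate(groups):
        order1 = order_record(
            corrected, members, seed=seed + 1000 + gi, n_starts=n_starts
        )
        order1 = ripple(corrected, order1, window=window)
        round1_orders.append(order1)
        corrected, _ = correct_singletons(corrected, order1)
        corrected, _ = impute_along_order(corrected, order1)

    final_groups = []
    for gi, (members, order1) in enumerate(zip(groups, round1_orders)):
        order2 = order_record(
            corrected, members, seed=seed + 2000 + gi, n_starts=n_starts
        )
        order2 = ripple(corrected, order2, window=window)
        len1 = _map_length(corrected, order1, ril_correction, generations)
        len2 = _map_length(corrected, order2, ril_correction, generations)
        best = order1 if len1 <= len2 else order2
        orders = (
            _split_at_gaps(
                best,
                _rf_to_cm(_adjacent_rf(corrected, best), ril_correction,
                          generations),
                split_gap_cm,
            )
            if split_gap_cm is not None
            else [best]
        )
        for order in orders:
            if len(order) < 2:
                singletons.extend(order)
                continue
            adj_rf = _adjacent_rf(corrected, order)
            adj_cm = _rf_to_cm(adj_rf, ril_correction, generations)
            final_groups.append(
                LinkageGroup(
                    label="",
                    markers=list(order),
                    adjacent_rf=adj_rf,
                    adjacent_cm=adj_cm,
                    cum_cm=np.concatenate([[0.0], np.cumsum(adj_cm)]),
                )
            )

    final_groups.sort(key=lambda g: (-len(g.markers), str(g.markers[0])))
    used = set()
    for i, g in enumerate(final_groups):
        chrom = _majority_chrom(g.markers, marker_info)
        if chrom is not None and chrom not in used:
            g.label = str(chrom)
            used.add(chrom)
        else:
            g.label = f"LG{i + 1}"
    final_groups.sort(key=lambda g: str(g.label))
    return OrderedMap(groups=final_groups, unplaced=list(singletons))
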