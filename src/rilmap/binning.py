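"""Flanking imputation and recombination-bin construction.

Within a scaffold, a run of missing calls whose nearest non-missing
calls on both sides are identical is assumed to contain no recombination
event and is filled with the flanking call.  Imputation never crosses a
scaffold boundary and never changes a non-missing call.

After imputation, markers whose call vectors are exactly identical
(including the positions of remaining missing calls) collapse into one
recombination bin represented by the member with the fewest missing
calls (ties: lowest bp, then lexicographic id).  Exact equality, rather
than mere compatibility, is required so that binning never silently
imputes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = ["BinGroup", "impute_flanking", "impute_along_order", "bin_identical"]


@dataclass
class BinGroup:
    """A set of markers sharing one segregation pattern."""

    bin_id: str
    representative: str
    members: list
    pattern: tuple

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


def _fill_runs(block: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill U-runs with identical flanking calls; columns must be in
    physical order.  Returns (filled block, log of filled cells)."""
    v = block.to_numpy(dtype="U1")
    n, m = v.shape
    fwd = np.empty_like(v)
    last = np.full(n, "", dtype="U1")
    for j in range(m):
        last = np.where(v[:, j] != "U", v[:, j], last)
        fwd[:, j] = last
    bwd = np.empty_like(v)
    nxt = np.full(n, "", dtype="U1")
    for j in range(m - 1, -1, -1):
        nxt = np.where(v[:, j] != "U", v[:, j], nxt)
        bwd[:, j] = nxt
    fillable = (v == "U") & (fwd == bwd) & (fwd != "")
    out = np.where(fillable, fwd, v)
    rows, cols = np.nonzero(fillable)
    log = pd.DataFrame(
        {
            "line": block.index[rows],
            "marker": block.columns[cols],
            "call": out[rows, cols],
        }
    )
    filled = pd.DataFrame(out, index=block.index, columns=block.columns)
    return filled, log


def impute_flanking(
    matrix: GenotypeMatrix, marker_info: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Impute missing calls from identical flanking calls within scaffolds.

    ``marker_info`` is indexed by marker id with columns ``scaffold`` and
    ``bp``; only markers present there with both fields participate.
    Returns the imputed matrix and a log with one row per filled cell
    (line, marker, call).
    """
    df = matrix.calls.copy()
    info = marker_info.loc[
        marker_info.index.intersection(df.columns)
    ].dropna(subset=["scaffold", "bp"])
    logs = []
    for scaffold, sub in info.groupby("scaffold", sort=False):
        cols = sub.sort_values("bp").index.tolist()
        if len(cols) < 3:
            continue
        filled, log = _fill_runs(df[cols])
        df[cols] = filled
        if len(log):
            logs.append(log)
    log = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["line", "marker", "call"])
    )
    return GenotypeMatrix(df, validate=False), log


def impute_along_order(
    matrix: GenotypeMatrix, order: list
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the same flanking-fill rule along a linkage-map order.

    Used between mapping rounds, once a marker order exists, to infer
    missing genotypes from agreeing flanks regardless of scaffold."""
    df = matrix.calls.copy()
    cols = [m for m in order if m in df.columns]
    if len(cols) < 3:
        return matrix.copy(), pd.DataFrame(columns=["line", "marker", "call"])
    filled, log = _fill_runs(df[cols])
    df[cols] = filled
    return GenotypeMatrix(df, validate=False), log


def bin_identical(
    matrix: GenotypeMatrix,
    marker_info: pd.DataFrame | None = None,
    scope: str = "genome",
) -> tuple[GenotypeMatrix, list[BinGroup]]:
    """Merge markers with exactly identical call vectors into bins.

    ``scope`` is ``"genome"`` (default) or ``"scaffold"``; the latter
    only merges markers on the same scaffold.  Returns the reduced
    matrix (one column per bin, representative's id, original column
    order) and the list of :class:`BinGroup`.
    """
    if scope not in ("genome", "scaffold"):
        raise ValueError("scope must be 'genome' or 'scaffold'")
    v = matrix.values()
    df = matrix.calls
    scaffold = {}
    bp = {}
    if marker_info is not None:
        idx = marker_info.index
        scaffold = marker_info["scaffold"].to_dict() if "scaffold" in marker_info else {}
        bp = marker_info["bp"].to_dict() if "bp" in marker_info else {}
    groups: dict = {}
    for j, mk in enumerate(df.columns):
        pattern = v[:, j].tobytes()
        key = (scaffold.get(mk), pattern) if scope == "scaffold" else pattern
        groups.setdefault(key, []).append(j)

    def sort_key(j):
        mk = df.columns[j]
        n_missing = int((v[:, j] == "U").sum())
        pos = bp.get(mk)
        pos = float("inf") if pos is None or pd.isna(pos) else float(pos)
        return (n_missing, pos, str(mk))

    bins = []
    rep_cols = []
    # deterministic bin order: by first-occurring member column
    for key, members in sorted(groups.items(), key=lambda kv: kv[1][0]):
        rep = min(members, key=sort_key)
        members_sorted = sorted(members)
        bins.append(
            BinGroup(
                bin_id=f"bin{len(bins) + 1:04d}",
                representative=df.columns[rep],
                members=[df.columns[j] for j in members_sorted],
                pattern=tuple(v[:, members_sorted[0]]),
            )
        )
        rep_cols.append(df.columns[rep])
    reduced = matrix.subset(markers=rep_cols)
    return reduced, bins
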