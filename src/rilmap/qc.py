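"""Marker- and line-level quality filters for RIL genotype matrices.

Two named filter profiles reflect the two stages at which raw calls are
screened in a RAD-seq mapping workflow:

``rad``
    SNP-calling stage: up to 66 % missing data per marker (inclusive),
    at most 10 % heterozygosity, parental allele frequency within
    [0.2, 0.8].
``map``
    pre-mapping stage: at most 30 % missing data per marker, same
    heterozygosity and allele-frequency bounds; lines missing more than
    25 % of calls are dropped.

Allele frequency is computed over homozygous calls only (freq of A =
nA / (nA + nB)); in a RIL heterozygosity is transient, so the 0.2-0.8
band targets parental allele balance among fixed lines.  "More than"
thresholds are strict (a line at exactly 10 % heterozygosity is kept);
"up to" thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = [
    "FILTER_PROFILES",
    "QCReport",
    "allele_frequency",
    "marker_stats",
    "line_stats",
    "filter_markers",
    "filter_lines",
]

FILTER_PROFILES = {
    "rad": dict(max_missing_frac=0.66, max_het_frac=0.10, af_low=0.2, af_high=0.8),
    "map": dict(max_missing_frac=0.30, max_het_frac=0.10, af_low=0.2, af_high=0.8),
}

#: line-level missing-call cutoff used by the ``map`` profile (strict >)
MAP_PROFILE_LINE_MISSING = 0.25
#: line-level residual-heterozygosity cutoff (strict >)
DEFAULT_LINE_HET = 0.10


@dataclass
class QCReport:
    """Per-marker and per-line statistics plus removal lists.

    ``removed_markers`` / ``removed_lines`` have columns ``id`` and
    ``reason`` (comma-joined codes: missing, heterozygosity,
    allele_frequency, line_missing, line_heterozygosity).
    """

    per_marker: pd.DataFrame
    per_line: pd.DataFrame
    removed_markers: pd.DataFrame
    removed_lines: pd.DataFrame


def allele_frequency(calls) -> float:
    """Frequency of the A allele among homozygous calls of one marker.

    H and U calls are excluded.  Returns NaN (undefined) when no
    homozygous calls remain.
    """
    v = np.asarray(list(calls) if not isinstance(calls, (np.ndarray, pd.Series))
                   else calls, dtype="U1")
    n_a = int((v == "A").sum())
    n_b = int((v == "B").sum())
    if n_a + n_b == 0:
        return float("nan")
    return n_a / (n_a + n_b)


def marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """missing fraction, het fraction (of non-missing), freq(A) per marker."""
    v = matrix.values()
    n = v.shape[0]
    miss = (v == "U").sum(axis=0)
    het = (v == "H").sum(axis=0)
    n_a = (v == "A").sum(axis=0).astype(float)
    n_b = (v == "B").sum(axis=0).astype(float)
    non_missing = n - miss
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(non_missing > 0, het / non_missing, np.nan)
        hom = n_a + n_b
        freq_a = np.where(hom > 0, n_a / np.where(hom > 0, hom, 1), np.nan)
    return pd.DataFrame(
        {
            "missing_frac": miss / n,
            "het_frac": het_frac,
            "freq_a": freq_a,
            "n_hom": hom.astype(int),
        },
        index=matrix.calls.columns,
    )


def line_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """missing fraction and het fraction (of non-missing) per line."""
    v = matrix.values()
    m = v.shape[1]
    miss = (v == "U").sum(axis=1)
    het = (v == "H").sum(axis=1)
    non_missing = m - miss
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(non_missing > 0, het / non_missing, np.nan)
    return pd.DataFrame(
        {"missing_frac": miss / m, "het_frac": het_frac},
        index=matrix.calls.index,
    )


def _empty_removed() -> pd.DataFrame:
    return pd.DataFrame({"id": pd.Series(dtype=object),
                         "reason": pd.Series(dtype=object)})


def filter_markers(
    matrix: GenotypeMatrix,
    max_missing_frac: float | None = None,
    max_het_frac: float | None = None,
    af_low: float | None = None,
    af_high: float | None = None,
    profile: str | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers exceeding missing/het limits or outside the AF band.

    Thresholds default to the named ``profile`` ("rad" unless given);
    explicit keyword arguments override profile values.  Markers whose
    allele frequency is undefined (no homozygous calls) are not removed
    on allele-frequency grounds but are flagged in the report.
    """
    params = dict(FILTER_PROFILES[profile or "rad"])
    overrides = dict(max_missing_frac=max_missing_frac, max_het_frac=max_het_frac,
                     af_low=af_low, af_high=af_high)
    params.update({k: v for k, v in overrides.items() if v is not None})
    if not (0 <= params["af_low"] < params["af_high"] <= 1):
        raise ValueError("require 0 <= af_low < af_high <= 1")

    stats = marker_stats(matrix)
    too_missing = stats["missing_frac"] > params["max_missing_frac"]
    too_het = stats["het_frac"] > params["max_het_frac"]
    af = stats["freq_a"]
    bad_af = (af < params["af_low"]) | (af > params["af_high"])  # NaN -> False

    reasons = []
    for mk in stats.index:
        r = []
        if too_missing[mk]:
            r.append("missing")
        if too_het[mk]:
            r.append("heterozygosity")
        if bad_af[mk]:
            r.append("allele_frequency")
        if r:
            reasons.append((mk, ",".join(r)))
    removed = pd.DataFrame(reasons, columns=["id", "reason"]) if reasons \
        else _empty_removed()
    keep = [mk for mk in matrix.markers if mk not in set(removed["id"])]
    out = matrix.subset(markers=keep)
    report = QCReport(
        per_marker=stats,
        per_line=line_stats(matrix),
        removed_markers=removed,
        removed_lines=_empty_removed(),
    )
    return out, report


def filter_lines(
    matrix: GenotypeMatrix,
    max_line_het: float = DEFAULT_LINE_HET,
    max_line_missing: float | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove lines with more than ``max_line_het`` residual heterozygosity
    (strict inequality) and, when given, more than ``max_line_missing``
    missing calls."""
    stats = line_stats(matrix)
    too_het = stats["het_frac"] > max_line_het
    too_missing = (
        stats["missing_frac"] > max_line_missing
        if max_line_missing is not None
        else pd.Series(False, index=stats.index)
    )
    reasons = []
    for ln in stats.index:
        r = []
        if too_het[ln]:
            r.append("line_heterozygosity")
        if too_missing[ln]:
            r.append("line_missing")
        if r:
            reasons.append((ln, ",".join(r)))
    removed = pd.DataFrame(reasons, columns=["id", "reason"]) if reasons \
        else _empty_removed()
    keep = [ln for ln in matrix.lines if ln not in set(removed["id"])]
    out = matrix.subset(lines=keep)
    report = QCReport(
        per_marker=marker_stats(matrix),
        per_line=stats,
        removed_markers=_empty_removed(),
        removed_lines=removed,
    )
    return out, report
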