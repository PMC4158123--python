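"""Map summary statistics, genome coverage, heterozygosity and
segregation distortion diagnostics.

Conventions
-----------
* Mean adjacent-marker spacing is reported as total map length divided by
  total marker count — the convention used in published map summaries of
  this kind (653 cM over 1,336 markers prints as 0.5 cM).
* The Chakravarti method-4 genome-length estimate scales each linkage
  group's observed length by (m + 1)/(m - 1), m = markers in the group;
  coverage is observed / estimated length (Sekino-Hara ratio).  A
  ``global`` mode applies the factor once to the whole map.
* The segregation distortion test is a 1:1 chi-square on homozygous
  calls only (df = 1); a marker is called distorted when p < alpha AND
  its allele frequency falls outside the open interval (0.4, 0.6).  No
  multiple-testing correction is applied by default; a Bonferroni flag
  is available.
* Segregation distortion regions (SDRs) are maximal runs of >= 2
  consecutive mapped markers distorted toward the same parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .matrix import GenotypeMatrix
from .mapping import OrderedMap

__all__ = [
    "CoverageEstimate",
    "DistortionRecord",
    "map_summary",
    "mean_marker_spacing",
    "chakravarti_estimate",
    "chakravarti_from_table",
    "residual_heterozygosity",
    "heterozygosity_fold",
    "distortion_test",
    "distortion_table",
    "detect_sdr",
]


# ----------------------------------------------------------------------
# map summary and coverage
# ----------------------------------------------------------------------

def mean_marker_spacing(total_length_cm: float, n_markers: int) -> float:
    """Average adjacent-marker distance: total map length / marker count."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return total_length_cm / n_markers


def map_summary(omap: OrderedMap) -> pd.DataFrame:
    """Per-group and total marker counts, lengths, spacing, largest gap."""
    if not omap.groups:
        raise ValueError("map has no linkage groups")
    rows = []
    for g in omap.groups:
        gaps = g.adjacent_cm
        rows.append(
            (
                g.label,
                len(g.markers),
                g.length_cm,
                mean_marker_spacing(g.length_cm, len(g.markers)),
                float(gaps.max()) if len(gaps) else 0.0,
            )
        )
    df = pd.DataFrame(
        rows, columns=["group", "n_markers", "length_cm", "mean_spacing_cm",
                       "largest_gap_cm"]
    )
    total = pd.DataFrame(
        [
            (
                "total",
                int(df["n_markers"].sum()),
                float(df["length_cm"].sum()),
                mean_marker_spacing(df["length_cm"].sum(), df["n_markers"].sum()),
                float(df["largest_gap_cm"].max()),
            )
        ],
        columns=df.columns,
    )
    return pd.concat([df, total], ignore_index=True)


@dataclass
class CoverageEstimate:
    """Observed vs Chakravarti-estimated map length and genome coverage."""

    per_group: pd.DataFrame
    observed_total_cm: float
    estimated_total_cm: float
    coverage: float


def chakravarti_from_table(
    groups: pd.DataFrame, mode: str = "per_group"
) -> CoverageEstimate:
    """Coverage from a table with columns ``n_markers`` and ``length_cm``.

    ``mode="per_group"`` (default) applies (m+1)/(m-1) to each group and
    sums; ``mode="global"`` applies the factor once with m = total
    markers.  Groups with fewer than 2 markers are excluded with a
    warning column rather than an exception.
    """
    if mode not in ("per_group", "global"):
        raise ValueError("mode must be 'per_group' or 'global'")
    df = groups.copy()
    usable = df["n_markers"] >= 2
    df["estimated_cm"] = np.where(
        usable,
        df["length_cm"] * (df["n_markers"] + 1) / np.maximum(df["n_markers"] - 1, 1),
        np.nan,
    )
    df["excluded"] = ~usable
    observed = float(df.loc[usable, "length_cm"].sum())
    if mode == "per_group":
        estimated = float(df.loc[usable, "estimated_cm"].sum())
    else:
        m = int(df.loc[usable, "n_markers"].sum())
        estimated = observed * (m + 1) / (m - 1)
    return CoverageEstimate(
        per_group=df,
        observed_total_cm=observed,
        estimated_total_cm=estimated,
        coverage=observed / estimated,
    )


def chakravarti_estimate(omap: OrderedMap, mode: str = "per_group") -> CoverageEstimate:
    """Chakravarti method-4 genome length and coverage for a built map."""
    table = pd.DataFrame(
        {
            "group": [g.label for g in omap.groups],
            "n_markers": [len(g.markers) for g in omap.groups],
            "length_cm": [g.length_cm for g in omap.groups],
        }
    )
    return chakravarti_from_table(table, mode=mode)


# ----------------------------------------------------------------------
# residual heterozygosity
# ----------------------------------------------------------------------

def heterozygosity_fold(observed_het: float, generations: int) -> float:
    """Observed / expected heterozygosity for an F_g population
    (expected = (1/2)^(g-1))."""
    if generations < 2:
        raise ValueError("generations must be >= 2")
    return observed_het / 0.5 ** (generations - 1)


def residual_heterozygosity(matrix: GenotypeMatrix, generations: int) -> dict:
    """Per-line and whole-population heterozygote fractions vs F_g
    expectation.

    Returns keys ``per_line`` (Series of H / non-missing per line),
    ``population`` (pooled fraction), ``expected`` and ``fold``.
    """
    v = matrix.values()
    het = (v == "H").sum(axis=1)
    non_missing = (v != "U").sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_line = np.where(non_missing > 0, het / np.maximum(non_missing, 1), np.nan)
    population = float(het.sum() / max(non_missing.sum(), 1))
    expected = 0.5 ** (generations - 1)
    return {
        "per_line": pd.Series(per_line, index=matrix.calls.index),
        "population": population,
        "expected": expected,
        "fold": heterozygosity_fold(population, generations),
    }


# ----------------------------------------------------------------------
# segregation distortion
# ----------------------------------------------------------------------

@dataclass
class DistortionRecord:
    marker: str
    n_a: int
    n_b: int
    n_h: int
    n_u: int
    freq_a: float
    chi2: float
    p_value: float
    distorted: bool
    direction: str  # "A", "B" or "none"


def distortion_test(
    calls,
    alpha: float = 0.05,
    af_bounds: tuple[float, float] | None = (0.4, 0.6),
    marker: str = "",
) -> DistortionRecord:
    """Chi-square 1:1 test on homozygous calls of one marker.

    Distorted iff p < alpha and freq(A) lies outside the open interval
    ``af_bounds`` (band disabled with ``af_bounds=None``).  Direction is
    the over-represented parent.  With no homozygous calls the record is
    undefined (NaN statistics, not distorted).
    """
    v = np.asarray(list(calls) if not isinstance(calls, (np.ndarray, pd.Series))
                   else calls, dtype="U1")
    n_a = int((v == "A").sum())
    n_b = int((v == "B").sum())
    n_h = int((v == "H").sum())
    n_u = int((v == "U").sum())
    if n_a + n_b == 0:
        return DistortionRecord(marker, n_a, n_b, n_h, n_u,
                                float("nan"), float("nan"), float("nan"),
                                False, "none")
    expected = (n_a + n_b) / 2.0
    stat = (n_a - expected) ** 2 / expected + (n_b - expected) ** 2 / expected
    p = float(chi2.sf(stat, df=1))
    freq_a = n_a / (n_a + n_b)
    in_band = af_bounds is not None and af_bounds[0] < freq_a < af_bounds[1]
    distorted = (p < alpha) and not in_band
    direction = "none"
    if distorted:
        direction = "A" if n_a > n_b else "B"
    return DistortionRecord(marker, n_a, n_b, n_h, n_u, freq_a, float(stat),
                            p, distorted, direction)


def distortion_table(
    matrix: GenotypeMatrix,
    alpha: float = 0.05,
    af_bounds: tuple[float, float] | None = (0.4, 0.6),
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-marker distortion records as a DataFrame (index = marker)."""
    eff_alpha = alpha / matrix.n_markers if bonferroni else alpha
    v = matrix.values()
    records = [
        distortion_test(v[:, j], alpha=eff_alpha, af_bounds=af_bounds,
                        marker=mk)
        for j, mk in enumerate(matrix.markers)
    ]
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("marker")
    return df


def detect_sdr(
    omap: OrderedMap,
    distortion: pd.DataFrame,
    max_gap_markers: int = 0,
) -> pd.DataFrame:
    """Segregation distortion regions on an ordered map.

    A region is a maximal run of >= 2 consecutive mapped markers
    distorted toward the same parent; up to ``max_gap_markers``
    interleaved non-distorted markers are tolerated inside a run
    (markers distorted toward the other parent always split).  Returns
    one row per region: group, direction, start/end cM, size in cM,
    marker count and member list.
    """
    rows = []
    for g in omap.groups:
        dirs = [
            distortion["direction"].get(mk, "none")
            if mk in distortion.index and distortion.loc[mk, "distorted"]
            else "none"
            for mk in g.markers
        ]
        i = 0
        n = len(g.markers)
        while i < n:
            if dirs[i] == "none":
                i += 1
                continue
            direction = dirs[i]
            members = [i]
            j = i + 1
            gap = 0
            while j < n:
                if dirs[j] == direction:
                    members.append(j)
                    gap = 0
                elif dirs[j] == "none" and gap < max_gap_markers:
                    gap += 1
                else:
                    break
                j += 1
            if len(members) >= 2:
                start, end = members[0], members[-1]
                rows.append(
                    (
                        g.label,
                        direction,
                        float(g.cum_cm[start]),
                        float(g.cum_cm[end]),
                        float(g.cum_cm[end] - g.cum_cm[start]),
                        len(members),
                        [g.markers[k] for k in members],
                    )
                )
            i = members[-1] + 1
    return pd.DataFrame(
        rows,
        columns=["group", "direction", "start_cm", "end_cm", "size_cm",
                 "n_markers", "members"],
    )
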