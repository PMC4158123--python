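"""Kosambi map function and its inverse.

The Kosambi function converts a recombination fraction ``r`` into an
additive map distance while allowing for moderate crossover
interference:

    d = 1/4 * ln((1 + 2r) / (1 - 2r))   [Morgans]

Distances are handled in centiMorgans throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kosambi_distance",
    "inverse_kosambi",
    "ril_observed_rf",
    "ril_meiotic_rf",
]


def kosambi_distance(r):
    """Map distance in cM for recombination fraction ``r`` (scalar or array).

    Raises ``ValueError`` for r < 0 or r >= 0.5, where the function is
    undefined.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * arr) / (1.0 - 2.0 * arr))
    return float(d) if np.isscalar(r) or getattr(r, "ndim", 0) == 0 else d


def inverse_kosambi(d_cm):
    """Recombination fraction for a map distance ``d_cm`` in cM.

    Inverse of :func:`kosambi_distance`: r = tanh(2d)/2 with d in Morgans.
    Raises ``ValueError`` for negative distances.
    """
    arr = np.asarray(d_cm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * arr / 100.0)
    return float(r) if np.isscalar(d_cm) or getattr(d_cm, "ndim", 0) == 0 else r


def ril_observed_rf(r: float, generations: int) -> float:
    """Expected observed recombinant fraction in an F_g selfing RIL.

    The fraction of recombinant two-locus genotypes among lines
    homozygous at both loci (heterozygotes are treated as missing by the
    mapping estimators), for per-meiosis recombination fraction ``r``
    and single-seed descent to generation ``generations``.  Computed
    exactly by propagating the two-locus diplotype Markov chain from the
    F1; at fixation this approaches the classical 2r/(1+2r).
    """
    if not (0.0 <= r < 0.5):
        raise ValueError("r must lie in [0, 0.5)")
    if generations < 2:
        raise ValueError("generations must be >= 2")
    # haplotypes: 0=AB, 1=Ab, 2=aB, 3=ab; diplotype state = (i, j), i <= j
    states = [(i, j) for i in range(4) for j in range(i, 4)]
    index = {s: k for k, s in enumerate(states)}
    alleles = [(0, 0), (0, 1), (1, 0), (1, 1)]

    def gamete_probs(i, j):
        p = np.zeros(4)
        p[i] += (1 - r) / 2
        p[j] += (1 - r) / 2
        (a1, a2), (b1, b2) = alleles[i], alleles[j]
        p[alleles.index((a1, b2))] += r / 2
        p[alleles.index((b1, a2))] += r / 2
        return p

    T = np.zeros((len(states), len(states)))
    for k, (i, j) in enumerate(states):
        g = gamete_probs(i, j)
        off = np.outer(g, g)
        for a in range(4):
            for b in range(a, 4):
                T[k, index[(a, b)]] += off[a, b] if a == b else off[a, b] + off[b, a]
    dist = np.zeros(len(states))
    dist[index[(0, 3)]] = 1.0  # F1: AB/ab
    for _ in range(generations - 1):
        dist = dist @ T
    hom = {h: dist[index[(h, h)]] for h in range(4)}
    denom = sum(hom.values())
    return (hom[1] + hom[2]) / denom if denom > 0 else 0.0


def ril_meiotic_rf(r_obs, generations: int | None = None):
    """Convert an observed RIL recombinant fraction back to meiotic r.

    With ``generations`` given, inverts :func:`ril_observed_rf`
    numerically (exact for F_g single-seed descent); otherwise applies
    the fixation-limit correction r = R / (2 - 2R).  Accepts scalars or
    arrays; values are clipped into the invertible range.
    """
    arr = np.atleast_1d(np.asarray(r_obs, dtype=float))
    if generations is None:
        out = arr / np.maximum(2.0 - 2.0 * arr, 1e-12)
    else:
        from scipy.optimize import brentq

        hi = 0.499999
        r_max = ril_observed_rf(hi, generations)
        out = np.empty_like(arr)
        for k, R in enumerate(arr):
            if R <= 0:
                out[k] = 0.0
            elif R >= r_max:
                out[k] = hi
            else:
                out[k] = brentq(
                    lambda x: ril_observed_rf(x, generations) - R, 0.0, hi,
                    xtol=1e-10,
                )
    out = np.clip(out, 0.0, 0.499999)
    return float(out[0]) if np.isscalar(r_obs) or getattr(r_obs, "ndim", 0) == 0 \
        else out
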