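"""Seeded simulator for F_g-derived RIL populations with a known truth set.

A recombinant inbred line (RIL) population starts from a fully
heterozygous F1 and is advanced by single-seed descent: each line selfs
for g-1 generations, halving residual heterozygosity per generation so
the expected heterozygote fraction at generation g is (1/2)^(g-1)
(1.5625 % for an F7-derived population).

Meiosis is Markovian along each chromosome: a gamete starts from one of
the two parental haplotypes with equal probability and switches between
them independently in each adjacent marker interval with probability
r = inverse_kosambi(delta_cM).  Using the inverse of the same map
function the mapping stage uses makes distance-recovery tests
self-consistent; no crossover interference beyond the map function is
modelled.

Transmission distortion is modelled as gametic viability weighting: each
gamete carrying the disfavoured allele at a distortion locus survives
with probability w per generation (rejection sampling), mimicking the
localized parental-allele skews seen in real RIL populations.

Observation noise (missing calls and A<->B genotyping errors) is applied
as a separate, reproducible step so that the pre-noise matrix can serve
as ground truth for imputation and error-correction tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapfunc import inverse_kosambi
from .matrix import GenotypeMatrix

__all__ = [
    "MarkerSpec",
    "ChromosomeSpec",
    "DistortionLocus",
    "SimConfig",
    "TruthSet",
    "simulate_ril_population",
    "apply_observation_noise",
    "cpr01_like_config",
]


@dataclass(frozen=True)
class MarkerSpec:
    """One marker: id, true genetic position (cM), physical position (bp)."""

    marker_id: str
    cm: float
    bp: int
    scaffold: str


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    markers: tuple

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))
        cms = [m.cm for m in self.markers]
        bps = [m.bp for m in self.markers]
        if any(b <= a for a, b in zip(cms, cms[1:])):
            raise ValueError(
                f"chromosome {self.name}: cM positions must be strictly increasing"
            )
        if any(b <= a for a, b in zip(bps, bps[1:])):
            raise ValueError(
                f"chromosome {self.name}: bp positions must be strictly increasing"
            )


@dataclass(frozen=True)
class DistortionLocus:
    """Viability weight w in (0, 1] applied per generation to gametes
    carrying the disfavoured parental allele at ``marker_id``."""

    marker_id: str
    weight: float
    disfavored: str = "B"

    def __post_init__(self):
        if not (0.0 < self.weight <= 1.0):
            raise ValueError("viability weight must lie in (0, 1]")
        if self.disfavored not in ("A", "B"):
            raise ValueError("disfavored allele must be 'A' or 'B'")


@dataclass
class SimConfig:
    """Population design for :func:`simulate_ril_population`."""

    chromosomes: list
    n_lines: int = 92
    generations: int = 7
    missing_rate: float = 0.0
    error_rate: float = 0.0
    distortion_loci: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.generations < 2:
            raise ValueError("generations must be >= 2 (F2 or later)")
        if self.n_lines < 1:
            raise ValueError("n_lines must be positive")
        for rate in (self.missing_rate, self.error_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        ids = [m.marker_id for c in self.chromosomes for m in c.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique across chromosomes")
        known = set(ids)
        for locus in self.distortion_loci:
            if locus.marker_id not in known:
                raise ValueError(f"distortion locus {locus.marker_id} not in map")

    @property
    def marker_ids(self) -> list:
        return [m.marker_id for c in self.chromosomes for m in c.markers]

    def marker_info(self) -> pd.DataFrame:
        """MarkerInfo table (scaffold, chrom, bp, cM) for the simulated map."""
        rows = [
            (m.marker_id, m.scaffold, c.name, m.bp, m.cm)
            for c in self.chromosomes
            for m in c.markers
        ]
        df = pd.DataFrame(rows, columns=["marker", "scaffold", "chrom", "bp", "cm"])
        return df.set_index("marker")


@dataclass
class TruthSet:
    """Ground truth of one simulated population.

    ``genotypes`` is the pre-noise call matrix (never missing);
    ``order`` maps chromosome name -> true marker order; ``cm`` gives the
    true genetic position of every marker.
    """

    order: dict
    cm: pd.Series
    genotypes: GenotypeMatrix
    distortion_loci: list


def _make_gametes(hap: np.ndarray, r: np.ndarray, rng: np.random.Generator,
                  weights: np.ndarray | None) -> np.ndarray:
    """One gamete per line from a (n, 2, m) haplotype pair.

    ``r`` holds the m-1 adjacent-interval crossover probabilities.
    ``weights`` (m-length, values in (0,1], mostly 1) are viability
    multipliers indexed by the allele code carried: weights[j] applies
    when the gamete carries allele 1 at marker j if sign +, handled by
    caller via per-allele weight arrays.
    """
    n, _, m = hap.shape
    out = np.empty((n, m), dtype=np.int8)
    pending = np.arange(n)
    while pending.size:
        k = pending.size
        start = rng.integers(0, 2, size=k)
        if m > 1:
            switches = rng.random((k, m - 1)) < r
            idx = np.empty((k, m), dtype=np.int64)
            idx[:, 0] = start
            idx[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
        else:
            idx = start[:, None]
        gam = hap[pending[:, None], idx, np.arange(m)[None, :]]
        if weights is None:
            out[pending] = gam
            break
        # viability: weights is (2, m) — survival multiplier per allele code
        w = np.prod(np.where(gam == 0, weights[0], weights[1]), axis=1)
        accept = rng.random(k) < w
        out[pending[accept]] = gam[accept]
        pending = pending[~accept]
    return out


def simulate_ril_population(config: SimConfig):
    """Simulate a RIL genotype matrix plus its :class:`TruthSet`.

    Returns ``(matrix, truth)`` where ``matrix`` already carries the
    configured observation noise and ``truth.genotypes`` is the pre-noise
    matrix.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_lines, config.generations
    blocks = []
    for chrom in config.chromosomes:
        m = len(chrom.markers)
        cms = np.array([mk.cm for mk in chrom.markers])
        r = inverse_kosambi(np.diff(cms)) if m > 1 else np.empty(0)
        weights = None
        loci = [
            (i, locus)
            for i, mk in enumerate(chrom.markers)
            for locus in config.distortion_loci
            if locus.marker_id == mk.marker_id
        ]
        if loci:
            weights = np.ones((2, m))
            for i, locus in loci:
                code = 0 if locus.disfavored == "A" else 1
                weights[code, i] = locus.weight
        # F1: haplotype 0 all parent-1 alleles, haplotype 1 all parent-2
        hap = np.zeros((n, 2, m), dtype=np.int8)
        hap[:, 1, :] = 1
        for _ in range(g - 1):
            g1 = _make_gametes(hap, r, rng, weights)
            g2 = _make_gametes(hap, r, rng, weights)
            hap = np.stack([g1, g2], axis=1)
        blocks.append(hap)
    geno = np.concatenate([h.sum(axis=1) for h in blocks], axis=1)
    calls = np.full(geno.shape, "H", dtype="U1")
    calls[geno == 0] = "A"
    calls[geno == 2] = "B"
    lines = [f"RIL{str(i + 1).zfill(3)}" for i in range(n)]
    markers = config.marker_ids
    pre_noise = GenotypeMatrix.from_values(calls, lines, markers)
    truth = TruthSet(
        order={c.name: [m.marker_id for m in c.markers] for c in config.chromosomes},
        cm=pd.Series(
            [m.cm for c in config.chromosomes for m in c.markers], index=markers
        ),
        genotypes=pre_noise,
        distortion_loci=list(config.distortion_loci),
    )
    noise_seed = int(rng.integers(0, 2**31 - 1))
    observed = apply_observation_noise(
        pre_noise, config.missing_rate, config.error_rate, seed=noise_seed
    )
    return observed, truth


def apply_observation_noise(matrix: GenotypeMatrix, missing_rate: float,
                            error_rate: float, seed: int) -> GenotypeMatrix:
    """Return a copy with calls masked to U and homozygotes flipped A<->B.

    Each call is independently set missing with ``missing_rate``; each
    surviving homozygous call is flipped with ``error_rate``.  The input
    matrix is left unchanged.
    """
    for rate in (missing_rate, error_rate):
        if not (0.0 <= rate < 1.0):
            raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    v = matrix.values().copy()
    if missing_rate > 0:
        v[rng.random(v.shape) < missing_rate] = "U"
    if error_rate > 0:
        hom = (v == "A") | (v == "B")
        flip = hom & (rng.random(v.shape) < error_rate)
        v[flip] = np.where(v[flip] == "A", "B", "A")
    return GenotypeMatrix.from_values(v, matrix.lines, matrix.markers)


def cpr01_like_config(
    n_lines: int = 92,
    generations: int = 7,
    n_chromosomes: int = 8,
    markers_per_chromosome: int = 25,
    length_cm: float = 80.0,
    mb_per_chromosome: float = 40.0,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    distortion_loci: list | None = None,
    seed: int = 0,
) -> SimConfig:
    """Study-like default design: 92 F7-derived lines on 8 chromosomes.

    Marker positions are evenly spaced in cM and bp; ids encode
    chromosome and rank.  The defaults mirror the population structure
    the pipeline was designed around (92 RILs, F7, eight ~70-100 cM
    linkage groups).
    """
    chroms = []
    for c in range(1, n_chromosomes + 1):
        spacing = length_cm / max(markers_per_chromosome - 1, 1)
        bp_spacing = int(mb_per_chromosome * 1e6 / max(markers_per_chromosome - 1, 1))
        markers = [
            MarkerSpec(
                marker_id=f"Ca{c}m{str(i + 1).zfill(3)}",
                cm=round(i * spacing, 6),
                bp=1 + i * bp_spacing,
                scaffold=f"scaffold{c}_{1 + i // 10}",
            )
            for i in range(markers_per_chromosome)
        ]
        chroms.append(ChromosomeSpec(name=f"Ca{c}", markers=markers))
    return SimConfig(
        chromosomes=chroms,
        n_lines=n_lines,
        generations=generations,
        missing_rate=missing_rate,
        error_rate=error_rate,
        distortion_loci=distortion_loci or [],
        seed=seed,
    )
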