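"""The central genotype container: lines x markers call matrix.

Calls use a four-symbol alphabet:

====== =============================================
symbol meaning
====== =============================================
A      homozygous for the parent-1 (maternal) allele
B      homozygous for the parent-2 (paternal) allele
H      heterozygous
U      missing / unknown
====== =============================================

Internally the matrix is a pandas DataFrame (index = line ids, columns =
marker ids).  Numeric routines use an int8 code view in which A = +1,
B = -1 and both H and U map to 0 — heterozygous calls are treated as
uninformative for recombination counting, the usual convention for RIL
mapping where residual heterozygosity is transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_SYMBOLS = ("A", "B", "H", "U")

_CODE = {"A": 1, "B": -1, "H": 0, "U": 0}


@dataclass
class GenotypeMatrix:
    """Rectangular call matrix with unique line and marker ids."""

    calls: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        if self.validate:
            df = self.calls
            if df.index.has_duplicates or df.columns.has_duplicates:
                raise ValueError("line and marker ids must be unique")
            bad = ~df.isin(CALL_SYMBOLS)
            if bad.to_numpy().any():
                rows, cols = np.nonzero(bad.to_numpy())
                cells = [
                    f"({df.index[r]}, {df.columns[c]}) = {df.iat[r, c]!r}"
                    for r, c in zip(rows[:10], cols[:10])
                ]
                raise ValueError(
                    "calls outside alphabet A/B/H/U: " + "; ".join(cells)
                )

    # ------------------------------------------------------------------
    @property
    def lines(self) -> list:
        return list(self.calls.index)

    @property
    def markers(self) -> list:
        return list(self.calls.columns)

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def values(self) -> np.ndarray:
        """Raw call symbols as a (lines x markers) object/str array."""
        return self.calls.to_numpy(dtype="U1")

    def codes(self) -> np.ndarray:
        """int8 view: A=+1, B=-1, H/U=0."""
        v = self.values()
        out = np.zeros(v.shape, dtype=np.int8)
        out[v == "A"] = 1
        out[v == "B"] = -1
        return out

    def missing_mask(self) -> np.ndarray:
        return self.values() == "U"

    def het_mask(self) -> np.ndarray:
        return self.values() == "H"

    # ------------------------------------------------------------------
    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy(), validate=False)

    def subset(self, lines=None, markers=None) -> "GenotypeMatrix":
        df = self.calls
        if lines is not None:
            df = df.loc[list(lines)]
        if markers is not None:
            df = df[list(markers)]
        return GenotypeMatrix(df.copy(), validate=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.calls.equals(other.calls)

    @classmethod
    def from_values(cls, values, lines, markers) -> "GenotypeMatrix":
        df = pd.DataFrame(np.asarray(values, dtype="U1"), index=list(lines),
                          columns=list(markers))
        return cls(df)
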