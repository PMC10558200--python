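"""Shared data types for attributable-fraction estimation.

The estimators in this package consume two kinds of input: a table of
literature-derived relative risks (one :class:`RiskFactorSpec` per factor,
optionally with 95% CI bounds and a population prevalence) and an
individual-level exposure table (:class:`ExposureMatrix`, one row per person,
one strictly-binary column per factor).  For the two-factor case a 2x2
contingency table of exposure counts (:class:`ContingencyTable2x2`) is an
equivalent, lossless representation.

All validation happens at construction time; estimators may assume their
inputs are well formed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RiskFactorSpec",
    "ExposureMatrix",
    "ContingencyTable2x2",
    "IndividualRisk",
    "PAFResult",
    "load_exposures",
    "load_risk_specs",
    "prevalences",
]


@dataclass(frozen=True)
class RiskFactorSpec:
    """A named binary risk factor with its relative risk.

    Parameters
    ----------
    name
        Text label; must match the exposure-matrix column it describes.
    rr
        Relative risk R > 0 of the outcome in exposed vs. unexposed
        individuals (unexposed baseline risk is 1).
    rr_low, rr_high
        Optional 95% CI bounds of ``rr``; both or neither must be given.
    prevalence
        Optional population prevalence in [0, 1], used by prevalence-only
        estimators when no exposure matrix is available.
    """

    name: str
    rr: float
    rr_low: Optional[float] = None
    rr_high: Optional[float] = None
    prevalence: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("risk factor name must be non-empty")
        if not self.rr > 0:
            raise ValueError(f"rr must be > 0, got {self.rr} for {self.name!r}")
        if (self.rr_low is None) != (self.rr_high is None):
            raise ValueError(
                f"risk factor {self.name!r}: rr_low and rr_high must be "
                "supplied together"
            )
        if self.rr_low is not None:
            if not (0 < self.rr_low <= self.rr <= self.rr_high):
                raise ValueError(
                    f"risk factor {self.name!r}: need 0 < rr_low <= rr <= "
                    f"rr_high, got ({self.rr_low}, {self.rr}, {self.rr_high})"
                )
        if self.prevalence is not None and not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(
                f"risk factor {self.name!r}: prevalence must be in [0, 1], "
                f"got {self.prevalence}"
            )

    @property
    def has_bounds(self) -> bool:
        return self.rr_low is not None


@dataclass(frozen=True)
class ExposureMatrix:
    """n individuals x k binary exposure indicators.

    ``values[i, j]`` is 1 when individual ``i`` carries risk factor ``j``.
    Entries must be exactly 0 or 1 — no truthy coercion, no missing values.
    Row order carries no meaning; every estimator is permutation-invariant
    over rows.
    """

    values: np.ndarray
    factor_names: tuple

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"exposure values must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("exposure matrix needs at least 1 row and 1 column")
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ValueError(
                f"exposure values must be 0 or 1; found {arr[tuple(bad)]!r} at "
                f"row {bad[0] + 1}, column {bad[1] + 1}"
            )
        names = tuple(str(n) for n in self.factor_names)
        if len(names) != arr.shape[1]:
            raise ValueError(
                f"{len(names)} factor names for {arr.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factor names in {names}")
        object.__setattr__(self, "values", arr.astype(np.int8))
        object.__setattr__(self, "factor_names", names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def prevalences(self) -> np.ndarray:
        """Empirical prevalence of each factor: the column means."""
        return self.values.mean(axis=0)

    def to_contingency(self) -> "ContingencyTable2x2":
        """Collapse a 2-column matrix to its 2x2 table of exposure counts."""
        if self.k != 2:
            raise ValueError(f"contingency form requires k=2, got k={self.k}")
        x = self.values[:, 0]
        y = self.values[:, 1]
        return ContingencyTable2x2(
            n1=int(np.sum((x == 1) & (y == 1))),
            n2=int(np.sum((x == 1) & (y == 0))),
            n3=int(np.sum((x == 0) & (y == 1))),
            n4=int(np.sum((x == 0) & (y == 0))),
        )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure counts for two binary factors x and y.

    ``n1`` counts individuals with both factors, ``n2`` x only, ``n3`` y only
    and ``n4`` neither; the total population is ``n = n1+n2+n3+n4``.
    """

    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self) -> None:
        for label, c in zip(("n1", "n2", "n3", "n4"), self.counts):
            if c < 0 or int(c) != c:
                raise ValueError(f"{label} must be a nonnegative integer, got {c}")
        if self.n < 1:
            raise ValueError("contingency table must count at least one individual")

    @property
    def counts(self) -> tuple:
        return (self.n1, self.n2, self.n3, self.n4)

    @property
    def n(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4

    def prevalences(self) -> tuple:
        """Marginal prevalences ((n1+n2)/n for x, (n1+n3)/n for y)."""
        return ((self.n1 + self.n2) / self.n, (self.n1 + self.n3) / self.n)

    def to_exposure_matrix(self, factor_names: Sequence[str] = ("x", "y")) -> ExposureMatrix:
        """Expand to one row per individual (lossless up to row order)."""
        rows = np.repeat(
            np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8),
            self.counts,
            axis=0,
        )
        return ExposureMatrix(rows, tuple(factor_names))


@dataclass(frozen=True)
class IndividualRisk:
    """One person's risk on the relative-risk scale (unexposed baseline 1).

    ``attributable`` is the excess over baseline, A = T - 1; it is 0 for an
    unexposed individual.
    """

    total: float
    attributable: float

    def __post_init__(self) -> None:
        if not self.total > 0:
            raise ValueError(f"total risk must be > 0, got {self.total}")
        if abs(self.attributable - (self.total - 1.0)) > 1e-12:
            raise ValueError("attributable risk must equal total - 1")


@dataclass(frozen=True)
class PAFResult:
    """A combined-PAF point estimate with audit metadata.

    ``sum_attributable`` and ``sum_total`` are the population sums ΣA and ΣT
    whose quotient is the PAF (absent for methods that never form them).
    ``contributions`` is an optional per-factor split summing to ``paf``.
    """

    paf: float
    method: str
    sum_attributable: Optional[float] = None
    sum_total: Optional[float] = None
    contributions: Optional[np.ndarray] = None
    factor_names: Optional[tuple] = None
    notes: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        out = {"method": self.method, "paf": self.paf}
        if self.sum_attributable is not None:
            out["sum_attributable"] = self.sum_attributable
            out["sum_total"] = self.sum_total
        if self.contributions is not None:
            names = self.factor_names or tuple(
                f"factor_{j + 1}" for j in range(len(self.contributions))
            )
            out["contributions"] = {
                name: float(c) for name, c in zip(names, self.contributions)
            }
        if self.notes:
            out["notes"] = list(self.notes)
        return out


# ---------------------------------------------------------------------------
# CSV input
# ---------------------------------------------------------------------------

def load_exposures(path) -> ExposureMatrix:
    """Read an exposure CSV: a mandatory header of factor names over 0/1 cells.

    Values are parsed strictly — only the literal strings ``0`` and ``1`` are
    accepted.  Missing cells, truthy spellings ("TRUE", "yes") and any other
    content are rejected with the offending row and column named.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(set(header)) != len(header):
            raise ValueError(f"{path}: duplicate factor name in header {header}")
        rows = []
        for i, row in enumerate(reader, start=1):
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: row {i} has {len(row)} cells, expected {len(header)}"
                )
            parsed = []
            for j, cell in enumerate(row):
                cell = cell.strip()
                if cell not in ("0", "1"):
                    raise ValueError(
                        f"{path}: non-binary value {cell!r} at row {i}, "
                        f"column {header[j]!r}"
                    )
                parsed.append(int(cell))
            rows.append(parsed)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return ExposureMatrix(np.array(rows, dtype=np.int8), tuple(header))


def load_risk_specs(path) -> list:
    """Read a risk-factor spec CSV with columns name,rr[,rr_low,rr_high,prevalence]."""
    df = pd.read_csv(path)
    missing = {"name", "rr"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")

    def _opt(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    specs = []
    for _, row in df.iterrows():
        specs.append(
            RiskFactorSpec(
                name=str(row["name"]),
                rr=float(row["rr"]),
                rr_low=_opt(row, "rr_low"),
                rr_high=_opt(row, "rr_high"),
                prevalence=_opt(row, "prevalence"),
            )
        )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate risk factor names")
    return specs


def prevalences(m: ExposureMatrix) -> np.ndarray:
    """Empirical prevalence vector of an exposure matrix (column means)."""
    return m.prevalences()
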