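"""Population attributable fractions from sums of individual risk.

For a single binary factor with prevalence p and relative risk R, Levin's
formula gives PAF = p(R-1) / [p(R-1) + 1].  The same quantity can be written
as a quotient of two population sums, PAF = ΣA_i / ΣT_i, where T_i is person
i's total relative risk given their full exposure pattern (baseline 1) and
A_i = T_i - 1 is their excess.  Written this way the formula extends to any
number of correlated binary factors once a rule is fixed for how co-occurring
factors combine into one total risk:

* multiplicative: T_i = Π_j (x_ij R_j - x_ij + 1), i.e. joint RRs multiply;
* additive:       T_i = Σ_j x_ij (R_j - 1) + 1, i.e. excess risks add.

The additive combined PAF depends on the data only through the marginal
prevalences, which yields a closed prevalence-only form
Σ p_j (R_j - 1) / [Σ p_j (R_j - 1) + 1]; the multiplicative combined PAF is
sensitive to the joint distribution and rises under positive clustering of
factors.  Both rules reduce exactly to Levin's formula for a single factor.

Custom combination rules may be registered; they must map the all-zero
pattern to 1 and a singleton exposure to its marginal RR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .population_model import (
    ContingencyTable2x2,
    ExposureMatrix,
    IndividualRisk,
    PAFResult,
    RiskFactorSpec,
)

__all__ = [
    "InteractionModel",
    "MULTIPLICATIVE",
    "ADDITIVE",
    "register_model",
    "get_model",
    "levin_paf",
    "individual_risk",
    "combined_paf",
    "contingency_paf",
    "prevalence_additive_paf",
    "contribution_decomposition",
]

# all algebraic identities in this module are exact; equivalence checks use
# this pure-arithmetic relative tolerance
RELATIVE_TOL = 1e-12


def _combine_multiplicative(x: np.ndarray, rr: np.ndarray) -> np.ndarray:
    return np.prod(x * (rr - 1.0) + 1.0, axis=-1)


def _combine_additive(x: np.ndarray, rr: np.ndarray) -> np.ndarray:
    return np.sum(x * (rr - 1.0), axis=-1) + 1.0


@dataclass(frozen=True)
class InteractionModel:
    """A rule mapping (exposure pattern, RR vector) to a total relative risk.

    ``combine`` must be vectorised over leading axes: given an (n, k) 0/1
    array and a length-k RR vector it returns n totals.  The contract —
    combine(all-zeros) == 1 and combine(singleton j) == R_j — is checked at
    construction and violations raise immediately.
    """

    name: str
    combine: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        rng = np.random.default_rng(17)
        for k in (1, 2, 4):
            rr = 1.0 + rng.uniform(0.1, 2.0, size=k)
            zero = np.zeros(k)
            if not np.isclose(float(self.combine(zero, rr)), 1.0, rtol=RELATIVE_TOL):
                raise ValueError(
                    f"interaction model {self.name!r} violates combine(all-zeros)=1"
                )
            for j in range(k):
                single = np.zeros(k)
                single[j] = 1.0
                if not np.isclose(
                    float(self.combine(single, rr)), float(rr[j]), rtol=1e-9
                ):
                    raise ValueError(
                        f"interaction model {self.name!r} does not reduce to the "
                        "marginal RR for a singleton exposure"
                    )

    def joint_rr(self, rr: Sequence[float]) -> float:
        """Total RR of an individual exposed to every factor in ``rr``."""
        rr = np.asarray(rr, dtype=float)
        return float(self.combine(np.ones_like(rr), rr))


MULTIPLICATIVE = InteractionModel("multiplicative", _combine_multiplicative)
ADDITIVE = InteractionModel("additive", _combine_additive)

_MODEL_REGISTRY = {"multiplicative": MULTIPLICATIVE, "additive": ADDITIVE}


def register_model(name: str, combine: Callable) -> InteractionModel:
    """Register a custom combination rule; the contract is validated here."""
    if name in _MODEL_REGISTRY:
        raise ValueError(f"interaction model {name!r} already registered")
    model = InteractionModel(name, combine)
    _MODEL_REGISTRY[name] = model
    return model


def get_model(model: Union[str, InteractionModel]) -> InteractionModel:
    if isinstance(model, InteractionModel):
        return model
    try:
        return _MODEL_REGISTRY[model]
    except KeyError:
        raise ValueError(
            f"unknown interaction model {model!r}; "
            f"known: {sorted(_MODEL_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Single factor
# ---------------------------------------------------------------------------

def levin_paf(p: float, r: float) -> float:
    """Levin's single-factor PAF, p(R-1) / [p(R-1) + 1].

    ``r < 1`` yields a negative value (a prevented fraction); this is allowed
    but flagged with a warning so protective factors are never mixed into an
    attributable sum silently.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    if not r > 0:
        raise ValueError(f"relative risk must be > 0, got {r}")
    if r < 1.0:
        warnings.warn(
            f"relative risk {r} < 1: result is a prevented fraction (negative)",
            stacklevel=2,
        )
    excess = p * (r - 1.0)
    return excess / (excess + 1.0)


def individual_risk(
    x: Sequence[int],
    rr: Sequence[float],
    model: Union[str, InteractionModel] = MULTIPLICATIVE,
) -> IndividualRisk:
    """Total and attributable relative risk for one exposure pattern."""
    model = get_model(model)
    x = np.asarray(x, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if x.shape != rr.shape:
        raise ValueError(
            f"exposure pattern length {x.size} != RR vector length {rr.size}"
        )
    if not np.all(rr > 0):
        raise ValueError("all relative risks must be > 0")
    total = float(model.combine(x, rr))
    if total <= 0:
        raise ValueError(
            f"model {model.name!r} produced non-positive total risk {total}"
        )
    return IndividualRisk(total=total, attributable=total - 1.0)


# ---------------------------------------------------------------------------
# Combined PAF over individual records
# ---------------------------------------------------------------------------

def _align_rr(m: ExposureMatrix, specs: Sequence[RiskFactorSpec]) -> np.ndarray:
    """RR vector in matrix-column order; specs are matched by name."""
    by_name = {s.name: s for s in specs}
    if len(by_name) != len(specs):
        raise ValueError("duplicate names in risk factor specs")
    if set(by_name) != set(m.factor_names):
        raise ValueError(
            f"exposure columns {m.factor_names} do not match spec names "
            f"{tuple(sorted(by_name))}"
        )
    return np.array([by_name[name].rr for name in m.factor_names])


def _check_protective(rr: np.ndarray, allow_protective: bool) -> tuple:
    notes = ()
    if np.any(rr < 1.0):
        if not allow_protective:
            raise ValueError(
                "relative risks < 1 (protective factors) are rejected by "
                "default; pass allow_protective=True to accept them"
            )
        notes = ("protective RRs (< 1) present",)
    return notes


def combined_paf(
    m: ExposureMatrix,
    specs: Sequence[RiskFactorSpec],
    model: Union[str, InteractionModel] = MULTIPLICATIVE,
    allow_protective: bool = False,
) -> PAFResult:
    """Combined PAF as the quotient of individual-risk sums, ΣA_i / ΣT_i.

    The exposure matrix supplies the joint distribution of factors; ``specs``
    supply the marginal RRs (matched to columns by name); ``model`` fixes how
    co-occurring factors combine into each person's total risk.
    """
    model = get_model(model)
    rr = _align_rr(m, specs)
    notes = _check_protective(rr, allow_protective)
    totals = model.combine(m.values.astype(float), rr)
    if np.any(totals <= 0):
        i = int(np.argmax(totals <= 0))
        raise ValueError(
            f"model {model.name!r} produced non-positive total risk for row {i + 1}"
        )
    sum_total = float(totals.sum())
    sum_attr = float(sum_total - m.n)
    paf = sum_attr / sum_total
    method = f"individual_{model.name}"
    contributions = contribution_decomposition(
        specs, method, exposures=m, combined=paf
    )
    return PAFResult(
        paf=paf,
        method=method,
        sum_attributable=sum_attr,
        sum_total=sum_total,
        contributions=contributions,
        factor_names=m.factor_names,
        notes=notes,
    )


def _contingency_value(
    n1, n2, n3, n4, rx: float, ry: float, rxy: float
) -> np.ndarray:
    """Closed-form combined PAF from 2x2 cell counts and a free joint RR.

    Broadcasts over array-valued counts.  Numerator is the population excess
    n1(Rxy - Rx - Ry + 1) + (n1+n2)(Rx-1) + (n1+n3)(Ry-1); denominator adds n.
    """
    n1 = np.asarray(n1, dtype=float)
    num = (
        n1 * (rxy - rx - ry + 1.0)
        + (n1 + n2) * (rx - 1.0)
        + (n1 + n3) * (ry - 1.0)
    )
    n = n1 + n2 + n3 + n4
    return num / (num + n)


def contingency_paf(
    t: ContingencyTable2x2,
    rx: float,
    ry: float,
    model: Union[str, InteractionModel] = MULTIPLICATIVE,
    rxy: Optional[float] = None,
    allow_protective: bool = False,
) -> PAFResult:
    """Two-factor combined PAF straight from a 2x2 table of exposure counts.

    When ``rxy`` is omitted the joint RR of the doubly-exposed cell comes
    from the interaction model (rx*ry or rx+ry-1); when supplied it is used
    directly and the method label becomes ``custom``, computing the general
    four-cell sum.  Identical (to floating tolerance) to :func:`combined_paf`
    on the row-expanded matrix.
    """
    if not (rx > 0 and ry > 0):
        raise ValueError("rx and ry must be > 0")
    notes = _check_protective(np.array([rx, ry]), allow_protective)
    if rxy is not None:
        if not rxy > 0:
            raise ValueError(f"rxy must be > 0, got {rxy}")
        method = "custom"
    else:
        model = get_model(model)
        rxy = model.joint_rr((rx, ry))
        method = f"individual_{model.name}"
    paf = float(_contingency_value(t.n1, t.n2, t.n3, t.n4, rx, ry, rxy))
    sum_total = t.n / (1.0 - paf)
    return PAFResult(
        paf=paf,
        method=method,
        sum_attributable=sum_total - t.n,
        sum_total=sum_total,
        notes=notes,
    )


def prevalence_additive_paf(
    specs: Sequence[RiskFactorSpec], allow_protective: bool = False
) -> PAFResult:
    """Additive combined PAF from prevalences and RRs alone.

    Because additive excess risks simply sum, the combined PAF collapses to
    Σ p_j (R_j - 1) / [Σ p_j (R_j - 1) + 1] — no individual-level data needed,
    and the result is independent of how the factors co-occur.
    """
    if any(s.prevalence is None for s in specs):
        missing = [s.name for s in specs if s.prevalence is None]
        raise ValueError(f"prevalence missing for risk factor(s) {missing}")
    rr = np.array([s.rr for s in specs])
    notes = _check_protective(rr, allow_protective)
    p = np.array([s.prevalence for s in specs])
    excess = p * (rr - 1.0)
    total = excess.sum() + 1.0
    return PAFResult(
        paf=float(excess.sum() / total),
        method="prevalence_additive",
        contributions=excess / total,
        factor_names=tuple(s.name for s in specs),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Per-factor contribution split
# ---------------------------------------------------------------------------

_ADDITIVE_METHODS = {"additive", "individual_additive", "prevalence_additive"}
_PROPORTIONAL_METHODS = {
    "multiplicative",
    "individual_multiplicative",
    "barnes_yaffe",
    "norton_weighted",
    "levin",
}


def contribution_decomposition(
    specs: Sequence[RiskFactorSpec],
    method: str,
    exposures: Optional[ExposureMatrix] = None,
    combined: Optional[float] = None,
) -> np.ndarray:
    """Split a combined PAF into per-factor shares summing to the total.

    Additive methods admit a direct split, p_j(R_j-1) / [Σ p_j(R_j-1) + 1].
    Multiplicative and weighted methods have no exact per-factor attribution,
    so the combined total is partitioned proportionally to the single-factor
    Levin PAFs (share_j = combined * PAF_j / Σ PAF_j).
    """
    if exposures is not None:
        order = {s.name: s for s in specs}
        if set(order) != set(exposures.factor_names):
            raise ValueError("spec names do not match exposure columns")
        specs = [order[name] for name in exposures.factor_names]
        p = exposures.prevalences()
    else:
        if any(s.prevalence is None for s in specs):
            raise ValueError("prevalences required when no exposure matrix given")
        p = np.array([s.prevalence for s in specs])
    rr = np.array([s.rr for s in specs])

    if method in _ADDITIVE_METHODS:
        excess = p * (rr - 1.0)
        return excess / (excess.sum() + 1.0)

    if method in _PROPORTIONAL_METHODS or method in _MODEL_REGISTRY or method.startswith(
        "individual_"
    ):
        singles = p * (rr - 1.0) / (p * (rr - 1.0) + 1.0)
        if combined is None:
            if exposures is not None and (
                method.startswith("individual_") or method in _MODEL_REGISTRY
            ):
                name = method.removeprefix("individual_")
                combined = combined_paf(
                    exposures, specs, get_model(name), allow_protective=True
                ).paf
            elif method in ("levin", "barnes_yaffe"):
                combined = 1.0 - np.prod(1.0 - singles)
            else:
                raise ValueError(
                    "an exposure matrix (or an explicit combined value) is "
                    f"needed to decompose method {method!r}"
                )
        denom = singles.sum()
        if denom == 0.0:
            return np.zeros_like(singles)
        return combined * singles / denom

    raise ValueError(f"unknown method label {method!r}")
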