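"""Legacy population-level methods for combining single-factor PAFs.

Two approaches predate the individual-sum formulation and are kept as
comparators.  The unweighted multiplicative combination (Barnes & Yaffe)
assumes the factors occur independently and multiply:

    PAF_combined = 1 - Π_j (1 - PAF_j).

The weighted variant (Norton et al.) first shrinks each single-factor PAF by
w_j = 1 - communality_j, where the communality is the share of factor j's
variance explained by the principal components retained (Kaiser criterion,
eigenvalue > 1) from a PCA of the inter-factor tetrachoric correlation
matrix:

    PAF_combined = 1 - Π_j (1 - w_j * PAF_j).

Retaining more components can only grow the communalities, shrink the
weights, and shrink the combined estimate — the sensitivity to an arbitrary
retention rule is precisely why this method is reported alongside, not
instead of, the individual-sum estimators.

The tetrachoric correlation of a 2x2 table is estimated the standard way:
thresholds fixed at the inverse-normal of the margins, then a 1-D maximum
likelihood search over the latent correlation ρ; tables with a zero cell get
a +0.5 continuity correction first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

from .population_model import ContingencyTable2x2, ExposureMatrix

__all__ = [
    "CommunalityWeights",
    "barnes_yaffe_paf",
    "norton_weighted_paf",
    "tetrachoric_correlation",
    "tetrachoric_matrix",
    "communality_weights",
    "communality_weights_from_corr",
]


def barnes_yaffe_paf(pafs: Sequence[float]) -> float:
    """Unweighted multiplicative combination, 1 - Π(1 - PAF_j)."""
    pafs = np.asarray(pafs, dtype=float)
    if pafs.size == 0:
        raise ValueError("need at least one single-factor PAF")
    if np.any(pafs >= 1.0):
        raise ValueError("single-factor PAFs must be < 1")
    return float(1.0 - np.prod(1.0 - pafs))


def norton_weighted_paf(pafs: Sequence[float], weights: Sequence[float]) -> float:
    """Communality-weighted combination, 1 - Π(1 - w_j PAF_j)."""
    pafs = np.asarray(pafs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if pafs.shape != weights.shape:
        raise ValueError(
            f"{pafs.size} PAFs but {weights.size} weights"
        )
    if np.any(pafs >= 1.0):
        raise ValueError("single-factor PAFs must be < 1")
    if np.any((weights < 0.0) | (weights > 1.0)):
        raise ValueError("weights must be in [0, 1]")
    return float(1.0 - np.prod(1.0 - weights * pafs))


# ---------------------------------------------------------------------------
# Tetrachoric correlation
# ---------------------------------------------------------------------------

def _quadrant_probs(tx: float, ty: float, rho: float) -> np.ndarray:
    """Probabilities of the four exposure cells (11, 10, 01, 00).

    Exposure corresponds to the latent normal exceeding its threshold, so
    cell (0,0) is the lower-orthant probability L(tx, ty; ρ).
    """
    low = multivariate_normal.cdf(
        np.array([tx, ty]), mean=np.zeros(2), cov=np.array([[1.0, rho], [rho, 1.0]])
    )
    px0 = norm.cdf(tx)  # P(x = 0)
    py0 = norm.cdf(ty)
    p11 = 1.0 - px0 - py0 + low
    p10 = py0 - low
    p01 = px0 - low
    return np.clip(np.array([p11, p10, p01, low]), 1e-300, 1.0)


def tetrachoric_correlation(t: ContingencyTable2x2) -> float:
    """ML tetrachoric correlation of a 2x2 table with margin-fixed thresholds.

    Models the two binary indicators as dichotomised coordinates of a latent
    bivariate standard normal; the thresholds are set so the latent margins
    reproduce the observed margins exactly, leaving only ρ to maximise the
    multinomial likelihood of the four cells.
    """
    counts = np.array(t.counts, dtype=float)
    if (t.n1 + t.n2 == 0) or (t.n3 + t.n4 == 0) or (t.n1 + t.n3 == 0) or (
        t.n2 + t.n4 == 0
    ):
        raise ValueError(
            "tetrachoric correlation undefined when a factor is absent from "
            "or universal in the population (zero margin)"
        )
    if np.any(counts == 0):
        counts = counts + 0.5  # continuity correction
    n = counts.sum()
    px = (counts[0] + counts[1]) / n
    py = (counts[0] + counts[2]) / n
    tx = norm.ppf(1.0 - px)
    ty = norm.ppf(1.0 - py)

    def negloglik(rho: float) -> float:
        return -float(counts @ np.log(_quadrant_probs(tx, ty, rho)))

    res = minimize_scalar(
        negloglik, bounds=(-0.9999, 0.9999), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def tetrachoric_matrix(m: ExposureMatrix) -> np.ndarray:
    """Pairwise tetrachoric correlation matrix of the exposure columns."""
    k = m.k
    corr = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            pair = ExposureMatrix(
                m.values[:, [a, b]], (m.factor_names[a], m.factor_names[b])
            )
            rho = tetrachoric_correlation(pair.to_contingency())
            corr[a, b] = corr[b, a] = rho
    return corr


# ---------------------------------------------------------------------------
# PCA communality weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunalityWeights:
    """Full audit trail of the PCA weighting step.

    ``weights[j] = 1 - communalities[j]`` where the communality is the sum of
    squared loadings of factor j on the retained components; the report keeps
    the tetrachoric matrix, its eigenvalues and the retained count so a user
    can see exactly why the weighted estimate shrank.
    """

    tetrachoric: np.ndarray
    eigenvalues: np.ndarray
    n_components: int
    communalities: np.ndarray
    weights: np.ndarray


def _repair_psd(corr: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to 0 and rescale back to unit diagonal."""
    lam, vec = np.linalg.eigh(corr)
    fixed = (vec * np.clip(lam, 0.0, None)) @ vec.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def communality_weights_from_corr(
    corr: np.ndarray,
    selection: Union[str, int] = "kaiser",
    repair: bool = True,
) -> CommunalityWeights:
    """PCA communality weights from a (tetrachoric) correlation matrix.

    ``selection`` picks the retained components: ``"kaiser"`` keeps those
    with eigenvalue strictly greater than 1 (so an identity matrix retains
    nothing and the weighted method collapses to the unweighted one),
    ``"kaiser_inclusive"`` uses >= 1, and an integer keeps a fixed count.
    Pairwise-estimated matrices need not be positive semidefinite; with
    ``repair`` they are fixed by eigenvalue clipping and rescaling to unit
    diagonal, otherwise an indefinite matrix raises.
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    if corr.shape != (k, k) or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-10:
        if not repair:
            raise ValueError(
                "estimated tetrachoric matrix is not positive semidefinite "
                "(pass repair=True to clip negative eigenvalues)"
            )
        corr = _repair_psd(corr)

    lam, vec = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]

    if selection == "kaiser":
        n_comp = int(np.sum(lam > 1.0))
    elif selection == "kaiser_inclusive":
        n_comp = int(np.sum(lam >= 1.0))
    elif isinstance(selection, int):
        if not 0 <= selection <= k:
            raise ValueError(f"component count must be in [0, {k}]")
        n_comp = selection
    else:
        raise ValueError(f"unknown component selection rule {selection!r}")

    loadings = vec[:, :n_comp] * np.sqrt(np.clip(lam[:n_comp], 0.0, None))
    communalities = np.clip((loadings**2).sum(axis=1), 0.0, 1.0)
    return CommunalityWeights(
        tetrachoric=corr,
        eigenvalues=lam,
        n_components=n_comp,
        communalities=communalities,
        weights=1.0 - communalities,
    )


def communality_weights(
    m: ExposureMatrix,
    selection: Union[str, int] = "kaiser",
    repair: bool = True,
) -> CommunalityWeights:
    """Estimate the tetrachoric matrix of ``m`` and derive PCA weights."""
    if m.k < 2:
        raise ValueError("communality weights need at least 2 risk factors")
    return communality_weights_from_corr(
        tetrachoric_matrix(m), selection=selection, repair=repair
    )
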