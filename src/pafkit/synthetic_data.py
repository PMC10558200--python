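"""Synthetic exposure data with controlled prevalences and correlation.

Correlated binary exposures are generated by Gaussian-copula thresholding:
draw latent vectors from a multivariate standard normal with the requested
correlation matrix, then mark factor j present when its latent coordinate
exceeds the (1 - p_j) quantile.  The latent correlation is exactly the
tetrachoric correlation of the resulting binary pair, so the generator
round-trips cleanly with the tetrachoric estimator in
:mod:`pafkit.legacy_methods`.

Also provides the exact 10-person, two-factor worked-example population
(one smoker with hearing loss, one smoker without, four with hearing loss
only, four with neither) and margin-preserving independent/maximal-overlap
scenario pairs for studying how positive clustering moves the multiplicative
PAF while leaving the additive PAF untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.stats import norm

from .population_model import ContingencyTable2x2, ExposureMatrix, RiskFactorSpec

__all__ = [
    "GeneratorConfig",
    "table2_fixture",
    "worked_example_specs",
    "generate_correlated_binary",
    "correlated_scenario_pair",
    "load_generator_config",
    "application_standin",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the copula generator.

    ``latent_correlation`` is on the tetrachoric scale: it is the correlation
    of the latent normals, not of the thresholded 0/1 indicators.
    """

    n: int
    prevalences: tuple
    latent_correlation: np.ndarray
    seed: int
    factor_names: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        p = tuple(float(v) for v in self.prevalences)
        if not all(0.0 < v < 1.0 for v in p):
            raise ValueError(f"prevalences must be in (0, 1), got {p}")
        corr = np.asarray(self.latent_correlation, dtype=float)
        k = len(p)
        if corr.shape != (k, k):
            raise ValueError(
                f"correlation shape {corr.shape} does not match {k} prevalences"
            )
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("latent correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("latent correlation must have a unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError("latent correlation must be positive semidefinite")
        names = self.factor_names
        if names is None:
            names = tuple(f"factor_{j + 1}" for j in range(k))
        elif len(names) != k:
            raise ValueError("factor_names length mismatch")
        object.__setattr__(self, "prevalences", p)
        object.__setattr__(self, "latent_correlation", corr)
        object.__setattr__(self, "factor_names", tuple(names))


def table2_fixture() -> ExposureMatrix:
    """The exact 10-person smoking / hearing-loss demonstration population.

    Prevalences are (0.2, 0.5) and the single doubly-exposed person makes the
    two factors exactly independent in counts (n1/n = 0.1 = 0.2 x 0.5).
    """
    rows = np.array(
        [
            [1, 1],
            [1, 0],
            [0, 1],
            [0, 0],
            [0, 1],
            [0, 0],
            [0, 1],
            [0, 0],
            [0, 1],
            [0, 0],
        ],
        dtype=np.int8,
    )
    return ExposureMatrix(rows, ("smoking", "hearing_loss"))


def worked_example_specs() -> list:
    """RR specs matching the demonstration population (smoking 1.6, hearing 1.9)."""
    return [
        RiskFactorSpec("smoking", rr=1.6, prevalence=0.2),
        RiskFactorSpec("hearing_loss", rr=1.9, prevalence=0.5),
    ]


def generate_correlated_binary(cfg: GeneratorConfig) -> ExposureMatrix:
    """Draw an exposure matrix by thresholding a latent Gaussian copula.

    Column j is 1 when the latent normal exceeds its (1 - p_j) quantile, so
    larger target prevalences lower the threshold.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.prevalences)
    # eigendecomposition square root: tolerates semidefinite correlations
    lam, vec = np.linalg.eigh(cfg.latent_correlation)
    root = vec * np.sqrt(np.clip(lam, 0.0, None))
    z = rng.standard_normal((cfg.n, k)) @ root.T
    thresholds = norm.ppf(1.0 - np.asarray(cfg.prevalences))
    return ExposureMatrix((z > thresholds).astype(np.int8), cfg.factor_names)


def correlated_scenario_pair(
    p: Sequence[float], n: int = 10, factor_names: Sequence[str] = ("x", "y")
) -> Tuple[ExposureMatrix, ExposureMatrix]:
    """Two populations with identical margins but different overlap.

    Returns (independent, maximal_overlap): the first has exactly independent
    counts (n1 = n p_x p_y), the second packs as many doubly-exposed
    individuals as the margins allow.  Requires n*p_x, n*p_y and n*p_x*p_y to
    be whole numbers, else the margins are infeasible at this n.
    """
    px, py = p
    nx, ny, n11 = n * px, n * py, n * px * py
    for label, v in (("n*p_x", nx), ("n*p_y", ny), ("n*p_x*p_y", n11)):
        if abs(v - round(v)) > 1e-9:
            raise ValueError(
                f"infeasible margins: {label} = {v} is not a whole count"
            )
    nx, ny, n11 = int(round(nx)), int(round(ny)), int(round(n11))

    def table(n1: int) -> ContingencyTable2x2:
        return ContingencyTable2x2(
            n1=n1, n2=nx - n1, n3=ny - n1, n4=n - nx - ny + n1
        )

    independent = table(n11).to_exposure_matrix(factor_names)
    overlap = table(min(nx, ny)).to_exposure_matrix(factor_names)
    return independent, overlap


def load_generator_config(path) -> GeneratorConfig:
    """Read a generator config from YAML.

    Keys: ``n``, ``seed``, ``prevalences`` and ``correlation`` — the latter a
    full matrix (nested lists), the string ``identity``, or
    ``exchangeable:RHO`` for a constant off-diagonal correlation.  Optional
    ``factor_names``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        n = int(raw["n"])
        seed = int(raw["seed"])
        prev = tuple(float(v) for v in raw["prevalences"])
        corr_spec = raw["correlation"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: missing or malformed generator key: {exc}")
    k = len(prev)
    if corr_spec == "identity":
        corr = np.eye(k)
    elif isinstance(corr_spec, str) and corr_spec.startswith("exchangeable:"):
        rho = float(corr_spec.split(":", 1)[1])
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
    else:
        corr = np.asarray(corr_spec, dtype=float)
    names = raw.get("factor_names")
    return GeneratorConfig(
        n=n,
        prevalences=prev,
        latent_correlation=corr,
        seed=seed,
        factor_names=tuple(names) if names else None,
    )


def application_standin(
    n: int = 5000, seed: int = 0, latent_rho: float = 0.45
) -> Tuple[list, ExposureMatrix]:
    """Synthetic 12-factor risk profile for method-comparison experiments.

    A fully synthetic stand-in: twelve binary risk factors with prevalence
    and RR magnitudes typical of published modifiable dementia risk profiles
    (education, hearing, vascular, lifestyle and environmental exposures),
    and an exchangeable positive latent correlation reflecting the known
    clustering of such factors.  The values are chosen to be field-realistic,
    not to reproduce any published input set.  Returns (specs, exposures).
    """
    profile = [
        # name, prevalence, rr, rr_low, rr_high
        ("low_education", 0.40, 1.6, 1.3, 2.0),
        ("hearing_loss", 0.32, 1.9, 1.4, 2.7),
        ("head_injury", 0.12, 1.8, 1.5, 2.2),
        ("hypertension", 0.09, 1.6, 1.2, 2.2),
        ("high_alcohol", 0.12, 1.2, 1.1, 1.3),
        ("obesity", 0.07, 1.6, 1.3, 1.9),
        ("smoking", 0.27, 1.6, 1.2, 2.2),
        ("depression", 0.13, 1.9, 1.6, 2.3),
        ("social_isolation", 0.11, 1.6, 1.3, 1.9),
        ("physical_inactivity", 0.17, 1.4, 1.2, 1.7),
        ("diabetes", 0.06, 1.5, 1.3, 1.8),
        ("air_pollution", 0.75, 1.1, 1.0, 1.2),
    ]
    specs = [
        RiskFactorSpec(name, rr=rr, rr_low=lo, rr_high=hi, prevalence=p)
        for name, p, rr, lo, hi in profile
    ]
    k = len(specs)
    corr = np.full((k, k), latent_rho)
    np.fill_diagonal(corr, 1.0)
    cfg = GeneratorConfig(
        n=n,
        prevalences=tuple(s.prevalence for s in specs),
        latent_correlation=corr,
        seed=seed,
        factor_names=tuple(s.name for s in specs),
    )
    return specs, generate_correlated_binary(cfg)
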