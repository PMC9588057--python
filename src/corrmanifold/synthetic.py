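"""Seeded generators of synthetic correlation-matrix data.

Two generating processes are emulated:

* sample Pearson correlation matrices of m i.i.d. draws from a standard
  multivariate Gaussian (so the population correlation is the identity and
  sampling noise is the only source of spread), and
* perturbations of a model correlation matrix by Gaussian noise of a given
  standard deviation applied in the tangent space at the model, expressed
  in coordinates orthonormal under the affine-invariant metric and mapped
  back through the manifold exponential.

Both are pure functions of their configuration (seed included), so every
downstream analysis is reproducible without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry

__all__ = [
    "GaussianCorrConfig",
    "PerturbationConfig",
    "gaussian_sample_corr",
    "perturb_tangent",
    "make_three_class",
    "random_model_corr",
    "make_separated_models",
]


@dataclass(frozen=True)
class GaussianCorrConfig:
    """Sample-correlation generator settings.

    ``n_draws`` observations per matrix must exceed ``dim`` so the sample
    correlation is full rank almost surely.
    """

    dim: int = 5
    n_draws: int = 50
    n_matrices: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws <= self.dim:
            raise ValueError(
                f"n_draws ({self.n_draws}) must exceed dim ({self.dim}) "
                "for an almost-surely full-rank sample correlation"
            )


@dataclass(frozen=True)
class PerturbationConfig:
    """Tangent-noise generator settings (noise sd in metric-orthonormal
    tangent coordinates at the model matrix)."""

    model: np.ndarray = None
    sd: float = 1.0
    n_samples: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def gaussian_sample_corr(cfg: GaussianCorrConfig) -> np.ndarray:
    """Pearson sample correlations of standard multivariate Gaussian draws."""
    rng = np.random.default_rng(cfg.seed)
    out = np.empty((cfg.n_matrices, cfg.dim, cfg.dim))
    for i in range(cfg.n_matrices):
        Z = rng.standard_normal((cfg.n_draws, cfg.dim))
        if cfg.dim == 1:
            out[i] = np.ones((1, 1))
            continue
        C = np.corrcoef(Z, rowvar=False)
        C = 0.5 * (C + C.T)
        np.fill_diagonal(C, 1.0)
        out[i] = C
    return out


def perturb_tangent(cfg: PerturbationConfig) -> np.ndarray:
    """Noisy samples around a model correlation matrix.

    Each sample is ``exp_model(E)`` on the correlation manifold, where E has
    i.i.d. N(0, sd^2) coordinates in an orthonormal (affine-invariant)
    tangent basis at the model.
    """
    model = geometry.validate_correlation(np.asarray(cfg.model, float), "model")
    rng = np.random.default_rng(cfg.seed)
    n = model.shape[0]
    dim = geometry.tangent_dim(n)
    out = np.empty((cfg.n_samples, n, n))
    for i in range(cfg.n_samples):
        z = rng.standard_normal(dim) * cfg.sd
        E = geometry.coords_to_tangent(model, z)
        out[i] = geometry.corr_exp(model, E)
    return out


def make_three_class(
    models, per_class: int, sd: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled dataset of tangent-noise samples around several models.

    Returns ``(matrices, labels)`` with labels in 1..len(models); class j
    uses a seed offset so classes are independent but jointly reproducible.
    """
    models = [np.asarray(m, float) for m in models]
    mats, labels = [], []
    for j, model in enumerate(models):
        cfg = PerturbationConfig(
            model=model, sd=sd, n_samples=per_class, seed=seed + j
        )
        mats.append(perturb_tangent(cfg))
        labels.append(np.full(per_class, j + 1, dtype=int))
    return np.concatenate(mats, axis=0), np.concatenate(labels)


def random_model_corr(
    n: int, seed: int = 0, min_eig: float = 1e-3, max_tries: int = 200
) -> np.ndarray:
    """Random full-rank correlation matrix (submersed Wishart draw).

    Retries until the smallest eigenvalue is at least ``min_eig``; serves as
    a stand-in for empirically derived connectivity model matrices.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    df = n + 2
    for _ in range(max_tries):
        G = rng.standard_normal((n, df))
        C = geometry.submersion(G @ G.T / df)
        if np.linalg.eigvalsh(C)[0] >= min_eig:
            return C
    raise RuntimeError(
        f"could not draw a correlation matrix with smallest eigenvalue >= "
        f"{min_eig} in {max_tries} tries"
    )


def make_separated_models(
    n: int,
    k: int = 3,
    min_dist: float = 3.0,
    seed: int = 0,
    spec: geometry.GeometrySpec | None = None,
    max_tries: int = 60,
) -> list[np.ndarray]:
    """k model correlation matrices with pairwise geodesic distance >= min_dist.

    Random tangent directions at the identity are scaled up until every
    pairwise quotient distance clears the threshold; the exponential map
    keeps every candidate a valid full-rank correlation matrix.  Stand-in
    for mutually distant connectivity-derived model matrices.
    """
    spec = spec or geometry.GeometrySpec()
    rng = np.random.default_rng(seed)
    eye = np.eye(n)
    dim = geometry.tangent_dim(n)
    dirs = rng.standard_normal((k, dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    scale = max(min_dist, 1.0)
    for _ in range(max_tries):
        models = [
            geometry.corr_exp(eye, geometry.coords_to_tangent(eye, scale * d))
            for d in dirs
        ]
        D = geometry.pairwise_distances(np.array(models), spec)
        off = D[np.triu_indices(k, 1)]
        if off.min() >= min_dist:
            return models
        scale *= 1.3
    raise RuntimeError(
        f"could not reach pairwise distance {min_dist} in {max_tries} scalings"
    )
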