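"""Synthetic data with known ground truth.

Three generators cover the workflow end to end:

* :func:`simulate_expression` — an expression matrix in which the signature
  genes respond linearly to a latent per-sample activity, on top of
  Gaussian background noise.  The latent activity is the ground truth the
  T-score is supposed to recover.
* :func:`simulate_sem_dataset` — a three-variable dataset drawn from the
  3-node path model with chosen coefficients, exogenous correlation and
  residual variance.
* :func:`make_chained_truth` — the full chain: two signatures embedded in
  one matrix whose latent activities are the path model's regressors, plus
  a reporter gene row equal to the model's endpoint, written to disk in the
  formats the readers accept.

All generators are deterministic given (parameters, seed).  Noise is
Gaussian throughout, matching the normality assumptions of both the t-test
and ML covariance-structure fitting; activities are standard normal so the
effect size is the sole signal-to-noise knob.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSignature,
    GeneSet,
    OrthologMap,
    write_expression_matrix,
    write_gene_set,
    write_ortholog_map,
    write_signature,
)
from .sem import SEMData, implied_covariance

__all__ = [
    "ActivityTruth",
    "SEMTruth",
    "simulate_expression",
    "simulate_sem_dataset",
    "make_chained_truth",
]


@dataclass(frozen=True)
class ActivityTruth:
    """How strongly signature genes track the latent activity.

    ``effect_size`` is the mean expression shift of an up gene per unit of
    activity (down genes shift by the negative); ``noise_sd`` is the SD of
    the residual expression noise on every gene.
    """

    effect_size: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class SEMTruth:
    """Generating parameters of the 3-node path model."""

    gamma11: float = 0.5
    gamma21: float = 0.3
    exo_corr: float = 0.4
    resid_var: float = 0.5
    n: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.exo_corr < 1.0:
            raise ValueError("exo_corr must be in (-1, 1)")
        if self.resid_var <= 0:
            raise ValueError("resid_var must be > 0")
        if self.n < 4:
            raise ValueError("n must be >= 4")

    def population_covariance(self) -> np.ndarray:
        """Exact covariance of (fac1, fac2, endpoint) under the generator."""
        return implied_covariance(
            1.0, 1.0, self.exo_corr, self.gamma11, self.gamma21, self.resid_var
        )


def _gene_names(prefix: str, count: int) -> list[str]:
    width = len(str(max(count - 1, 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(count)]


def simulate_expression(
    n_samples: int,
    n_background_genes: int,
    sig_sizes: tuple[int, int],
    truth: ActivityTruth,
    seed: int,
    activities: np.ndarray | None = None,
    gene_prefix: str = "G",
    sample_prefix: str = "S",
) -> tuple[ExpressionMatrix, GeneSignature, np.ndarray]:
    """Expression matrix with an embedded directional signature.

    Up-signature genes are shifted by ``+effect_size * activity_s`` in
    sample s and down genes by the negative; background genes are pure
    noise.  Activities default to standard-normal draws but can be supplied
    (that is how :func:`make_chained_truth` wires in path-model regressors).

    Returns the matrix (gene level, not yet median-centered), the
    signature, and the per-sample activities.
    """
    n_up, n_down = sig_sizes
    if n_up < 2 or n_down < 2:
        raise ValueError("signature needs at least 2 genes per direction")
    rng = np.random.default_rng(seed)
    if activities is None:
        activities = rng.standard_normal(n_samples)
    activities = np.asarray(activities, dtype=float)
    if activities.shape != (n_samples,):
        raise ValueError("activities must have one value per sample")

    n_genes = n_background_genes + n_up + n_down
    up_names = _gene_names(f"{gene_prefix}UP", n_up)
    down_names = _gene_names(f"{gene_prefix}DN", n_down)
    bg_names = _gene_names(f"{gene_prefix}BG", n_background_genes)
    names = up_names + down_names + bg_names

    values = rng.normal(0.0, truth.noise_sd, size=(n_genes, n_samples))
    values[:n_up] += truth.effect_size * activities
    values[n_up : n_up + n_down] -= truth.effect_size * activities

    samples = _gene_names(sample_prefix, n_samples)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=names, columns=samples), level="gene"
    )
    sig = GeneSignature(frozenset(up_names), frozenset(down_names), species="synthetic")
    return matrix, sig, activities


def simulate_sem_dataset(truth: SEMTruth) -> SEMData:
    """Draw a three-variable dataset from the 3-node path model.

    (fac1, fac2) are bivariate normal with unit variances and correlation
    ``exo_corr``; endpoint = gamma11*fac1 + gamma21*fac2 + N(0, resid_var).
    """
    rng = np.random.default_rng(truth.seed)
    cov = np.array([[1.0, truth.exo_corr], [truth.exo_corr, 1.0]])
    chol = np.linalg.cholesky(cov)
    fac = rng.standard_normal((truth.n, 2)) @ chol.T
    endpoint = (
        truth.gamma11 * fac[:, 0]
        + truth.gamma21 * fac[:, 1]
        + rng.normal(0.0, np.sqrt(truth.resid_var), truth.n)
    )
    return SEMData(fac[:, 0], fac[:, 1], endpoint)


def make_chained_truth(
    truth: SEMTruth,
    out_dir: str | Path,
    sig_sizes: tuple[int, int] = (15, 15),
    n_background_genes: int = 100,
    activity: ActivityTruth = ActivityTruth(effect_size=2.0, noise_sd=1.0),
    n_direct_targets: int = 6,
) -> dict[str, object]:
    """End-to-end fixture: signature -> T-score -> path model, on disk.

    The two regressors of a :func:`simulate_sem_dataset` draw become the
    latent activities of two signatures embedded in a single expression
    matrix; a reporter gene row carries the endpoint values.  A "direct
    target" subset of signature 1 and a background gene pool are written as
    gene sets for elimination-bootstrap runs.

    Returns the in-memory objects plus the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sem_data = simulate_sem_dataset(truth)

    mat1, sig1, act1 = simulate_expression(
        truth.n, n_background_genes, sig_sizes, activity,
        seed=truth.seed + 1, activities=sem_data.fac1, gene_prefix="A",
    )
    mat2, sig2, act2 = simulate_expression(
        truth.n, 0, sig_sizes, activity,
        seed=truth.seed + 2, activities=sem_data.fac2, gene_prefix="B",
        sample_prefix="S",
    )
    reporter = pd.DataFrame(
        sem_data.endpoint[None, :], index=["REPORTER"], columns=mat1.sample_ids
    )
    combined = ExpressionMatrix(
        pd.concat([mat1.data, mat2.data, reporter]), level="gene"
    )

    direct = sorted(sig1.up_genes)[: n_direct_targets // 2] + sorted(sig1.down_genes)[
        : n_direct_targets - n_direct_targets // 2
    ]
    pool_genes = frozenset(g for g in combined.row_ids if g.startswith("ABG"))
    target = GeneSet("direct_targets", frozenset(direct))
    pool = GeneSet("background_pool", pool_genes)
    omap = OrthologMap.identity(combined.row_ids)

    paths = {
        "matrix": out_dir / "matrix.tsv",
        "signature1": out_dir / "signature1.tsv",
        "signature2": out_dir / "signature2.tsv",
        "ortholog_map": out_dir / "ortholog_map.tsv",
        "target": out_dir / "direct_targets.txt",
        "pool": out_dir / "pool.txt",
    }
    write_expression_matrix(combined, paths["matrix"])
    write_signature(sig1, paths["signature1"])
    write_signature(sig2, paths["signature2"])
    write_ortholog_map(omap, paths["ortholog_map"])
    write_gene_set(target, paths["target"])
    write_gene_set(pool, paths["pool"])

    return {
        "matrix": combined,
        "signature1": sig1,
        "signature2": sig2,
        "sem_data": sem_data,
        "target": target,
        "pool": pool,
        "reporter_gene": "REPORTER",
        "truth": truth,
        "paths": paths,
    }
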