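"""Two-class elimination bootstrap over the signature -> T-score -> SEM chain.

The question asked: does removing a designated subset of a regulator's
signature (for instance the direct targets of a downstream effector) change
the fitted path model more than removing an arbitrary subset of the same
size?  The observed statistic is the chosen path-model summary after
deterministically removing the target subset.  The null replicates come in
two modes:

* ``without_replacement`` — remove an equally sized subset drawn uniformly
  from the non-target signature genes, so the signature shrinks by N.
* ``with_replacement`` — remove the target subset and refill with N genes
  drawn uniformly (no repetition) from a background pool, restoring the
  original signature size; each refill gene inherits the direction of the
  removed gene it replaces, matched by removal order.

Each replicate recomputes T-scores from the perturbed signature and refits
the path model with the other regulator and the endpoint unchanged.  The
empirical p-value is floored at 1/B, so B = 1000 iterations can resolve
p = 0.001 at best.  Replicates use independent seed substreams spawned from
the master seed, so results are identical no matter the execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, GeneSet
from .preprocess import ProjectedSignature
from .sem import SEMData, PathModelSpec, SATURATED, ConvergenceError, PathModel
from .tscore import DegenerateGroupError, compute_tscores

__all__ = ["PerturbationSpec", "BootstrapResult", "perturb_signature", "run_bootstrap"]

_TAILS = ("lower", "upper", "two_sided")
_MODES = ("without_replacement", "with_replacement")
MAX_FAILURE_FRACTION = 0.05


@dataclass(frozen=True)
class PerturbationSpec:
    """What to eliminate, how to resample, and which statistic to test."""

    target_genes: GeneSet
    mode: str = "without_replacement"
    pool: GeneSet | None = None
    iterations: int = 1000
    seed: int = 0
    statistic: str = "gamma11"
    tail: str = "two_sided"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.tail not in _TAILS:
            raise ValueError(f"tail must be one of {_TAILS}, got {self.tail!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.mode == "with_replacement" and self.pool is None:
            raise ValueError("with_replacement mode requires a gene pool")


@dataclass
class BootstrapResult:
    """Observed statistic, replicate distribution and empirical p-value."""

    observed: float
    replicates: np.ndarray  # length B; NaN marks a failed replicate
    pvalue: float
    mode: str
    seed: int
    B: int
    statistic: str
    tail: str
    n_failed: int = 0
    observed_fit: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, object]:
        return {
            "observed": self.observed,
            "pvalue": self.pvalue,
            "mode": self.mode,
            "seed": self.seed,
            "iterations": self.B,
            "statistic": self.statistic,
            "tail": self.tail,
            "n_failed": self.n_failed,
            "replicates": [float(x) if np.isfinite(x) else None for x in self.replicates],
            "observed_fit": self.observed_fit,
        }


def _remove_and_refill(
    sig: ProjectedSignature,
    remove: list[str],
    refill: list[str] | None,
) -> ProjectedSignature:
    """Remove ``remove`` (ordered) and optionally add ``refill`` genes, each
    refill gene taking the direction of the removed gene at the same index."""
    up = set(sig.up_homologs)
    down = set(sig.down_homologs)
    directions: list[str] = []
    for g in remove:
        if g in up:
            up.discard(g)
            directions.append("up")
        elif g in down:
            down.discard(g)
            directions.append("down")
        else:
            raise ValueError(f"gene {g!r} is not in the projected signature")
    if refill is not None:
        if len(refill) != len(remove):
            raise ValueError("refill must match the number of removed genes")
        for g, direction in zip(refill, directions):
            (up if direction == "up" else down).add(g)
    if len(up) < 2 or len(down) < 2:
        raise ValueError(
            f"perturbation leaves too few genes: {len(up)} up / {len(down)} down "
            "(need >=2 per direction)"
        )
    return ProjectedSignature(
        frozenset(up), frozenset(down), sig.dropped_up, sig.dropped_down
    )


def _draw_refill(
    sig_genes: frozenset[str], pool: GeneSet, n: int, rng: np.random.Generator
) -> list[str]:
    candidates = sorted(pool.genes - sig_genes)
    if len(candidates) < n:
        raise ValueError(
            f"pool has only {len(candidates)} genes outside the signature; need {n}"
        )
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in idx]


def perturb_signature(
    sig: ProjectedSignature,
    spec: PerturbationSpec,
    rng: np.random.Generator,
) -> ProjectedSignature:
    """Apply the specified elimination to a projected signature.

    ``without_replacement`` removes the target genes; ``with_replacement``
    removes them and refills to the original size from the pool.  An empty
    intersection of targets with the signature returns the signature
    unchanged.
    """
    sig_genes = sig.up_homologs | sig.down_homologs
    stray = spec.target_genes.genes - sig_genes
    if stray:
        raise ValueError(
            f"target genes not in the projected signature: {sorted(stray)[:5]}"
        )
    remove = sorted(spec.target_genes.genes & sig_genes)
    if not remove:
        return sig
    if spec.mode == "without_replacement":
        return _remove_and_refill(sig, remove, None)
    refill = _draw_refill(sig_genes, spec.pool, len(remove), rng)
    return _remove_and_refill(sig, remove, refill)


def _replicate_rng(seed: int, index: int) -> np.random.Generator:
    """Independent substream for replicate ``index`` of master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def run_bootstrap(
    matrix: ExpressionMatrix,
    sig: ProjectedSignature,
    other_regulator: np.ndarray,
    endpoint: np.ndarray,
    spec: PerturbationSpec,
    model_spec: PathModelSpec = SATURATED,
) -> BootstrapResult:
    """Elimination bootstrap on the signature -> T-score -> path-model chain.

    ``matrix`` must be the gene-level, median-centered matrix the reference
    T-scores were computed on.  The perturbed signature's T-scores enter the
    path model as fac1; ``other_regulator`` (T-scores or expression of the
    second regulator) and ``endpoint`` are held fixed.

    The p-value counts replicates at least as extreme as the observed
    statistic under ``spec.tail`` and is floored at one count.
    """
    sig_genes = sig.up_homologs | sig.down_homologs
    remove = sorted(spec.target_genes.genes & sig_genes)
    stray = spec.target_genes.genes - sig_genes
    if stray:
        raise ValueError(
            f"target genes not in the projected signature: {sorted(stray)[:5]}"
        )
    non_target = sorted(sig_genes - set(remove))
    n_remove = len(remove)

    other_regulator = np.asarray(other_regulator, dtype=float)
    endpoint = np.asarray(endpoint, dtype=float)

    def _statistic(perturbed: ProjectedSignature) -> tuple[float, dict[str, float]]:
        tt = compute_tscores(matrix, perturbed)
        data = SEMData(tt["tscore"].to_numpy(), other_regulator, endpoint)
        fit = PathModel(data, model_spec).fit()
        return fit.statistic(spec.statistic), fit.to_dict()

    # observed: deterministic removal of the actual target set
    observed_sig = _remove_and_refill(sig, remove, None) if remove else sig
    observed, observed_fit = _statistic(observed_sig)

    B = spec.iterations
    replicates = np.full(B, np.nan)
    n_failed = 0
    for i in range(B):
        rng = _replicate_rng(spec.seed, i)
        try:
            if spec.mode == "without_replacement":
                if n_remove > len(non_target):
                    raise ValueError(
                        f"cannot draw {n_remove} non-target genes from "
                        f"{len(non_target)} available"
                    )
                idx = rng.choice(len(non_target), size=n_remove, replace=False)
                null_remove = [non_target[j] for j in idx]
                perturbed = _remove_and_refill(sig, null_remove, None)
            else:
                refill = _draw_refill(sig_genes, spec.pool, n_remove, rng)
                perturbed = _remove_and_refill(sig, remove, refill)
            replicates[i], _ = _statistic(perturbed)
        except (DegenerateGroupError, ConvergenceError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > MAX_FAILURE_FRACTION * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed (limit "
            f"{MAX_FAILURE_FRACTION:.0%}); inputs too degenerate"
        )

    ok = replicates[np.isfinite(replicates)]
    b_eff = len(ok)
    c_le = int(np.sum(ok <= observed))
    c_ge = int(np.sum(ok >= observed))
    if spec.tail == "lower":
        count = c_le
    elif spec.tail == "upper":
        count = c_ge
    else:
        count = min(2 * min(c_le, c_ge), b_eff)
    pvalue = max(count, 1) / b_eff

    return BootstrapResult(
        observed=float(observed),
        replicates=replicates,
        pvalue=float(pvalue),
        mode=spec.mode,
        seed=spec.seed,
        B=B,
        statistic=spec.statistic,
        tail=spec.tail,
        n_failed=n_failed,
        observed_fit=observed_fit,
    )
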