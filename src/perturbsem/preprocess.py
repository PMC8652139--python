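"""Probe collapse, median centering, and signature projection.

Pipeline order is collapse → median-center → project: the centering must
describe the gene-level values that are actually tested, and the projected
signature must refer to rows of the final matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GeneSignature, OrthologMap

logger = logging.getLogger(__name__)

__all__ = ["ProjectedSignature", "collapse_probes", "median_center", "project_signature"]


@dataclass
class ProjectedSignature:
    """A signature mapped onto the gene universe of a target matrix.

    ``up_homologs`` / ``down_homologs`` are rows of the gene-level matrix.
    ``dropped_up`` / ``dropped_down`` count source genes that contributed no
    surviving homolog (missing map entry, homolog absent from the matrix,
    or removed as an up/down conflict).
    """

    up_homologs: frozenset[str]
    down_homologs: frozenset[str]
    dropped_up: int = 0
    dropped_down: int = 0

    def __post_init__(self) -> None:
        self.up_homologs = frozenset(self.up_homologs)
        self.down_homologs = frozenset(self.down_homologs)
        if self.up_homologs & self.down_homologs:
            raise ValueError("projected up/down homolog sets overlap")

    def __len__(self) -> int:
        return len(self.up_homologs) + len(self.down_homologs)


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene: OrthologMap
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    For each gene with several probes the probe row with the largest sample
    standard deviation (ddof=1) represents the gene; ties break to the
    lexicographically first probe id.  Probes with no mapping, or mapped to
    more than one gene, are dropped (counts logged).
    """
    if matrix.level != "probe":
        raise ValueError("collapse_probes expects a probe-level matrix")
    mapping = probe_to_gene.as_dict()

    gene_of: dict[str, str] = {}
    n_unmapped = 0
    n_ambiguous = 0
    for probe in matrix.row_ids:
        targets = mapping.get(probe)
        if not targets:
            n_unmapped += 1
        elif len(targets) > 1:
            n_ambiguous += 1
        else:
            gene_of[probe] = next(iter(targets))
    if n_unmapped or n_ambiguous:
        logger.info(
            "collapse_probes: dropped %d unmapped and %d ambiguously mapped probes",
            n_unmapped,
            n_ambiguous,
        )
    if not gene_of:
        raise ValueError("no probe maps to a unique gene; nothing to collapse")

    df = matrix.data
    sds = df.std(axis=1, ddof=1)
    best: dict[str, tuple[float, str, int]] = {}  # gene -> (sd, probe_id, row position)
    for pos, probe in enumerate(df.index):
        gene = gene_of.get(probe)
        if gene is None:
            continue
        key = (float(sds.iloc[pos]), probe, pos)
        cur = best.get(gene)
        # keep the larger SD; on an exact SD tie the lexicographically first probe id
        if cur is None or key[0] > cur[0] or (key[0] == cur[0] and key[1] < cur[1]):
            best[gene] = key
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    out = df.iloc[rows].copy()
    out.index = genes
    return ExpressionMatrix(out, level="gene")


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center every row to median zero across samples.

    Even sample counts use the mean of the two middle order statistics, so
    the operation is idempotent.
    """
    if matrix.n_samples < 1:
        raise ValueError("median centering needs at least one sample")
    values = matrix.values
    centered = values - np.median(values, axis=1, keepdims=True)
    out = matrix.data.copy()
    out.loc[:, :] = centered
    return ExpressionMatrix(out, level=matrix.level)


def project_signature(
    sig: GeneSignature,
    mapping: OrthologMap | None,
    matrix: ExpressionMatrix,
) -> ProjectedSignature:
    """Map a signature through an ortholog table onto a gene-level matrix.

    Each direction is the set image under the map intersected with the
    matrix rows.  A homolog reachable from both directions is a conflict and
    is excluded from both sets.  ``mapping=None`` means same-species use and
    implies the identity map.
    """
    if matrix.level != "gene":
        raise ValueError("project_signature expects a gene-level matrix")
    if mapping is None:
        mapping = OrthologMap.identity(sig.up_genes | sig.down_genes)
    universe = frozenset(matrix.row_ids)

    up_img = mapping.image(sig.up_genes) & universe
    down_img = mapping.image(sig.down_genes) & universe
    conflicts = up_img & down_img
    if conflicts:
        logger.warning(
            "project_signature: %d homologs reachable from both directions "
            "excluded: %s",
            len(conflicts),
            sorted(conflicts)[:5],
        )
    up_final = up_img - conflicts
    down_final = down_img - conflicts

    fwd = mapping.as_dict()

    def _n_dropped(source_genes: frozenset[str], kept: frozenset[str]) -> int:
        return sum(1 for g in source_genes if not (fwd.get(g, frozenset()) & kept))

    result_dropped_up = _n_dropped(sig.up_genes, up_final)
    result_dropped_down = _n_dropped(sig.down_genes, down_final)

    if not (up_final or down_final):
        raise ValueError("signature has no homologs in matrix")
    return ProjectedSignature(
        up_homologs=up_final,
        down_homologs=down_final,
        dropped_up=result_dropped_up,
        dropped_down=result_dropped_down,
    )
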