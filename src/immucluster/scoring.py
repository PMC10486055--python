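"""Robust standardization and single-sample geneset enrichment scoring.

Enrichment scores are the substrate of the immune clustering: each immune
cell-type geneset is scored per sample with a rank-weighted running-sum
statistic (ssGSEA), and score rows are then median-centred and MAD-scaled
before consensus clustering.

The MAD used throughout is the *raw* median absolute deviation, without the
1.4826 normality consistency constant, so that thresholds expressed in MAD
units (e.g. the 2-MAD specificity rule in geneset derivation) keep their
plain meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ScaledMatrix",
    "ScoreMatrix",
    "scale_expression",
    "scale_scores",
    "ssgsea_score",
]


@dataclass
class ScaledMatrix:
    """Per-row median-centred, MAD-scaled matrix.

    Attributes
    ----------
    values
        Row-standardized matrix, same shape/labels as the input. Rows with
        zero MAD carry all-zero values and are flagged in ``degenerate``.
    center, scale
        Per-row median and raw MAD; scaling is invertible where ``scale > 0``.
    degenerate
        Boolean per-row flag for MAD == 0 rows.
    """

    values: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    degenerate: pd.Series

    @property
    def columns(self) -> pd.Index:
        return self.values.columns

    @property
    def index(self) -> pd.Index:
        return self.values.index


def scale_expression(matrix: pd.DataFrame) -> ScaledMatrix:
    """Median-centre and MAD-scale every row of ``matrix``.

    Parameters
    ----------
    matrix
        Gene-by-column (sample or cell type) matrix of finite values.

    Returns
    -------
    ScaledMatrix
        ``(x - median(x)) / MAD(x)`` per row, raw MAD (no consistency
        constant). Constant rows (MAD == 0) are flagged and set to zero.

    Raises
    ------
    ValueError
        If the matrix has fewer than two columns (scale is undefined).
    """
    if matrix.shape[1] < 2:
        raise ValueError("scaling requires at least two columns")
    x = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains non-finite values")
    med = np.median(x, axis=1)
    mad = np.median(np.abs(x - med[:, None]), axis=1)
    degenerate = mad == 0.0
    safe = np.where(degenerate, 1.0, mad)
    z = (x - med[:, None]) / safe[:, None]
    z[degenerate, :] = 0.0
    return ScaledMatrix(
        values=pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        center=pd.Series(med, index=matrix.index, name="median"),
        scale=pd.Series(mad, index=matrix.index, name="mad"),
        degenerate=pd.Series(degenerate, index=matrix.index, name="degenerate"),
    )


@dataclass
class ScoreMatrix:
    """Geneset-by-sample enrichment scores.

    ``normalized`` records whether scores were divided by the global
    ``max - min`` of the raw score matrix; ``tau`` is the rank-weighting
    exponent used.
    """

    scores: pd.DataFrame
    normalized: bool
    tau: float


def _resolve_genesets(
    genesets: Mapping[str, Iterable[str]], genes: pd.Index
) -> dict[str, np.ndarray]:
    """Map each geneset to a boolean membership mask over ``genes``.

    Genes absent from the expression matrix are dropped with a warning; a
    geneset with no overlap at all is a hard error naming the set.
    """
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    masks: dict[str, np.ndarray] = {}
    for name, members in genesets.items():
        members = list(members)
        mask = np.zeros(n, dtype=bool)
        hit = 0
        for g in members:
            i = gene_pos.get(g)
            if i is not None:
                mask[i] = True
                hit += 1
        if hit == 0:
            raise ValueError(
                f"geneset {name!r} shares no genes with the expression matrix"
            )
        if hit < len(set(members)):
            warnings.warn(
                f"geneset {name!r}: {len(set(members)) - int(mask.sum())} gene(s) "
                "absent from the expression matrix were dropped",
                stacklevel=3,
            )
        if mask.all():
            raise ValueError(
                f"geneset {name!r} covers every gene; enrichment is undefined"
            )
        masks[name] = mask
    return masks


def ssgsea_score(
    expr: pd.DataFrame,
    genesets: Mapping[str, Iterable[str]] | object,
    tau: float = 0.25,
    normalize: bool = True,
) -> ScoreMatrix:
    """Single-sample geneset enrichment (ssGSEA) scores.

    For each sample, genes are ranked by expression in decreasing order
    (ties broken by stable input gene order). The gene at descending
    position ``i`` (0-based) carries rank weight ``(N - i) ** tau``. The
    running sum accumulates weight-normalized increments for in-set genes
    minus uniform ``1 / (N - m)`` increments for out-of-set genes, and the
    enrichment score is the sum of the running sum over all positions
    (the integral form of the statistic).

    Parameters
    ----------
    expr
        Gene-by-sample expression; ``log2(TPM + 1)`` is the expected input
        for the immune clustering pipeline, but any monotone per-sample
        transform yields identical raw scores (the statistic is rank-based).
    genesets
        Mapping of set name to gene identifiers, or any object with a
        ``genesets`` attribute holding such a mapping (e.g. a catalog).
    tau
        Rank-weighting exponent (0.25 by default, the documented ssGSEA
        convention).
    normalize
        If true, divide the whole score matrix by its global ``max - min``.

    Returns
    -------
    ScoreMatrix
    """
    mapping = getattr(genesets, "genesets", genesets)
    if not mapping:
        raise ValueError("no genesets supplied")
    genes = expr.index
    if genes.has_duplicates:
        raise ValueError("expression matrix has duplicated gene identifiers")
    masks = _resolve_genesets(mapping, genes)

    x = expr.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    # descending sort; stable kind keeps input gene order among ties
    order = np.argsort(-x, axis=0, kind="stable")
    weights = np.arange(n_genes, 0, -1, dtype=float) ** tau

    names = list(masks)
    scores = np.empty((len(names), n_samples), dtype=float)
    for j in range(n_samples):
        ordj = order[:, j]
        for si, name in enumerate(names):
            in_set = masks[name][ordj]
            w_in = np.where(in_set, weights, 0.0)
            p_in = np.cumsum(w_in)
            p_in /= p_in[-1]
            m = int(in_set.sum())
            p_out = np.cumsum(~in_set) / float(n_genes - m)
            scores[si, j] = float(np.sum(p_in - p_out))

    if normalize:
        span = scores.max() - scores.min()
        if span == 0.0:
            warnings.warn("score matrix is constant; normalization skipped")
        else:
            scores = scores / span
    return ScoreMatrix(
        scores=pd.DataFrame(scores, index=names, columns=expr.columns),
        normalized=normalize,
        tau=tau,
    )


def scale_scores(scores: ScoreMatrix | pd.DataFrame) -> ScaledMatrix:
    """Median-centre and MAD-scale each geneset row of a score matrix.

    Thin wrapper over :func:`scale_expression`; rows with zero MAD are
    flagged as degenerate and zeroed.
    """
    frame = scores.scores if isinstance(scores, ScoreMatrix) else scores
    return scale_expression(frame)
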