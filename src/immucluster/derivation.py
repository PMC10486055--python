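"""Derivation of tumour-clean immune cell-type genesets.

The procedure identifies genes that are (i) expressed in at least one
immune population, (ii) specific to immune over non-immune populations by a
robust margin, (iii) free of evidence of expression in tumour cells, and
(iv) assigned to exactly one major immune cell type by at least two
independent annotation sources. The result is a catalog of disjoint
cell-type genesets suitable for per-sample enrichment scoring.

All expression filters operate on median-centred, MAD-scaled values (see
:func:`immucluster.scoring.scale_expression`); thresholds are therefore in
raw-MAD units.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import ScaledMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MAJOR_CELL_TYPES",
    "SourceAssignment",
    "ConsensusAssignment",
    "GenesetCatalog",
    "EmptyCatalogError",
    "harmonize_cell_type",
    "expressed_genes",
    "immune_specific_genes",
    "tumor_expressed_genes",
    "consensus_assign",
    "build_catalog",
]

#: Major immune cell types that per-source annotations are aggregated into.
MAJOR_CELL_TYPES = (
    "T",
    "B",
    "NK",
    "monocyte",
    "dendritic",
    "granulocyte",
    "macrophage",
    "myeloid",
)

# Aggregation patterns from common subtype labels to major cell types.
# Order matters: the first matching pattern wins.
_SUBTYPE_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"\bnkt?\b|natural.?killer", "NK"),
    (r"treg|cd4|cd8|t.?(cell|helper|follicular|memory|naive)|\bth\d|^t$", "T"),
    (r"plasma|memory.?b|naive.?b|b.?cell|^b$", "B"),
    (r"\bcdc\d?\b|\bpdc\b|dendritic|\bdc\b", "dendritic"),
    (r"macrophage|\btam\b|microglia|kupffer", "macrophage"),
    (r"monocyte|\bmono\b", "monocyte"),
    (r"neutrophil|eosinophil|basophil|mast|granulocyte", "granulocyte"),
    (r"myeloid|\bmdsc\b", "myeloid"),
)


def harmonize_cell_type(label: str) -> str | None:
    """Map an immune cell-subtype label to its major cell type.

    Returns ``None`` when the label matches no known immune lineage, so
    callers can drop non-immune annotations.
    """
    if label in MAJOR_CELL_TYPES:
        return label
    low = label.strip().lower().replace("_", " ")
    for pattern, major in _SUBTYPE_PATTERNS:
        if re.search(pattern, low):
            return major
    return None


@dataclass
class SourceAssignment:
    """One annotation source's gene -> major-cell-type map.

    ``assignments`` must hold exactly one major cell type per gene; use
    :meth:`from_raw` to aggregate subtype labels first.
    """

    source_id: str
    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {ct for ct in self.assignments.values() if ct not in MAJOR_CELL_TYPES}
        if bad:
            raise ValueError(
                f"source {self.source_id!r}: unknown cell types {sorted(bad)}; "
                "aggregate subtype labels with SourceAssignment.from_raw"
            )

    @classmethod
    def from_raw(cls, source_id: str, raw: Mapping[str, str]) -> "SourceAssignment":
        """Build an assignment from subtype-level labels, dropping genes whose
        label does not map to a major immune cell type."""
        out: dict[str, str] = {}
        for gene, label in raw.items():
            major = harmonize_cell_type(label)
            if major is None:
                logger.debug("source %s: dropping %s (label %r not immune)",
                             source_id, gene, label)
                continue
            out[gene] = major
        return cls(source_id=source_id, assignments=out)


@dataclass
class ConsensusAssignment:
    """Result of the multi-source consensus vote.

    ``assignments`` holds genes reaching quorum for exactly one cell type;
    ``support`` the voting sources per assigned gene; ``ambiguous`` genes
    where two or more cell types independently reached quorum.
    """

    assignments: dict[str, str]
    support: dict[str, tuple[str, ...]]
    ambiguous: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)


class EmptyCatalogError(ValueError):
    """Raised when filtering leaves no geneset; the pipeline cannot proceed."""


@dataclass
class GenesetCatalog:
    """Disjoint cell-type genesets with per-gene provenance.

    ``excluded_small`` records cell types removed because they retained
    fewer genes than the minimum geneset size, with the reason.
    """

    genesets: dict[str, list[str]]
    provenance: dict[str, tuple[str, ...]]
    excluded_small: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.genesets.items())


def expressed_genes(scaled: ScaledMatrix, quantile: float = 0.75) -> set[str]:
    """Genes whose scaled value strictly exceeds the per-column quantile
    (linear-interpolation) in at least one column.

    Degenerate (MAD == 0) rows are all-zero and can never strictly exceed
    a quantile of a column they belong to when all rows are constant; they
    are not special-cased otherwise.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    z = scaled.values.to_numpy()
    thresh = np.quantile(z, quantile, axis=0, method="linear")
    hits = (z > thresh[None, :]).any(axis=1)
    return set(scaled.index[hits])


def immune_specific_genes(
    scaled: ScaledMatrix,
    immune_flags: Sequence[bool] | pd.Series,
    delta: float = 2.0,
) -> set[str]:
    """Genes at least ``delta`` scaled-MAD units higher in immune than in
    non-immune populations.

    Specificity is the difference of group maxima: a marker needs only one
    expressing immune cell type, so ``max(immune) - max(non-immune) >= delta``
    is the least restrictive reading consistent with the requirement.
    MAD-degenerate genes are never specific.
    """
    flags = np.asarray(immune_flags, dtype=bool)
    if flags.shape[0] != scaled.values.shape[1]:
        raise ValueError("immune_flags length must match the number of columns")
    if flags.all() or not flags.any():
        raise ValueError("both immune and non-immune column groups must be non-empty")
    z = scaled.values.to_numpy()
    diff = z[:, flags].max(axis=1) - z[:, ~flags].max(axis=1)
    ok = (diff >= delta) & ~scaled.degenerate.to_numpy()
    return set(scaled.index[ok])


def tumor_expressed_genes(
    bulk_sources: Iterable[ScaledMatrix] = (),
    singlecell_sources: Iterable[tuple[ScaledMatrix, Sequence[bool]]] = (),
    quantile: float = 0.75,
    delta: float = 2.0,
) -> set[str]:
    """Union of genes with evidence of expression in tumour (non-immune) cells.

    Bulk tumour sources (PDX / cell-line analogues) contribute genes expressed
    above the per-column quantile in any column; single-cell tumour sources
    contribute genes whose non-immune maximum exceeds the immune maximum by
    ``delta`` MAD units. The returned set is meant to be subtracted from the
    immune candidate set.
    """
    bulk_sources = list(bulk_sources)
    singlecell_sources = list(singlecell_sources)
    if not bulk_sources and not singlecell_sources:
        logger.warning("no tumour sources supplied; exclusion set is empty")
        return set()
    excluded: set[str] = set()
    for src in bulk_sources:
        excluded |= expressed_genes(src, quantile=quantile)
    for src, immune_flags in singlecell_sources:
        flags = np.asarray(immune_flags, dtype=bool)
        # non-immune vs immune: reuse the specificity rule with flags inverted
        excluded |= immune_specific_genes(src, ~flags, delta=delta)
    return excluded


def consensus_assign(
    sources: Sequence[SourceAssignment],
    min_sources: int = 2,
) -> ConsensusAssignment:
    """Assign each gene to the unique cell type supported by a quorum.

    A gene is assigned to cell type ``c`` iff at least ``min_sources``
    sources vote for ``c`` and no other cell type also reaches quorum for
    that gene; multi-quorum genes are dropped as ambiguous and logged.
    """
    if min_sources < 2:
        raise ValueError("min_sources must be at least 2")
    ids = [s.source_id for s in sources]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate source ids: {sorted(ids)}")

    votes: dict[str, dict[str, list[str]]] = {}
    for src in sources:
        for gene, ct in src.assignments.items():
            votes.setdefault(gene, {}).setdefault(ct, []).append(src.source_id)

    assignments: dict[str, str] = {}
    support: dict[str, tuple[str, ...]] = {}
    ambiguous: dict[str, dict[str, tuple[str, ...]]] = {}
    for gene, per_ct in votes.items():
        quorum = {ct: tuple(v) for ct, v in per_ct.items() if len(v) >= min_sources}
        if len(quorum) == 1:
            (ct, srcs), = quorum.items()
            assignments[gene] = ct
            support[gene] = srcs
        elif len(quorum) > 1:
            ambiguous[gene] = quorum
            logger.info("gene %s ambiguous across cell types %s; dropped",
                        gene, sorted(quorum))
    return ConsensusAssignment(assignments=assignments, support=support,
                               ambiguous=ambiguous)


def build_catalog(
    candidates: set[str],
    exclusion: set[str],
    assignment: ConsensusAssignment | Mapping[str, str],
    min_geneset_size: int = 10,
) -> GenesetCatalog:
    """Assemble the final catalog from candidates minus tumour-expressed genes.

    Genesets smaller than ``min_geneset_size`` are removed and recorded in
    ``excluded_small`` (small sets yield unstable enrichment scores).

    Raises
    ------
    EmptyCatalogError
        If no geneset survives filtering.
    """
    if isinstance(assignment, ConsensusAssignment):
        mapping = assignment.assignments
        support = assignment.support
    else:
        mapping = dict(assignment)
        support = {}

    kept = sorted((candidates - exclusion) & mapping.keys())
    by_type: dict[str, list[str]] = {}
    for gene in kept:
        by_type.setdefault(mapping[gene], []).append(gene)

    genesets: dict[str, list[str]] = {}
    excluded_small: dict[str, str] = {}
    for ct in sorted(by_type):
        genes = by_type[ct]
        if len(genes) < min_geneset_size:
            excluded_small[ct] = (
                f"only {len(genes)} gene(s), below minimum size {min_geneset_size}"
            )
        else:
            genesets[ct] = genes
    if not genesets:
        raise EmptyCatalogError(
            "no geneset survived filtering; cannot build a catalog"
        )
    provenance = {g: support.get(g, ()) for gs in genesets.values() for g in gs}
    return GenesetCatalog(genesets=genesets, provenance=provenance,
                          excluded_small=excluded_small)
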