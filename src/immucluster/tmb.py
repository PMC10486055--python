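"""Harmonized tumour mutational burden, oncogenic pathway flags and
peptide binder classification.

Mutation burden is only comparable across capture designs on territory
assayed by every design, so the module intersects padded interval sets
(BED, 0-based half-open) into a common region, filters variant tables
(1-based positions, VCF convention) on allele frequency and consequence
class, and normalizes counts per megabase. The coordinate bridge is
explicit: a 1-based position ``p`` falls in interval ``[start, end)`` iff
``start < p <= end``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalSet",
    "NONSYNONYMOUS_CLASSES",
    "common_regions",
    "filter_variants",
    "compute_tmb",
    "pathway_flags",
    "classify_binders",
]

NONSYNONYMOUS_CLASSES = frozenset({"nonsynonymous_snv", "nonsynonymous_indel"})
CONSEQUENCE_CLASSES = frozenset(
    {"nonsynonymous_snv", "nonsynonymous_indel", "synonymous", "other"}
)


def _merge(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, merged genomic intervals in 0-based half-open coordinates."""

    intervals: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_intervals(cls, intervals: Iterable[Sequence]) -> "IntervalSet":
        cleaned = []
        for item in intervals:
            chrom, start, end = str(item[0]), int(item[1]), int(item[2])
            if end <= start or start < 0:
                raise ValueError(f"malformed interval {chrom}:{start}-{end}")
            cleaned.append((chrom, start, end))
        return cls(intervals=tuple(_merge(cleaned)))

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
                try:
                    rows.append((fields[0], int(fields[1]), int(fields[2])))
                except ValueError as err:
                    raise ValueError(f"{path}:{lineno}: {err}") from None
        return cls.from_intervals(rows)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")

    @property
    def total_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def pad(self, pad: int) -> "IntervalSet":
        """Pad both sides by ``pad`` bp (clamped at coordinate 0) and merge."""
        return IntervalSet.from_intervals(
            (chrom, max(0, start - pad), end + pad)
            for chrom, start, end in self.intervals
        )

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in other.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        out = []
        for chrom, start, end in self.intervals:
            for o_start, o_end in by_chrom.get(chrom, ()):
                lo, hi = max(start, o_start), min(end, o_end)
                if hi > lo:
                    out.append((chrom, lo, hi))
        return IntervalSet(intervals=tuple(_merge(out)))

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Membership of a 1-based position: ``start < p <= end``."""
        return any(c == chrom and start < pos_1based <= end
                   for c, start, end in self.intervals)


def common_regions(sets: Sequence[IntervalSet], pad: int = 50) -> IntervalSet:
    """Intersection of interval sets, each padded by ``pad`` bp and merged.

    This is the harmonization step that makes burden comparable across
    exome kits and whole genomes: only territory covered by every design
    (after padding) contributes to the denominator.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("need at least one interval set")
    result = sets[0].pad(pad)
    for s in sets[1:]:
        result = result.intersect(s.pad(pad))
    return result


_VARIANT_COLUMNS = ("sample_id", "chromosome", "position", "consequence_class", "vaf")


def _validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns {missing}")
    bad_class = set(variants["consequence_class"]) - CONSEQUENCE_CLASSES
    if bad_class:
        raise ValueError(f"unknown consequence classes {sorted(bad_class)}")
    vaf = variants["vaf"].to_numpy(dtype=float)
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("VAF values must lie in [0, 1]")
    if np.any(variants["position"].to_numpy() < 1):
        raise ValueError("positions are 1-based and must be >= 1")
    return variants


def _normalize_chrom_names(variants: pd.DataFrame, regions: IntervalSet) -> pd.DataFrame:
    region_chroms = {c for c, _, _ in regions.intervals}
    var_chroms = set(variants["chromosome"].astype(str))
    if var_chroms & region_chroms:
        return variants
    region_prefixed = any(c.startswith("chr") for c in region_chroms)
    var_prefixed = any(c.startswith("chr") for c in var_chroms)
    if region_prefixed != var_prefixed:
        warnings.warn("chromosome naming differs between variants and regions; "
                      "normalizing 'chr' prefix")
        variants = variants.copy()
        if region_prefixed:
            variants["chromosome"] = "chr" + variants["chromosome"].astype(str)
        else:
            variants["chromosome"] = (
                variants["chromosome"].astype(str).str.removeprefix("chr"))
    return variants


def filter_variants(
    variants: pd.DataFrame,
    regions: IntervalSet,
    vaf_min: float = 0.03,
    classes: frozenset[str] | set[str] = NONSYNONYMOUS_CLASSES,
) -> pd.DataFrame:
    """Retain variants with ``vaf >= vaf_min``, a qualifying consequence
    class, and a 1-based position inside the common regions.

    Variants below 3% allele frequency are excluded by default (strict
    ``<`` exclusion, i.e. exactly 3% is retained). Indels are located by
    their start position.
    """
    variants = _validate_variants(variants)
    variants = _normalize_chrom_names(variants, regions)
    keep_class = variants["consequence_class"].isin(classes)
    keep_vaf = variants["vaf"].to_numpy(dtype=float) >= vaf_min
    in_region = [
        regions.contains(str(chrom), int(pos))
        for chrom, pos in zip(variants["chromosome"], variants["position"])
    ]
    return variants[keep_class & keep_vaf & np.asarray(in_region)].copy()


def compute_tmb(
    filtered: pd.DataFrame,
    regions: IntervalSet,
    include_indels: bool = True,
) -> pd.Series:
    """Per-sample mutation burden in variants per megabase of common region.

    ``include_indels`` switches between the SNV-only and SNV+Indel rates;
    only non-synonymous classes are counted (apply
    :func:`filter_variants` first for the VAF/region filters).
    """
    total_bp = regions.total_bp
    if total_bp == 0:
        raise ValueError("common region is empty; TMB is undefined")
    classes = {"nonsynonymous_snv"}
    if include_indels:
        classes.add("nonsynonymous_indel")
    sub = filtered[filtered["consequence_class"].isin(classes)]
    counts = sub.groupby("sample_id").size()
    all_samples = pd.Index(pd.unique(filtered["sample_id"]), name="sample_id")
    counts = counts.reindex(all_samples, fill_value=0)
    return (counts / (total_bp / 1e6)).rename("tmb_per_mb")


def pathway_flags(
    variants: pd.DataFrame,
    pathway_genes: Mapping[str, Sequence[str]],
    fusions: pd.DataFrame | None = None,
    known_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Sample-by-pathway boolean alteration flags.

    ``variants`` should already be filtered to qualifying alterations
    (non-synonymous, VAF-passing) and must carry a ``gene`` column.
    A fusion counts for both partner genes. Pathway genes absent from
    ``known_genes`` (when provided) are logged and ignored.
    """
    if "gene" not in variants.columns:
        raise ValueError("variant table needs a 'gene' column for pathway flags")
    samples: list[str] = list(pd.unique(variants["sample_id"]))
    hits: dict[str, set[str]] = {
        s: set(g) for s, g in variants.groupby("sample_id")["gene"]
    }
    if fusions is not None and len(fusions):
        for _, row in fusions.iterrows():
            s = row["sample_id"]
            hits.setdefault(s, set()).update([row["gene_a"], row["gene_b"]])
            if s not in samples:
                samples.append(s)
    known = set(known_genes) if known_genes is not None else None
    flags = {}
    for pathway, genes in pathway_genes.items():
        genes = list(genes)
        if known is not None:
            unknown = [g for g in genes if g not in known]
            if unknown:
                logger.warning("pathway %s: ignoring unknown gene symbols %s",
                               pathway, unknown)
                genes = [g for g in genes if g in known]
        gene_set = set(genes)
        flags[pathway] = [bool(hits.get(s, set()) & gene_set) for s in samples]
    return pd.DataFrame(flags, index=pd.Index(samples, name="sample_id"))


def classify_binders(ranks: pd.DataFrame) -> pd.DataFrame:
    """Count strong/weak/non-binding peptides per sample from percentile ranks.

    Thresholds: rank <= 0.5 is a strong binder, 0.5 < rank <= 2 a weak
    binder, anything larger a non-binder; boundary values classify as
    strong and weak respectively. Negative ranks are a domain error.
    """
    for col in ("sample_id", "percentile_rank"):
        if col not in ranks.columns:
            raise ValueError(f"rank table missing column {col!r}")
    r = ranks["percentile_rank"].to_numpy(dtype=float)
    if np.any(r < 0):
        raise ValueError("percentile ranks must be non-negative")
    cls = np.where(r <= 0.5, "n_strong", np.where(r <= 2.0, "n_weak", "n_nonbinder"))
    out = (
        pd.DataFrame({"sample_id": ranks["sample_id"], "class": cls})
        .groupby(["sample_id", "class"]).size().unstack(fill_value=0)
    )
    for col in ("n_strong", "n_weak", "n_nonbinder"):
        if col not in out.columns:
            out[col] = 0
    return out[["n_strong", "n_weak", "n_nonbinder"]]
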