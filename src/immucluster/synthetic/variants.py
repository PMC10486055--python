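"""Synthetic somatic variant tables over genomic interval systems.

Variants are placed uniformly over the union of the supplied interval
sets; non-synonymous counts per sample follow a Poisson law at the
requested per-megabase rate, with synonymous/other variants added on top
according to the class mix. Allele frequencies are Beta-distributed. The
generator records, per sample, the planted number of non-synonymous
variants falling in the padded common region (with and without the VAF
filter), which downstream filtering must reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..tmb import IntervalSet, common_regions

__all__ = ["SyntheticVariants", "simulate_variants"]

_BASES = ("A", "C", "G", "T")

#: Consequence-class mix conditional on (non)synonymous status.
DEFAULT_CLASS_MIX = {
    "nonsynonymous_snv": 0.8,
    "nonsynonymous_indel": 0.2,
}


@dataclass
class SyntheticVariants:
    """Variant table plus planted per-sample truth counts."""

    variants: pd.DataFrame
    common: IntervalSet
    truth_nonsyn_in_common: pd.Series
    truth_nonsyn_in_common_vafpass: pd.Series
    seed: int


def _uniform_positions(rng: np.random.Generator, region: IntervalSet,
                       k: int) -> list[tuple[str, int]]:
    """k positions (1-based) uniform over the region's bases."""
    lengths = np.array([end - start for _, start, end in region.intervals])
    total = int(lengths.sum())
    offsets = rng.integers(0, total, size=k)
    cum = np.cumsum(lengths)
    out = []
    for off in offsets:
        i = int(np.searchsorted(cum, off, side="right"))
        chrom, start, _ = region.intervals[i]
        within = int(off - (cum[i - 1] if i else 0))
        out.append((chrom, start + within + 1))  # 1-based
    return out


def simulate_variants(
    n_samples: int = 20,
    tmb_per_sample: Sequence[float] | float = 1.0,
    interval_sets: Sequence[IntervalSet] = (),
    vaf_beta_params: tuple[float, float] = (5.0, 20.0),
    pathway_genes: Mapping[str, Sequence[str]] | None = None,
    synonymous_rate: float = 0.5,
    vaf_min: float = 0.03,
    pad: int = 50,
    seed: int | None = None,
) -> SyntheticVariants:
    """Simulate somatic variants for ``n_samples`` samples.

    ``tmb_per_sample`` is the expected *non-synonymous* mutation rate per
    megabase of the padded common region; realized counts are Poisson
    draws recorded as truth. ``synonymous_rate`` adds synonymous/other
    variants as a fraction of the non-synonymous expectation. Each variant
    is annotated with a gene symbol; when ``pathway_genes`` is given, a
    fifth of variants are assigned to pathway genes at random so pathway
    flags have planted positives.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    interval_sets = list(interval_sets)
    if not interval_sets:
        raise ValueError("at least one interval set is required")
    common = common_regions(interval_sets, pad=pad)
    if common.total_bp == 0:
        raise ValueError("interval sets have an empty common region")
    rates = (np.full(n_samples, float(tmb_per_sample))
             if np.isscalar(tmb_per_sample)
             else np.asarray(tmb_per_sample, dtype=float))
    if rates.shape != (n_samples,):
        raise ValueError("tmb_per_sample must be scalar or length n_samples")

    rng = np.random.default_rng(seed)
    mb = common.total_bp / 1e6
    pathway_pool = (
        [g for genes in pathway_genes.values() for g in genes]
        if pathway_genes else []
    )

    rows = []
    truth_all: dict[str, int] = {}
    truth_pass: dict[str, int] = {}
    class_names = list(DEFAULT_CLASS_MIX)
    class_p = np.array([DEFAULT_CLASS_MIX[c] for c in class_names])
    for i in range(n_samples):
        sample = f"V{i:04d}"
        n_nonsyn = int(rng.poisson(rates[i] * mb))
        n_other = int(rng.poisson(rates[i] * mb * synonymous_rate))
        truth_all[sample] = n_nonsyn
        n_pass = 0
        positions = _uniform_positions(rng, common, n_nonsyn + n_other)
        for j, (chrom, pos) in enumerate(positions):
            nonsyn = j < n_nonsyn
            if nonsyn:
                cls = class_names[int(rng.choice(len(class_names), p=class_p))]
            else:
                cls = "synonymous" if rng.random() < 0.75 else "other"
            vaf = float(rng.beta(*vaf_beta_params))
            if nonsyn and vaf >= vaf_min:
                n_pass += 1
            ref = str(rng.choice(_BASES))
            if cls == "nonsynonymous_indel":
                alt = ref + "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
            else:
                alt = str(rng.choice([b for b in _BASES if b != ref]))
            if pathway_pool and rng.random() < 0.2:
                gene = str(rng.choice(pathway_pool))
            else:
                gene = f"GENE{int(rng.integers(1000)):03d}"
            rows.append({
                "sample_id": sample, "chromosome": chrom, "position": pos,
                "ref": ref, "alt": alt, "consequence_class": cls,
                "vaf": vaf, "gene": gene,
            })
        truth_pass[sample] = n_pass

    variants = pd.DataFrame(
        rows, columns=["sample_id", "chromosome", "position", "ref", "alt",
                       "consequence_class", "vaf", "gene"])
    samples = pd.Index([f"V{i:04d}" for i in range(n_samples)], name="sample_id")
    return SyntheticVariants(
        variants=variants,
        common=common,
        truth_nonsyn_in_common=pd.Series(truth_all, index=samples,
                                         name="nonsyn_in_common"),
        truth_nonsyn_in_common_vafpass=pd.Series(truth_pass, index=samples,
                                                 name="nonsyn_in_common_vafpass"),
        seed=int(seed),
    )
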