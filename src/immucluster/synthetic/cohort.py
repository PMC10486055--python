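"""Synthetic bulk tumour cohorts as convex tumour/immune mixtures.

Each sample is a convex combination of a tumour archetype (the average
non-immune profile of a reference panel) and a per-sample immune mixture,
formed on the transcript-fraction scale and renormalized to TPM. Four
planted immune clusters differ in the immune fraction range and the immune
cell types contributing to the mixture: *Inflamed* samples draw all immune
lineages at high fractions, *MyeloidPredominant* only myeloid lineages,
*Neutral* all lineages at intermediate fractions and *Desert* fractions
near zero. PDX-like negative controls carry an immune fraction of exactly
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import ReferencePanel

TPM_TOTAL = 1e6

__all__ = ["SyntheticCohort", "simulate_cohort", "CLUSTER_ORDER",
           "DEFAULT_FRACTION_RANGES", "MYELOID_TYPES"]

CLUSTER_ORDER = ("Inflamed", "MyeloidPredominant", "Neutral", "Desert")

#: Immune-fraction ranges per planted cluster. The values emulate a
#: low-infiltration paediatric cohort: the inflamed minority reaches
#: ~11-16% immune reads, the myeloid and neutral groups sit in mid-single
#: digits and the desert group is essentially devoid of immune signal.
DEFAULT_FRACTION_RANGES: dict[str, tuple[float, float]] = {
    "Inflamed": (0.11, 0.16),
    "MyeloidPredominant": (0.07, 0.12),
    "Neutral": (0.05, 0.08),
    "Desert": (0.0, 0.008),
}

#: Immune cell types counted as myeloid for the MyeloidPredominant mixture.
MYELOID_TYPES = frozenset({"monocyte", "dendritic", "granulocyte",
                           "macrophage", "myeloid"})


@dataclass
class SyntheticCohort:
    """Gene-by-sample TPM cohort with planted cluster and fraction truth."""

    expression: pd.DataFrame
    truth_cluster: pd.Series
    truth_immune_fraction: pd.Series
    batch: pd.Series
    negative_control: pd.Series
    seed: int

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns


def _to_fractions(col: np.ndarray) -> np.ndarray:
    total = col.sum()
    if total <= 0:
        raise ValueError("profile with non-positive total abundance")
    return col / total


def simulate_cohort(
    panel: ReferencePanel,
    n_per_cluster: Sequence[int] = (24, 72, 103, 41),
    fraction_ranges: Mapping[str, tuple[float, float]] | None = None,
    n_negative_controls: int = 0,
    noise_sd: float = 0.15,
    mixture_concentration: float = 10.0,
    seed: int | None = None,
) -> SyntheticCohort:
    """Simulate a cohort of tumour/immune mixtures from a reference panel.

    Parameters
    ----------
    panel
        Reference panel supplying immune profiles (its immune columns) and
        the tumour archetype (mean of its non-immune columns).
    n_per_cluster
        Sample counts for (Inflamed, MyeloidPredominant, Neutral, Desert);
        the default mirrors a 10/30/43/17% cluster prevalence design at
        n = 240.
    fraction_ranges
        Per-cluster immune-fraction intervals within [0, 1].
    noise_sd
        Multiplicative log-normal noise (sdlog) applied gene-wise before
        the final TPM renormalization; 0 gives exact mixtures.
    mixture_concentration
        Symmetric Dirichlet concentration for the per-sample immune
        cell-type weights; larger values give more even mixtures.
    n_negative_controls
        Extra PDX-like samples with immune fraction exactly 0 (batch tag
        "PDX").
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if len(n_per_cluster) != len(CLUSTER_ORDER):
        raise ValueError(f"n_per_cluster must have {len(CLUSTER_ORDER)} entries")
    ranges = dict(DEFAULT_FRACTION_RANGES)
    if fraction_ranges:
        ranges.update(fraction_ranges)
    for name, (lo, hi) in ranges.items():
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"fraction range for {name} outside [0, 1]: {(lo, hi)}")

    rng = np.random.default_rng(seed)
    genes = panel.expression.index
    immune_cols = panel.immune_columns
    myeloid_cols = [c for c in immune_cols if c in MYELOID_TYPES]
    if not myeloid_cols:
        raise ValueError("panel has no myeloid immune cell types")
    tumor = _to_fractions(
        panel.expression[panel.nonimmune_columns].to_numpy(dtype=float).mean(axis=1)
    )
    immune_fracs = {
        c: _to_fractions(panel.expression[c].to_numpy(dtype=float))
        for c in immune_cols
    }

    columns, clusters, fractions, batches, negatives = [], [], [], [], []
    data = []

    def _make_sample(cluster: str, f: float, types: Sequence[str]) -> np.ndarray:
        weights = rng.dirichlet(np.full(len(types), mixture_concentration))
        immune = np.sum(
            [w * immune_fracs[t] for w, t in zip(weights, types)], axis=0
        )
        mix = (1.0 - f) * tumor + f * immune
        if noise_sd > 0:
            mix = mix * rng.lognormal(0.0, noise_sd, size=mix.shape)
        return mix / mix.sum() * TPM_TOTAL

    idx = 0
    for cluster, n in zip(CLUSTER_ORDER, n_per_cluster):
        lo, hi = ranges[cluster]
        types = myeloid_cols if cluster == "MyeloidPredominant" else immune_cols
        for _ in range(int(n)):
            f = float(rng.uniform(lo, hi))
            data.append(_make_sample(cluster, f, types))
            columns.append(f"S{idx:04d}")
            clusters.append(cluster)
            fractions.append(f)
            batches.append("cohort")
            negatives.append(False)
            idx += 1
    for _ in range(int(n_negative_controls)):
        data.append(_make_sample("Desert", 0.0, immune_cols))
        columns.append(f"PDX{idx:04d}")
        clusters.append("Desert")
        fractions.append(0.0)
        batches.append("PDX")
        negatives.append(True)
        idx += 1

    expression = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    samples = pd.Index(columns, name="sample")
    return SyntheticCohort(
        expression=expression,
        truth_cluster=pd.Series(clusters, index=samples, name="truth_cluster"),
        truth_immune_fraction=pd.Series(fractions, index=samples,
                                        name="truth_immune_fraction"),
        batch=pd.Series(batches, index=samples, name="batch"),
        negative_control=pd.Series(negatives, index=samples,
                                   name="negative_control"),
        seed=int(seed),
    )
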