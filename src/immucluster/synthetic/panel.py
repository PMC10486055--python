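"""Synthetic purified cell-type reference panels with planted ground truth.

The panel emulates a compendium of purified cell-type expression profiles
(immune and non-immune populations). Gene baselines are drawn from a common
log-normal; cell-type columns add Gaussian noise on the log2 scale. Marker
genes are planted at ``median + effect * MAD`` of their own background row
(so the planted effect is expressed directly in the scaled-MAD units used
by the downstream filters) in exactly one cell type; immune markers carry
near-zero abundance in every non-immune population (the tumour-clean
property the derivation is meant to recover). Tumour-shared genes are
planted high in every non-immune population and silenced (half-normal
below the row centre) in immune populations, mimicking tumour-intrinsic
genes with no immune expression. With ``effect = 0`` nothing is planted
(the null construction: truth sets are recorded but carry no signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ReferencePanel", "simulate_reference_panel", "DEFAULT_CELL_TYPES"]

#: (cell type, immune flag) defaults: six immune lineages scored downstream
#: plus six non-immune populations acting as the tumour/stromal comparator.
DEFAULT_CELL_TYPES: tuple[tuple[str, bool], ...] = (
    ("T", True),
    ("B", True),
    ("NK", True),
    ("monocyte", True),
    ("dendritic", True),
    ("granulocyte", True),
    ("fibroblast", False),
    ("endothelial", False),
    ("astrocyte", False),
    ("neuron", False),
    ("tumour_line", False),
    ("pdx", False),
)


@dataclass
class ReferencePanel:
    """Gene-by-cell-type abundances with planted truth.

    ``truth_markers`` maps each cell type to its planted marker genes (every
    marker belongs to exactly one cell type); ``truth_tumor_shared`` holds
    genes planted as expressed in tumour (non-immune) populations only.
    """

    expression: pd.DataFrame
    cell_type_labels: list[str]
    immune_flag: pd.Series
    source_id: str
    truth_markers: dict[str, set[str]] = field(default_factory=dict)
    truth_tumor_shared: set[str] = field(default_factory=set)

    @property
    def immune_columns(self) -> list[str]:
        return list(self.immune_flag[self.immune_flag].index)

    @property
    def nonimmune_columns(self) -> list[str]:
        return list(self.immune_flag[~self.immune_flag].index)


def simulate_reference_panel(
    n_genes: int = 500,
    cell_types: Sequence[tuple[str, bool]] = DEFAULT_CELL_TYPES,
    n_markers_per_type: int = 20,
    n_tumor_shared: int = 30,
    effect: float = 4.0,
    noise_sd: float = 1.0,
    baseline_meanlog: float = 1.0,
    baseline_sdlog: float = 1.0,
    seed: int | None = None,
    source_id: str = "synthetic_panel",
) -> ReferencePanel:
    """Generate a reference panel with planted markers and tumour genes.

    Parameters
    ----------
    n_genes
        Total genes; must accommodate all planted markers plus the
        tumour-shared set.
    cell_types
        ``(name, immune_flag)`` pairs; at least two immune and one
        non-immune population are required.
    effect
        Planted marker elevation in scaled-MAD units of the background row
        (markers land at ``median + effect * MAD``).
    noise_sd
        Cross-cell-type Gaussian noise on the log2(1 + TPM) scale.
    seed
        Required; the generators refuse to run unseeded.

    Notes
    -----
    Internally the panel is built on the ``log2(1 + x)`` scale and
    exponentiated, so applying ``log2(1 + x)`` downstream recovers the
    planted structure exactly (values are clamped at zero abundance).
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    cell_types = list(cell_types)
    names = [n for n, _ in cell_types]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cell type names")
    flags = np.array([f for _, f in cell_types], dtype=bool)
    if flags.sum() < 2 or (~flags).sum() < 1:
        raise ValueError("need at least 2 immune and 1 non-immune cell types")
    n_types = len(cell_types)
    if n_genes < n_types * n_markers_per_type + n_tumor_shared:
        raise ValueError(
            f"n_genes={n_genes} cannot hold {n_types} x {n_markers_per_type} "
            f"markers plus {n_tumor_shared} tumour-shared genes"
        )

    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    baseline = np.log2(1.0 + rng.lognormal(baseline_meanlog, baseline_sdlog,
                                           size=n_genes))
    n_planted = n_types * n_markers_per_type + n_tumor_shared
    # planted genes are well-expressed in their own population; a baseline
    # floor keeps their rows clear of the zero-abundance clamp
    baseline[:n_planted] = np.maximum(baseline[:n_planted], 1.5)
    y = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_types))
    # log2(1 + TPM) values cannot be negative; clamp before planting so the
    # planted structure survives the expression round trip exactly
    y = np.maximum(y, 0.0)

    med = np.median(y, axis=1)
    mad = np.median(np.abs(y - med[:, None]), axis=1)

    def _plant(row: np.ndarray, cell: int) -> None:
        """Fix one cell at ``effect`` scaled-MAD units above its row centre.

        Self-consistent: iterates value <- median + effect * MAD of the
        whole row (including the planted cell) so the planted value sits at
        ~``effect`` in the units the downstream row scaler will compute.
        The MAD is floored at half the noise scale so planting stays
        meaningful for near-silent background rows.
        """
        rest = np.delete(row, cell)
        m = np.median(rest)
        v = m + effect * max(np.median(np.abs(rest - m)), 0.5 * noise_sd)
        for _ in range(8):
            row[cell] = v
            m = np.median(row)
            s = max(np.median(np.abs(row - m)), 0.5 * noise_sd)
            new = m + effect * s
            if abs(new - v) < 1e-12:
                break
            v = new
        row[cell] = v

    truth_markers: dict[str, set[str]] = {name: set() for name in names}
    imm_idx = np.flatnonzero(flags)
    non_idx = np.flatnonzero(~flags)
    g = 0
    for t, name in enumerate(names):
        for _ in range(n_markers_per_type):
            if effect > 0:
                if flags[t]:
                    # immune markers lack tumour/stromal expression: near-zero
                    # abundance in every non-immune population
                    y[g, non_idx] = np.abs(rng.normal(0.0, 0.1, size=len(non_idx)))
                _plant(y[g], t)
            truth_markers[name].add(genes[g])
            g += 1
    truth_tumor_shared: set[str] = set()
    for _ in range(n_tumor_shared):
        if effect > 0:
            y[g, non_idx] = med[g] + effect * max(mad[g], 0.5 * noise_sd)
            # silenced in immune populations: half-normal below the row centre
            y[g, imm_idx] = np.maximum(
                med[g] - np.abs(rng.normal(0.0, noise_sd, size=len(imm_idx))),
                0.0)
        truth_tumor_shared.add(genes[g])
        g += 1

    expression = np.maximum(np.exp2(y) - 1.0, 0.0)
    frame = pd.DataFrame(expression, index=genes, columns=names)
    return ReferencePanel(
        expression=frame,
        cell_type_labels=names,
        immune_flag=pd.Series(flags, index=names, name="immune_flag"),
        source_id=source_id,
        truth_markers=truth_markers,
        truth_tumor_shared=truth_tumor_shared,
    )
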