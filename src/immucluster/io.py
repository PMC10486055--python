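"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices are genes-by-samples TSV with a header row of sample
identifiers; genesets travel as GMT; clonotypes as MiXCR-style TSV;
variants as MAF-like TSV; intervals as 3-column BED (see
:class:`immucluster.tmb.IntervalSet` for BED handling).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .derivation import GenesetCatalog
from .synthetic.repertoire import SyntheticRepertoire

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "write_clonotypes",
    "write_variants",
    "read_variants",
    "read_panel_annotation",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV (first column = gene identifiers)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicated gene identifiers")
    return df


def write_expression(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping name -> gene list."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need name, "
                                 "description and at least one gene")
            out[fields[0]] = [g for g in fields[2:] if g]
    return out


def write_gmt(
    genesets: GenesetCatalog | Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    """Write genesets as GMT; for a catalog, the description records the
    supporting-source count range of the set's genes."""
    if isinstance(genesets, GenesetCatalog):
        mapping = genesets.genesets
        descriptions = {}
        for name, genes in mapping.items():
            counts = [len(genesets.provenance.get(g, ())) for g in genes]
            counts = [c for c in counts if c > 0]
            descriptions[name] = (
                f"sources_{min(counts)}-{max(counts)}" if counts else "na")
    else:
        mapping = dict(genesets)
    with open(path, "w") as fh:
        for name, genes in mapping.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_clonotypes(rep: SyntheticRepertoire, path: str | Path) -> None:
    """Write a repertoire as a MiXCR-style clonotype TSV."""
    total = sum(c[3] for c in rep.clones)
    rows = []
    for i, (cdr3, chain, c_seg, count) in enumerate(rep.clones):
        rows.append({
            "cloneCount": count,
            "cloneFraction": f"{count / total:.10g}",
            "aaSeqCDR3": cdr3,
            "allVHitsWithScore": f"{chain}V{i % 30 + 1}-1*00(1000)",
            "allCHitsWithScore": f"{c_seg}*00(500)" if c_seg else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_variants(variants: pd.DataFrame, path: str | Path) -> None:
    variants.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    df["position"] = df["position"].astype(np.int64)
    df["vaf"] = df["vaf"].astype(float)
    return df


def read_panel_annotation(path: str | Path) -> pd.DataFrame:
    """Sidecar column-annotation TSV: column, cell_type, immune_flag,
    source_id."""
    ann = pd.read_csv(path, sep="\t")
    required = {"column", "cell_type", "immune_flag", "source_id"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    ann["immune_flag"] = ann["immune_flag"].astype(bool)
    return ann
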