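"""T- and B-cell repertoire diversity, clonality and IGH cluster analysis.

Clonotype tables (MiXCR-style TSV) provide per-clone CDR3 amino-acid
sequences, chain and constant-segment labels, and read counts. From these
the module computes observed diversity (richness, Shannon entropy, inverse
Simpson), asymptotic diversity via frequency-count estimators (Chao1
richness; the Chao-Wang-Jost asymptotic Shannon entropy built from
rarefaction slopes plus a singleton tail correction; the unbiased inverse
Simpson), classifies samples as clonal/polyclonal/typical from residuals of
a diversity-versus-reads regression, and analyses IGH repertoires: isotype
composition, mismatch-tolerant CDR3 octamer clustering (somatic
hypermutation produces near-identical descendants of one naive ancestor)
and the gini index of cluster-size inequality.

Shannon entropy uses the natural logarithm throughout; the clonality
regression operates on log10 axes by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "ClonotypeTable",
    "DiversityEstimate",
    "RepertoireClassification",
    "IGHClusterResult",
    "read_clonotypes",
    "observed_diversity",
    "asymptotic_diversity",
    "classify_repertoires",
    "isotype_composition",
    "central_octamer",
    "cluster_igh_cdr3",
    "gini_index",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


@dataclass
class ClonotypeTable:
    """Per-sample clone records.

    ``records`` columns: ``cdr3_aa`` (uppercase amino-acid string), ``chain``
    ({"TRB", "IGH", "other"}), ``c_segment`` (isotype label or None),
    ``count`` (positive integer) and ``fraction`` (count over the chain
    total).
    """

    sample_id: str
    records: pd.DataFrame

    def chain(self, chain: str) -> pd.DataFrame:
        return self.records[self.records["chain"] == chain]

    @property
    def counts(self) -> np.ndarray:
        return self.records["count"].to_numpy()


def _infer_chain(v_hits: str, c_hits: str) -> str:
    for hits in (v_hits, c_hits):
        if isinstance(hits, str):
            if hits.startswith("TRB"):
                return "TRB"
            if hits.startswith("IGH"):
                return "IGH"
    return "other"


def _c_segment(c_hits: str) -> str | None:
    if not isinstance(c_hits, str) or not c_hits:
        return None
    return c_hits.split(",")[0].split("*")[0].split("(")[0].strip()


def read_clonotypes(path: str | Path, sample_id: str | None = None) -> ClonotypeTable:
    """Parse a MiXCR-style clonotype TSV into a :class:`ClonotypeTable`.

    Requires columns ``cloneCount`` and ``aaSeqCDR3``; chain is inferred
    from the V/C hit prefixes and clone fractions are recomputed from
    counts within each chain. Malformed rows (non-positive counts, empty or
    non-amino-acid CDR3 strings) are logged and skipped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cloneCount", "aaSeqCDR3"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    rows = []
    for i, row in df.iterrows():
        try:
            count = float(row["cloneCount"])
        except (TypeError, ValueError):
            logger.warning("%s row %d: unparseable cloneCount; skipped", path.name, i)
            continue
        if not count >= 1 or count != int(count):
            logger.warning("%s row %d: invalid count %r; skipped", path.name, i, count)
            continue
        cdr3 = str(row["aaSeqCDR3"]).strip().upper()
        if not cdr3 or not set(cdr3) <= _AA_SET:
            logger.warning("%s row %d: malformed CDR3 %r; skipped", path.name, i, cdr3)
            continue
        v_hits = row.get("allVHitsWithScore", "")
        c_hits = row.get("allCHitsWithScore", "")
        rows.append(
            {"cdr3_aa": cdr3, "chain": _infer_chain(v_hits, c_hits),
             "c_segment": _c_segment(c_hits), "count": int(count)}
        )
    records = pd.DataFrame(rows, columns=["cdr3_aa", "chain", "c_segment", "count"])
    if len(records):
        totals = records.groupby("chain")["count"].transform("sum")
        records["fraction"] = records["count"] / totals
    else:
        records["fraction"] = pd.Series(dtype=float)
    return ClonotypeTable(sample_id=sample_id or path.stem, records=records)


def _check_counts(counts: Sequence[float]) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty clone counts")
    if np.any(x < 1) or np.any(x != np.round(x)):
        raise ValueError("clone counts must be positive integers")
    return x


def observed_diversity(counts: Sequence[float]) -> tuple[int, float, float]:
    """Observed richness, Shannon entropy (natural log) and inverse Simpson."""
    x = _check_counts(counts)
    p = x / x.sum()
    shannon = float(-np.sum(p * np.log(p)))
    simpson_inv = float(1.0 / np.sum(p**2))
    return int(x.size), shannon, simpson_inv


@dataclass
class DiversityEstimate:
    """Observed and asymptotic diversity for one sample.

    Asymptotic fields are ``None`` when the sample is excluded (fewer than
    three clonotypes, or all clone fractions identical).
    """

    n: int
    s_obs: int
    f1: int
    f2: int
    shannon_obs: float
    simpson_inv_obs: float
    chao1: float | None
    shannon_est: float | None
    simpson_inv_est: float | None
    excluded: bool
    exclusion_reason: str  # {"too_few_clonotypes", "all_equal_fractions", "none"}


def _chao1(s_obs: int, n: int, f1: int, f2: int) -> float:
    if f2 > 0:
        return s_obs + (n - 1) / n * f1**2 / (2.0 * f2)
    return s_obs + (n - 1) / n * f1 * (f1 - 1) / 2.0


def _shannon_tail(a: float, n: int) -> float:
    """Singleton tail sum ``(1-A)^(1-n) * (-ln A - sum_{r<n} (1-A)^r / r)``.

    Computed directly as ``sum_{r>=n} (1-A)^(r+1-n) / r`` to avoid the
    catastrophic cancellation of the textbook form at large n.
    """
    q = 1.0 - a
    if q <= 0.0:
        return 0.0
    total = 0.0
    r = n
    w = q  # q ** (r + 1 - n) at r = n
    while True:
        block = 0
        while block < 10000:
            term = w / r
            total += term
            r += 1
            w *= q
            block += 1
            if term < 1e-16 * max(total, 1e-300):
                return total
        if w == 0.0:
            return total


def asymptotic_diversity(counts: Sequence[float]) -> DiversityEstimate:
    """Frequency-count asymptotic diversity estimators for one sample.

    Chao1 richness uses the singleton/doubleton correction (with the
    bias-corrected form when no doubletons exist). The asymptotic Shannon
    entropy adds the rarefaction-slope sum
    ``sum_{x_i <= n-1} (x_i / n) * sum_{k=x_i}^{n-1} 1/k`` and a singleton
    tail correction governed by ``A = 2 f2 / ((n-1) f1 + 2 f2)`` (with the
    stated degenerate forms when ``f2 = 0``). The asymptotic inverse
    Simpson is ``1 / sum x_i (x_i - 1) / (n (n - 1))``.

    Samples with fewer than three clonotypes, or with all clone counts
    identical, are marked excluded and carry no asymptotic estimates.
    """
    x = _check_counts(counts)
    n = int(x.sum())
    s_obs = int(x.size)
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    _, shannon_obs, simpson_inv_obs = observed_diversity(x)

    if s_obs < 3:
        reason = "too_few_clonotypes"
    elif np.unique(x).size == 1:
        reason = "all_equal_fractions"
    else:
        reason = "none"
    if reason != "none":
        return DiversityEstimate(
            n=n, s_obs=s_obs, f1=f1, f2=f2, shannon_obs=shannon_obs,
            simpson_inv_obs=simpson_inv_obs, chao1=None, shannon_est=None,
            simpson_inv_est=None, excluded=True, exclusion_reason=reason)

    chao1 = _chao1(s_obs, n, f1, f2)

    # rarefaction-slope term: sum over clones with x_i <= n-1 of
    # (x_i / n) * (H_{n-1} - H_{x_i - 1}) with harmonic numbers H.
    harmonic = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, n))])  # H_0..H_{n-1}
    xi = x[x <= n - 1].astype(int)
    slope_sum = float(np.sum(xi / n * (harmonic[n - 1] - harmonic[xi - 1])))

    if f2 > 0:
        a = 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2)
    elif f1 > 0:
        a = 2.0 / ((n - 1) * (f1 - 1) + 2.0)
    else:
        a = 1.0
    tail = 0.0 if (f1 == 0 or a >= 1.0) else f1 / n * _shannon_tail(a, n)
    shannon_est = slope_sum + tail

    denom = float(np.sum(x * (x - 1))) / (n * (n - 1))
    simpson_inv_est = float("inf") if denom == 0 else 1.0 / denom

    return DiversityEstimate(
        n=n, s_obs=s_obs, f1=f1, f2=f2, shannon_obs=shannon_obs,
        simpson_inv_obs=simpson_inv_obs, chao1=float(chao1),
        shannon_est=float(shannon_est), simpson_inv_est=simpson_inv_est,
        excluded=False, exclusion_reason="none")


@dataclass
class RepertoireClassification:
    """Residual-based clonal/polyclonal calls plus the regression fit."""

    table: pd.DataFrame  # columns: x, y, residual, class
    slope: float
    intercept: float
    sigma: float
    adj_r2: float


def classify_repertoires(
    estimates: pd.DataFrame,
    log_axes: bool = True,
) -> RepertoireClassification:
    """Classify samples as clonal/polyclonal/typical by regression residuals.

    ``estimates`` must hold per-sample columns ``shannon_est`` and
    ``n_reads``. Estimated diversity is regressed on ``log10(n_reads)`` by
    ordinary least squares (the diversity is log10-transformed too when
    ``log_axes``); residuals more than two residual standard deviations
    below the line are *clonal* (uneven repertoire for its sequencing
    depth), more than two above are *polyclonal*, all others *typical*.
    A perfectly collinear fit (sigma = 0) yields no outliers.
    """
    df = estimates[["shannon_est", "n_reads"]].dropna().copy()
    if log_axes:
        pos = df["shannon_est"] > 0
        if (~pos).any():
            logger.warning("%d sample(s) with non-positive diversity dropped "
                           "from log-scale regression", int((~pos).sum()))
        df = df[pos]
    if len(df) < 10:
        raise ValueError("need at least 10 non-excluded samples for a stable "
                         "residual standard deviation")
    x = np.log10(df["n_reads"].to_numpy(dtype=float))
    y = df["shannon_est"].to_numpy(dtype=float)
    if log_axes:
        y = np.log10(y)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    resid = y - fitted
    dof = len(df) - 2
    sigma = float(np.sqrt(np.sum(resid**2) / dof))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (len(df) - 1) / dof
    if sigma > 0:
        cls = np.where(resid < -2 * sigma, "clonal",
                       np.where(resid > 2 * sigma, "polyclonal", "typical"))
    else:
        cls = np.full(len(df), "typical", dtype=object)
    table = pd.DataFrame({"x": x, "y": y, "residual": resid, "class": cls},
                         index=df.index)
    return RepertoireClassification(table=table, slope=float(slope),
                                    intercept=float(intercept), sigma=sigma,
                                    adj_r2=float(adj_r2))


def isotype_composition(table: ClonotypeTable) -> pd.DataFrame:
    """Per-isotype composition of the IGH repertoire.

    Returns fractions of clonotypes and of reads per constant-segment label
    among labelled IGH records; empty with a log message when the sample
    has no labelled IGH clones.
    """
    igh = table.chain("IGH")
    igh = igh[igh["c_segment"].notna()]
    if igh.empty:
        logger.info("sample %s: no labelled IGH records", table.sample_id)
        return pd.DataFrame(columns=["clonotype_fraction", "read_fraction"])
    by = igh.groupby("c_segment")["count"]
    return pd.DataFrame({
        "clonotype_fraction": by.size() / len(igh),
        "read_fraction": by.sum() / igh["count"].sum(),
    }).sort_index()


def central_octamer(cdr3: str) -> str:
    """Central length-8 window of a CDR3 (left-biased for odd overhangs)."""
    start = (len(cdr3) - 8) // 2
    return cdr3[start:start + 8]


@dataclass
class IGHClusterResult:
    """Octamer clusters of an IGH repertoire and their size inequality."""

    clusters: list[tuple[tuple[str, ...], int]]
    gini: float | None
    n_sequences_used: int
    excluded: bool


def cluster_igh_cdr3(
    table: ClonotypeTable,
    min_count: int = 3,
    size_by_reads: bool = True,
) -> IGHClusterResult:
    """Cluster IGH CDR3 sequences by central octamer with one mismatch.

    Sequences with fewer than ``min_count`` reads are removed (somatic
    hypermutation and sequencing error make low-count sequences
    unreliable). Each retained CDR3 of length >= 8 is represented by its
    central octamer; single-linkage clustering joins sequences whose
    octamers differ by at most one substitution. Sub-octamer sequences are
    always singleton clusters. Cluster size is the summed read count
    (or the number of member sequences when ``size_by_reads`` is false).
    Samples retaining three or fewer sequences are flagged excluded and get
    no gini index.
    """
    igh = table.chain("IGH")
    agg = igh.groupby("cdr3_aa", sort=True)["count"].sum()
    agg = agg[agg >= min_count]
    seqs = list(agg.index)
    n = len(seqs)

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    octamers = [central_octamer(s) if len(s) >= 8 else None for s in seqs]
    eligible = [i for i, o in enumerate(octamers) if o is not None]
    for a_idx in range(len(eligible)):
        i = eligible[a_idx]
        oi = octamers[i]
        for b_idx in range(a_idx + 1, len(eligible)):
            j = eligible[b_idx]
            mism = sum(c1 != c2 for c1, c2 in zip(oi, octamers[j]))
            if mism <= 1:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for members in groups.values():
        names = tuple(seqs[i] for i in members)
        size = int(sum(agg.iloc[i] for i in members)) if size_by_reads else len(members)
        clusters.append((names, size))
    clusters.sort(key=lambda c: (-c[1], c[0]))

    excluded = n <= 3
    gini = None if excluded else gini_index([size for _, size in clusters])
    return IGHClusterResult(clusters=clusters, gini=gini,
                            n_sequences_used=n, excluded=excluded)


def gini_index(
    sizes: Sequence[float],
    min_sequences: int | None = None,
) -> float | None:
    """Gini index of inequality ``sum_ij |x_i - x_j| / (2 n^2 mu)``.

    Computed via the sorted-rank identity (O(n log n)); 0 for perfect
    equality, bounded above by ``1 - 1/n``. When ``min_sequences`` is given
    and fewer sizes are supplied, returns ``None`` (sample excluded).
    """
    x = np.asarray(sizes, dtype=float)
    if x.size == 0:
        raise ValueError("empty size vector")
    if np.any(x <= 0):
        raise ValueError("sizes must be positive")
    if min_sequences is not None and x.size < min_sequences:
        return None
    xs = np.sort(x)
    n = xs.size
    ranks = np.arange(1, n + 1)
    return float(2.0 * np.sum(ranks * xs) / (n * xs.sum()) - (n + 1) / n)
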