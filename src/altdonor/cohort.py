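"""Cohort-level statistics on per-sample in-ex ratios.

The unit of analysis is a filtered cohort: samples retained when the target
gene is expressed (TPM >= 1) and the alternative-donor event is covered by at
least three junction-spanning reads.  Tissue-level inclusion/exclusion
distributions are then compared with

* the exact 1-D p-Wasserstein distance between empirical distributions
  (quantile-function merge; p = 1 by default),
* complete-linkage agglomerative clustering of the tissue distance matrix,
* the exact Wilcoxon rank-sum test with midrank tie handling (shift
  algorithm over doubled ranks) and the rank effect size r = |Z| / sqrt(N).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .junctions import compute_inex_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "CNS_CATEGORIES",
    "SampleRecord",
    "CohortTable",
    "DistanceMatrix",
    "Dendrogram",
    "TestResult",
    "is_cns_category",
    "filter_samples",
    "tissue_distribution",
    "wasserstein1d",
    "distance_matrix",
    "complete_linkage_cluster",
    "wilcoxon_ranksum",
    "read_sample_table",
    "read_s1_table",
    "write_cohort",
    "write_distance_matrix",
    "write_test_results",
]

#: Tissue categories counted as central nervous system.  Derived from the
#: ENCODE body-map nomenclature; override by passing your own set to
#: :func:`is_cns_category` / :func:`read_sample_table`.
CNS_CATEGORIES: frozenset[str] = frozenset(
    {
        "brain",
        "forebrain",
        "midbrain",
        "hindbrain",
        "spinal cord",
        "central nervous system",
        "cns",
        "neural tube",
        "cerebellum",
        "cerebral cortex",
    }
)


def is_cns_category(tissue_category: str, cns_categories: Iterable[str] = CNS_CATEGORIES) -> bool:
    """True when a tissue category belongs to the central nervous system."""
    return tissue_category.strip().lower() in {c.lower() for c in cns_categories}


@dataclass(frozen=True)
class SampleRecord:
    """One sample's metadata, junction counts and target-gene expression."""

    sample_id: str
    tissue_type: str
    tissue_category: str
    is_cns: bool
    inclusion_reads: int
    exclusion_reads: int
    gene_tpm: float

    @property
    def inex_ratio(self) -> float:
        return compute_inex_ratio(self.inclusion_reads, self.exclusion_reads)

    @property
    def total_junction_reads(self) -> int:
        return self.inclusion_reads + self.exclusion_reads


@dataclass
class CohortTable:
    """Samples surviving the expression and junction-coverage filters."""

    records: list[SampleRecord]
    species_label: str = ""
    #: samples retained per tissue type (filled by :func:`filter_samples`)
    retained_per_tissue: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_tissue_types(self) -> int:
        return len({r.tissue_type for r in self.records})

    def ratios(self, tissue_type: str | None = None, cns: bool | None = None) -> np.ndarray:
        """In-ex ratios, optionally restricted to a tissue type or CNS flag."""
        recs = self.records
        if tissue_type is not None:
            recs = [r for r in recs if r.tissue_type == tissue_type]
        if cns is not None:
            recs = [r for r in recs if r.is_cns == cns]
        return np.array([r.inex_ratio for r in recs], dtype=float)

    def groups(self, by: str = "tissue_type") -> dict[str, np.ndarray]:
        """In-ex ratio samples keyed by group label."""
        if by == "tissue_type":
            keys = sorted({r.tissue_type for r in self.records})
            return {k: self.ratios(tissue_type=k) for k in keys}
        if by == "cns_flag":
            out = {}
            for flag, name in ((True, "CNS"), (False, "other")):
                vals = self.ratios(cns=flag)
                if vals.size:
                    out[name] = vals
            return out
        raise ValueError(f"unknown grouping: {by!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "tissue_type": [r.tissue_type for r in self.records],
                "tissue_category": [r.tissue_category for r in self.records],
                "is_cns": [r.is_cns for r in self.records],
                "inclusion_reads": [r.inclusion_reads for r in self.records],
                "exclusion_reads": [r.exclusion_reads for r in self.records],
                "inex_ratio": [r.inex_ratio for r in self.records],
                "gene_tpm": [r.gene_tpm for r in self.records],
            }
        )


def filter_samples(
    records: Iterable[SampleRecord],
    tpm_min: float = 1.0,
    min_junction_reads: int = 3,
    species_label: str = "",
) -> CohortTable:
    """Apply the cohort inclusion filters (both thresholds inclusive).

    A sample is retained when its target-gene expression is at least
    ``tpm_min`` TPM *and* its combined junction-read support
    (inclusion + exclusion) is at least ``min_junction_reads``.
    """
    kept = [
        r
        for r in records
        if r.gene_tpm >= tpm_min and r.total_junction_reads >= min_junction_reads
    ]
    per_tissue: dict[str, int] = {}
    for r in kept:
        per_tissue[r.tissue_type] = per_tissue.get(r.tissue_type, 0) + 1
    return CohortTable(records=kept, species_label=species_label, retained_per_tissue=per_tissue)


def tissue_distribution(
    cohort: CohortTable,
    group_by: str = "tissue_type",
    bin_width: float = 0.1,
) -> dict[str, dict]:
    """Binned in-ex ratio densities per group over [-1, 1].

    Each group's histogram is normalized to unit area (density * bin_width
    sums to 1), matching side-by-side comparison of groups with different
    sample sizes.  Groups with zero samples are omitted with a warning.
    """
    if not cohort.records:
        raise ValueError("cohort is empty")
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:  # make sure +1 falls inside the last bin
        edges = np.append(edges, 1.0)
    out: dict[str, dict] = {}
    for name, vals in cohort.groups(by=group_by).items():
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            logger.warning("group %r has no samples with a defined ratio — omitted", name)
            continue
        density, _ = np.histogram(vals, bins=edges, density=True)
        out[name] = {"edges": edges, "density": density, "n": int(vals.size)}
    return out


def wasserstein1d(x: Sequence[float], y: Sequence[float], p: float = 1.0) -> float:
    """Exact p-Wasserstein distance between 1-D empirical distributions.

    Computed from the quantile functions of the two empirical distributions
    (merge of the breakpoints i/n_x and j/n_y; no Monte-Carlo):

        W_p(x, y) = ( integral_0^1 |F_x^-1(q) - F_y^-1(q)|^p dq )^(1/p)

    For equal sample sizes and p = 1 this reduces to the mean absolute
    difference of sorted values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wasserstein1d needs non-empty samples")
    if p < 1:
        raise ValueError("p must be >= 1")
    xs, ys = np.sort(x), np.sort(y)
    # merged quantile breakpoints of both empirical CDFs
    qs = np.union1d(np.arange(1, x.size + 1) / x.size, np.arange(1, y.size + 1) / y.size)
    widths = np.diff(np.concatenate(([0.0], qs)))
    # quantile function value on (q_{k-1}, q_k] is the ceil(q_k * n)-th order stat
    xi = np.ceil(qs * x.size - 1e-12).astype(int) - 1
    yi = np.ceil(qs * y.size - 1e-12).astype(int) - 1
    diffs = np.abs(xs[xi] - ys[yi])
    return float(np.sum(widths * diffs**p) ** (1.0 / p))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise Wasserstein distances between groups."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(
    cohort: CohortTable,
    group_by: str = "tissue_type",
    p: float = 1.0,
) -> DistanceMatrix:
    """Pairwise W1 between per-group raw in-ex ratio samples.

    Distances are computed on the raw per-sample ratios, not on binned
    histograms; binning is presentation-only.
    """
    groups = {k: v[~np.isnan(v)] for k, v in cohort.groups(by=group_by).items()}
    groups = {k: v for k, v in groups.items() if v.size > 0}
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups with samples")
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = wasserstein1d(groups[labels[i]], groups[labels[j]], p=p)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


@dataclass
class Dendrogram:
    """Agglomerative clustering result as an ordered merge list.

    ``merges`` holds tuples ``(left, right, height)`` where left/right are
    tuples of leaf labels (each sorted) and ``height`` is the linkage
    distance at which they merge.  Heights are non-decreasing.
    """

    leaves: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    def to_newick(self) -> str:
        """Ultrametric Newick string (branch length = height difference / 2)."""
        node: dict[tuple[str, ...], tuple[str, float]] = {
            (leaf,): (leaf, 0.0) for leaf in self.leaves
        }
        for left, right, height in self.merges:
            lname, lh = node.pop(left)
            rname, rh = node.pop(right)
            text = f"({lname}:{(height - lh) / 2:.6g},{rname}:{(height - rh) / 2:.6g})"
            node[tuple(sorted(left + right))] = (text, height)
        (tree, _), = node.values()
        return tree + ";"


def complete_linkage_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Complete-linkage agglomerative clustering of a distance matrix.

    At each step the pair of clusters with the smallest complete-linkage
    distance (maximum pairwise leaf distance) is merged; ties are broken by
    the lexicographically smallest label pair so the dendrogram is
    deterministic.
    """
    labels = dm.labels
    if len(labels) < 2:
        raise ValueError("need at least two labels to cluster")
    d = {
        frozenset((a, b)): dm.values[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    def linkage(c1: tuple[str, ...], c2: tuple[str, ...]) -> float:
        return max(d[frozenset((a, b))] for a in c1 for b in c2)

    while len(clusters) > 1:
        best: tuple[float, tuple[str, ...], tuple[str, ...]] | None = None
        for c1, c2 in itertools.combinations(sorted(clusters), 2):
            h = linkage(c1, c2)
            cand = (h, c1, c2)
            if best is None or cand < best:
                best = cand
        h, c1, c2 = best
        clusters.remove(c1)
        clusters.remove(c2)
        clusters.append(tuple(sorted(c1 + c2)))
        merges.append((c1, c2, h))
    return Dendrogram(leaves=sorted(labels), merges=merges)


@dataclass(frozen=True)
class TestResult:
    """Wilcoxon rank-sum test summary."""

    p_value: float
    z_statistic: float
    effect_size_r: float
    n_total: int
    method: str = "exact"


def _ranksum_null_moments(midranks: np.ndarray, n_x: int) -> tuple[float, float]:
    """Tie-corrected null mean and variance of the x-sample rank sum."""
    n = midranks.size
    n_y = n - n_x
    mean = n_x * (n + 1) / 2.0
    # Var(S) = n_x n_y / (N (N-1)) * (sum r_i^2 - N ((N+1)/2)^2)
    var = n_x * n_y / (n * (n - 1)) * (np.sum(midranks**2) - n * ((n + 1) / 2.0) ** 2)
    return mean, var


def _exact_ranksum_tails(midranks: np.ndarray, n_x: int, s_obs: float) -> tuple[float, float]:
    """P(S <= s_obs) and P(S >= s_obs) for the rank sum of n_x midranks.

    Shift algorithm over doubled midranks (integers even in the presence of
    ties): dynamic program over the number of chosen ranks and their sum,
    counting the C(N, n_x) equally likely subsets.
    """
    doubled = np.rint(2 * midranks).astype(np.int64)
    total = int(doubled.sum())
    # dp[k, s] = number of k-subsets of the first processed ranks with sum s
    dp = np.zeros((n_x + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled:
        r = int(r)
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    dist = dp[n_x]
    n_subsets = dist.sum()
    s2 = 2 * s_obs
    sums = np.arange(total + 1)
    # half-integer tolerance: observed sum is always attainable
    p_le = dist[sums <= s2 + 1e-9].sum() / n_subsets
    p_ge = dist[sums >= s2 - 1e-9].sum() / n_subsets
    return float(p_le), float(p_ge)


def wilcoxon_ranksum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    exact_threshold: int = 200,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test with midrank ties and effect size.

    ``mode`` is ``"exact"`` (enumerate the permutation null of the rank sum
    via the shift algorithm over doubled midranks), ``"normal_approx"``
    (tie-corrected normal approximation, no continuity correction) or
    ``"auto"`` (exact up to ``exact_threshold`` pooled observations).  The
    two-sided exact p-value is the central one, ``min(1, 2 min(P(S<=s),
    P(S>=s)))``.  In every mode the standardized statistic Z uses the
    tie-corrected null mean and variance, and the effect size is
    ``r = |Z| / sqrt(n_x + n_y)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode: {mode!r}")
    n_x, n_y = int(x.size), int(y.size)
    n = n_x + n_y
    pooled = np.concatenate([x, y])
    midranks = stats.rankdata(pooled)
    s_obs = float(midranks[:n_x].sum())
    mean, var = _ranksum_null_moments(midranks, n_x)
    if var <= 0:  # all pooled values identical
        return TestResult(p_value=1.0, z_statistic=0.0, effect_size_r=0.0,
                          n_total=n, method="degenerate")
    z = (s_obs - mean) / math.sqrt(var)
    use_exact = mode == "exact" or (mode == "auto" and n <= exact_threshold)
    if use_exact:
        p_le, p_ge = _exact_ranksum_tails(midranks, n_x, s_obs)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        p = 2.0 * stats.norm.sf(abs(z))
        method = "normal_approx"
    r = abs(z) / math.sqrt(n)
    return TestResult(p_value=float(p), z_statistic=float(z), effect_size_r=float(r),
                      n_total=n, method=method)


# ---------------------------------------------------------------------------
# I/O


def read_sample_table(
    path: str | Path,
    cns_categories: Iterable[str] = CNS_CATEGORIES,
    species_label: str = "",
) -> list[SampleRecord]:
    """Read a sample metadata + counts TSV.

    Required columns: ``sample_id``, ``tissue_type``, ``tissue_category``,
    ``inclusion_reads``, ``exclusion_reads``, ``gene_tpm``.  The CNS flag is
    derived from ``tissue_category`` via ``cns_categories`` unless an
    explicit boolean ``is_cns`` column is present.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["sample_id", "tissue_type", "tissue_category",
                "inclusion_reads", "exclusion_reads", "gene_tpm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        cat = str(row["tissue_category"])
        cns = bool(row["is_cns"]) if "is_cns" in df.columns else is_cns_category(cat, cns_categories)
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                tissue_type=str(row["tissue_type"]),
                tissue_category=cat,
                is_cns=cns,
                inclusion_reads=int(row["inclusion_reads"]),
                exclusion_reads=int(row["exclusion_reads"]),
                gene_tpm=float(row["gene_tpm"]),
            )
        )
    return records


#: Column synonyms accepted when loading a re-exported supplementary sample
#: table (per-sample GN[N/S]K-/+ counts, tissue labels and KIT TPM).
_S1_SYNONYMS: Mapping[str, tuple[str, ...]] = {
    "sample_id": ("sample_id", "sample", "accession", "experiment id", "run"),
    "tissue_type": ("tissue_type", "tissue type", "tissue"),
    "tissue_category": ("tissue_category", "tissue category", "category"),
    "inclusion_reads": ("inclusion_reads", "gnnk+", "gnsk+", "gn[n/s]k+", "read count of gnnk+",
                        "read count of gnsk+"),
    "exclusion_reads": ("exclusion_reads", "gnnk-", "gnsk-", "gn[n/s]k-", "read count of gnnk-",
                        "read count of gnsk-"),
    "gene_tpm": ("gene_tpm", "tpm", "kit tpm", "tpm of kit"),
}


def read_s1_table(
    path: str | Path,
    species_label: str = "",
    cns_categories: Iterable[str] = CNS_CATEGORIES,
) -> list[SampleRecord]:
    """Read a supplementary-style per-sample table re-exported as TSV.

    Accepts the column-name variants used in published per-sample summaries
    of GN[N/S]K-/+ junction counts (see ``_S1_SYNONYMS``); normalizes them to
    the :func:`read_sample_table` schema and delegates to it.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lower = {c.strip().lower(): c for c in df.columns}
    rename = {}
    for canonical, synonyms in _S1_SYNONYMS.items():
        for syn in synonyms:
            if syn in lower:
                rename[lower[syn]] = canonical
                break
        else:
            raise ValueError(f"{path}: no column recognizable as {canonical!r}")
    df = df.rename(columns=rename)
    tmp = Path(path).with_suffix(".normalized.tsv")
    df.to_csv(tmp, sep="\t", index=False)
    try:
        return read_sample_table(tmp, cns_categories=cns_categories, species_label=species_label)
    finally:
        tmp.unlink(missing_ok=True)


def write_cohort(cohort: CohortTable, path: str | Path, header_comment: str = "") -> None:
    """Write a filtered cohort as TSV (optionally with a provenance header)."""
    with Path(path).open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        cohort.to_frame().to_csv(fh, sep="\t", index=False)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path, header_comment: str = "") -> None:
    with Path(path).open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        dm.to_frame().to_csv(fh, sep="\t")


def write_test_results(
    results: Mapping[tuple[str, str], TestResult], path: str | Path, header_comment: str = ""
) -> None:
    """Write test results as TSV: group_a, group_b, n, p, Z, r, method."""
    with Path(path).open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("group_a\tgroup_b\tn_total\tp_value\tz_statistic\teffect_size_r\tmethod\n")
        for (a, b), t in results.items():
            fh.write(f"{a}\t{b}\t{t.n_total}\t{t.p_value:.6g}\t{t.z_statistic:.6g}\t"
                     f"{t.effect_size_r:.6g}\t{t.method}\n")
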