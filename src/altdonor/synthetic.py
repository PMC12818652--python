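"""Synthetic cohorts, expression matrices, junction files and sequences.

The generator emulates the statistical structure the analysis assumes so
every stage can be exercised end to end without downloads:

* per-tissue binomial inclusion/exclusion junction counts, with CNS tissues
  given inclusion probabilities above 0.5 and other tissues below 0.5
  (the CNS-shifted in-ex distributions seen in real body-map cohorts);
* negative-binomial junction depth (uneven RNA-seq coverage; Poisson in the
  dispersion -> infinity limit);
* target-gene TPM per sample and a gene panel whose expression follows a
  linear model in the realized in-ex ratio, giving genes with a specified
  correlation sign and strength;
* nucleotide sequences with planted YCAY clusters and GU runs on a
  background that is YCAY-free and GU-run-free by construction, together
  with a truth table of expected scores derived directly from the pattern
  table (independently of the scanner).

All randomness flows from ``SimConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import SampleRecord
from .enrichment import GeneSetCollection, write_gmt
from .junctions import SpliceSiteSpec, gnnk_event

__all__ = [
    "TissueSpec",
    "GeneSpec",
    "PlannedElement",
    "SequencePlan",
    "SimConfig",
    "default_config",
    "expected_cluster_score",
    "simulate_cohort",
    "write_sj_files",
    "simulate_expression",
    "simulate_sequences",
    "cns_gene_set",
    "write_simulation",
]


@dataclass(frozen=True)
class TissueSpec:
    """One simulated tissue: sample count and inclusion probability."""

    name: str
    n_samples: int
    inclusion_prob: float
    is_cns: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.inclusion_prob <= 1.0:
            raise ValueError(f"inclusion_prob must be in [0, 1], got {self.inclusion_prob}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class GeneSpec:
    """Linear expression model: TPM = baseline + slope * inex + N(0, noise_sd)."""

    gene_id: str
    baseline: float
    slope: float
    noise_sd: float


@dataclass(frozen=True)
class PlannedElement:
    """A planted sequence element.

    ``kind`` is ``"cluster"`` (YCAY motifs joined by poly-A gaps of the given
    lengths) or ``"gu_run"`` (a GU repeat of ``length`` nt).
    """

    kind: str
    start: int
    gaps: tuple[int, ...] = ()
    length: int = 0

    def span(self) -> int:
        if self.kind == "cluster":
            return 4 * (len(self.gaps) + 1) + sum(self.gaps)
        return self.length


@dataclass(frozen=True)
class SequencePlan:
    sequence_id: str
    length: int
    elements: tuple[PlannedElement, ...] = ()


def _default_panel() -> list[GeneSpec]:
    panel = []
    for i in range(30):
        panel.append(GeneSpec(f"CNSLIKE_{i:03d}", baseline=20.0, slope=15.0, noise_sd=4.0))
    for i in range(30):
        panel.append(GeneSpec(f"ANTICNS_{i:03d}", baseline=20.0, slope=-15.0, noise_sd=4.0))
    for i in range(140):
        panel.append(GeneSpec(f"NULL_{i:03d}", baseline=20.0, slope=0.0, noise_sd=5.0))
    return panel


def _default_tissues() -> list[TissueSpec]:
    # CNS inclusion probability 0.7 vs 0.2 elsewhere, 50 samples per class
    return [
        TissueSpec("brain", 25, 0.7, True),
        TissueSpec("spinal cord", 25, 0.7, True),
        TissueSpec("heart", 10, 0.2, False),
        TissueSpec("liver", 10, 0.2, False),
        TissueSpec("lung", 10, 0.2, False),
        TissueSpec("kidney", 10, 0.2, False),
        TissueSpec("muscle", 10, 0.2, False),
    ]


def _default_plans() -> tuple[SequencePlan, ...]:
    return (
        SequencePlan(
            "planted_clusters",
            300,
            (
                PlannedElement("cluster", 40, gaps=(2, 2)),   # tight triple -> 8
                PlannedElement("cluster", 120, gaps=(4, 2)),  # mixed triple -> 4
                PlannedElement("cluster", 200, gaps=(1,)),    # tight pair   -> 2
                PlannedElement("gu_run", 260, length=6),
            ),
        ),
        SequencePlan("background_only", 120),
    )


@dataclass
class SimConfig:
    """Full description of one simulation run (all randomness from ``seed``)."""

    seed: int = 0
    tissues: list[TissueSpec] = field(default_factory=_default_tissues)
    depth_mean: float = 100.0
    depth_dispersion: float | None = 5.0  # None -> Poisson depth
    tpm_mean: float = 30.0
    tpm_sd: float = 10.0
    gene_panel: list[GeneSpec] = field(default_factory=_default_panel)
    n_decoy_junctions: int = 2
    sequence_plans: tuple[SequencePlan, ...] = field(default_factory=_default_plans)

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")


def default_config(seed: int = 0) -> SimConfig:
    """The stock study-like configuration (CNS-shifted inclusion)."""
    return SimConfig(seed=seed)


# ---------------------------------------------------------------------------
# cohort + junction files


def _draw_depth(rng: np.random.Generator, config: SimConfig, size: int) -> np.ndarray:
    if config.depth_dispersion is None or not np.isfinite(config.depth_dispersion):
        return rng.poisson(config.depth_mean, size=size)
    k = config.depth_dispersion
    p = k / (k + config.depth_mean)
    return rng.negative_binomial(k, p, size=size)


def simulate_cohort(config: SimConfig) -> list[SampleRecord]:
    """Draw per-sample junction counts and target-gene TPM.

    For each sample of tissue t the total junction depth n_i follows the
    configured (negative-binomial) depth distribution, inclusion reads are
    Binomial(n_i, p_t) and exclusion reads the remainder; TPM is normal
    (clipped at 0).
    """
    rng = np.random.default_rng(config.seed)
    records: list[SampleRecord] = []
    for tissue in config.tissues:
        depths = _draw_depth(rng, config, tissue.n_samples)
        incs = rng.binomial(depths, tissue.inclusion_prob)
        tpms = np.clip(rng.normal(config.tpm_mean, config.tpm_sd, size=tissue.n_samples), 0.0, None)
        for i in range(tissue.n_samples):
            records.append(
                SampleRecord(
                    sample_id=f"{tissue.name.replace(' ', '_')}_{i:03d}",
                    tissue_type=tissue.name,
                    tissue_category=tissue.name,
                    is_cns=tissue.is_cns,
                    inclusion_reads=int(incs[i]),
                    exclusion_reads=int(depths[i] - incs[i]),
                    gene_tpm=float(tpms[i]),
                )
            )
    return records


def write_sj_files(
    records: Sequence[SampleRecord],
    out_dir: str | Path,
    spec: SpliceSiteSpec | None = None,
    n_decoys: int = 2,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one STAR-style ``SJ.out.tab`` per sample.

    Each file holds the exclusion (SDS1->SAS) and inclusion (SDS2->SAS) rows
    for the event plus ``n_decoys`` decoy junctions (an acceptor mismatch on
    the event chromosome and junctions on another chromosome) that must be
    classified OTHER.
    """
    spec = spec or gnnk_event()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    strand_code = "1" if spec.strand == "+" else "2"
    paths: dict[str, Path] = {}
    for rec in records:
        rows = [
            (spec.chrom, spec.sds1, spec.sas, strand_code, "1", "1", rec.exclusion_reads, 0, 30),
            (spec.chrom, spec.sds2, spec.sas, strand_code, "1", "1", rec.inclusion_reads, 0, 30),
        ]
        for d in range(n_decoys):
            if d % 2 == 0:  # acceptor mismatch on the event chromosome
                rows.append((spec.chrom, spec.sds1, spec.sas + 50 + d,
                             strand_code, "1", "0", int(rng.integers(1, 20)), int(rng.integers(0, 5)), 25))
            else:  # different chromosome entirely
                rows.append(("chrDECOY", 1000 + d, 2000 + d, "0", "0", "0",
                             int(rng.integers(1, 20)), int(rng.integers(0, 5)), 25))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        path = out_dir / f"{rec.sample_id}.SJ.out.tab"
        with path.open("w") as fh:
            for row in rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
        paths[rec.sample_id] = path
    return paths


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimConfig,
    cohort: Sequence[SampleRecord],
    clip: bool = True,
) -> pd.DataFrame:
    """Sample x gene TPM matrix following each gene's linear model.

    Uses the *realized* in-ex ratio of each sample (0 substituted, with a
    log, for the rare sample with no junction reads).  Negative draws are
    clipped at 0 unless ``clip`` is False; the clipped count is logged.
    """
    import logging

    logger = logging.getLogger(__name__)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ratios = np.array([r.inex_ratio for r in cohort], dtype=float)
    n_nan = int(np.isnan(ratios).sum())
    if n_nan:
        logger.info("%d sample(s) with undefined ratio; using 0 for expression model", n_nan)
        ratios = np.nan_to_num(ratios, nan=0.0)
    data = {}
    for gene in config.gene_panel:
        noise = rng.normal(0.0, gene.noise_sd, size=len(cohort)) if gene.noise_sd > 0 else 0.0
        vals = gene.baseline + gene.slope * ratios + noise
        data[gene.gene_id] = vals
    df = pd.DataFrame(data, index=[r.sample_id for r in cohort])
    if clip:
        n_clip = int((df.to_numpy() < 0).sum())
        if n_clip:
            logger.info("clipped %d negative TPM draws to 0", n_clip)
        df = df.clip(lower=0.0)
    return df


def cns_gene_set(config: SimConfig, name: str = "CNS_like_up") -> GeneSetCollection:
    """Gene sets derived from the panel: positive-slope genes form the
    CNS-like set (their expression rises with inclusion), negative-slope
    genes its mirror image, plus a null set of zero-slope genes."""
    up = [g.gene_id for g in config.gene_panel if g.slope > 0]
    down = [g.gene_id for g in config.gene_panel if g.slope < 0]
    null = [g.gene_id for g in config.gene_panel if g.slope == 0]
    sets = {name: up}
    if down:
        sets["CNS_like_down"] = down
    if null:
        sets["null_set"] = null[: max(len(up), 20)]
    return GeneSetCollection(sets=sets, descriptions={k: "synthetic panel set" for k in sets})


# ---------------------------------------------------------------------------
# sequences

_PATTERN_TABLE_DOC = """Expected cluster scores come straight from the
pattern table: pairs score 2 (gap <= 2), 1 (gap 3-6) or 0 (gap >= 7);
triples score 8 (both gaps <= 2), 4 (gaps mixed <= 2 / 3-6), and decompose
into scored pairs when a gap of >= 7 separates them."""


def expected_cluster_score(gaps: Sequence[int]) -> int:
    """Expected raw score of an isolated planted cluster, from the table.

    Independent of the scanning implementation: applies the published
    pattern table (and the same leading-pair convention for the unpublished
    (3-6, 3-6) triple) directly to the planted gap layout.
    """
    gaps = list(gaps)
    if not gaps:
        return 0

    def pair(g: int) -> int:
        return 2 if g <= 2 else (1 if g <= 6 else 0)

    if len(gaps) == 1:
        return pair(gaps[0])
    if len(gaps) == 2:
        g1, g2 = gaps
        if g1 >= 7 and g2 >= 7:
            return 0
        if g1 >= 7:
            return pair(g2)
        if g2 >= 7:
            return pair(g1)
        if g1 <= 2 and g2 <= 2:
            return 8
        if (g1 <= 2) != (g2 <= 2):
            return 4
        return 1  # unpublished (3-6, 3-6): leading pair
    raise ValueError("planted clusters hold at most three motifs")


_MOTIF = "UCAU"


def _render_element(el: PlannedElement) -> str:
    if el.kind == "cluster":
        return _MOTIF + "".join("A" * g + _MOTIF for g in el.gaps)
    if el.kind == "gu_run":
        return ("GU" * el.length)[: el.length]
    raise ValueError(f"unknown element kind: {el.kind!r}")


def _background(rng: np.random.Generator, length: int) -> list[str]:
    """Random background free of YCAY and of G/U runs >= 4.

    Drawn from {A, C, G}; each candidate base is rejected if it would
    complete a YCAY (only CCAC is possible without U) or a 4-base G run.
    """
    out: list[str] = []
    while len(out) < length:
        c = "ACG"[int(rng.integers(3))]
        tail = "".join(out[-3:]) + c
        if tail.endswith("CCAC"):
            continue
        if len(tail) >= 4 and set(tail[-4:]) <= {"G", "U"}:
            continue
        out.append(c)
    return out


def simulate_sequences(
    config: SimConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Build FASTA records with planted elements plus a truth table.

    Every planted element is padded with a forced ``AA`` on both sides so no
    spurious YCAY or GU run spans an element/background boundary; elements
    (including that padding) must not overlap.  The truth table lists, per
    element, its coordinates and the expected raw window score
    (:func:`expected_cluster_score`) or run length.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    records: list[tuple[str, str]] = []
    truth_rows = []
    for plan in config.sequence_plans:
        seq = _background(rng, plan.length)
        occupied: list[tuple[int, int]] = []
        for el in sorted(plan.elements, key=lambda e: e.start):
            text = _render_element(el)
            lo, hi = el.start - 2, el.start + len(text) + 2  # include AA padding
            if lo < 0 or hi > plan.length:
                raise ValueError(f"element at {el.start} exceeds sequence bounds")
            for a, b in occupied:
                if lo < b and a < hi:
                    raise ValueError(f"planted elements overlap near position {el.start}")
            occupied.append((lo, hi))
            seq[lo : el.start] = ["A", "A"]
            seq[el.start : el.start + len(text)] = list(text)
            seq[el.start + len(text) : hi] = ["A", "A"]
            truth_rows.append(
                {
                    "sequence_id": plan.sequence_id,
                    "kind": el.kind,
                    "start": el.start,
                    "end": el.start + len(text),
                    "gaps": ",".join(map(str, el.gaps)),
                    "expected_raw_score": expected_cluster_score(el.gaps)
                    if el.kind == "cluster"
                    else 0,
                    "length": len(text),
                }
            )
        records.append((plan.sequence_id, "".join(seq)))
    truth = pd.DataFrame(
        truth_rows,
        columns=["sequence_id", "kind", "start", "end", "gaps", "expected_raw_score", "length"],
    )
    return records, truth


# ---------------------------------------------------------------------------
# one-call simulation run


def write_simulation(config: SimConfig, out_dir: str | Path,
                     spec: SpliceSiteSpec | None = None) -> dict:
    """Run the full generator and write every artifact under ``out_dir``.

    Emits per-sample SJ.out.tab files, a sample metadata TSV, the TPM
    matrix, the panel GMT, a FASTA with planted motifs, its truth table, and
    a manifest JSON tying the run together.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = spec or gnnk_event()
    cohort = simulate_cohort(config)
    sj_paths = write_sj_files(cohort, out_dir / "sj", spec=spec,
                              n_decoys=config.n_decoy_junctions, seed=config.seed)

    meta_path = out_dir / "samples.tsv"
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in cohort],
            "tissue_type": [r.tissue_type for r in cohort],
            "tissue_category": [r.tissue_category for r in cohort],
            "is_cns": [r.is_cns for r in cohort],
            "inclusion_reads": [r.inclusion_reads for r in cohort],
            "exclusion_reads": [r.exclusion_reads for r in cohort],
            "gene_tpm": [r.gene_tpm for r in cohort],
        }
    ).to_csv(meta_path, sep="\t", index=False)

    tpm = simulate_expression(config, cohort)
    tpm_path = out_dir / "tpm.tsv"
    tpm.to_csv(tpm_path, sep="\t", index_label="sample_id")

    gmt_path = out_dir / "panel.gmt"
    write_gmt(cns_gene_set(config), gmt_path)

    seqs, truth = simulate_sequences(config)
    fasta_path = out_dir / "sequences.fasta"
    with fasta_path.open("w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    truth_path = out_dir / "sequence_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "n_samples": len(cohort),
        "tissues": [t.name for t in config.tissues],
        "event": {
            "chrom": spec.chrom,
            "strand": spec.strand,
            "sds1": spec.sds1,
            "sds2": spec.sds2,
            "sas": spec.sas,
            "gene_id": spec.gene_id,
        },
        "files": {
            "samples": meta_path.name,
            "tpm": tpm_path.name,
            "gmt": gmt_path.name,
            "fasta": fasta_path.name,
            "sequence_truth": truth_path.name,
            "sj_dir": "sj",
            "sj_files": {k: str(p.relative_to(out_dir)) for k, p in sorted(sj_paths.items())},
        },
    }
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
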