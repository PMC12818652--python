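"""End-to-end pipeline drivers binding the analysis stages together.

Each ``run_*`` function consumes files, executes one pipeline stage and
writes its outputs with a provenance header (tool version + parameters).
The :class:`PipelineConfig` defaults are the analysis defaults throughout
the package: TPM >= 1 and >= 3 junction reads for the cohort filter, W1
(p = 1) distances with complete linkage, exact Wilcoxon, GSEA set sizes
20-500 with p cutoff 0.01 and seed 1111, a 45-nt motif window advancing 1 nt
and GU runs of >= 4 nt.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from . import cohort as cohort_mod
from . import enrichment as enrich_mod
from . import junctions as junc_mod
from . import motifscan as motif_mod
from .cohort import CohortTable, SampleRecord
from .junctions import SpliceSiteSpec, gnnk_event

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_inex", "run_compare", "run_gsea", "run_motifscan"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their analysis defaults."""

    # event specification; None -> packaged GN[N/S]K fixture
    splice_spec: SpliceSiteSpec | None = None
    count_mode: str = "unique_only"
    # cohort filters
    tpm_min: float = 1.0
    min_junction_reads: int = 3
    # distribution statistics
    wasserstein_p: float = 1.0
    bin_width: float = 0.1
    linkage: str = "complete"
    wilcoxon_mode: str = "auto"
    # GSEA
    gsea_min_size: int = 20
    gsea_max_size: int = 500
    gsea_p_cutoff: float = 0.01
    gsea_n_perm: int = 1000
    gsea_seed: int = 1111
    # motif scanning
    motif_window: int = 45
    motif_step: int = 1
    gu_min_len: int = 4

    def event(self) -> SpliceSiteSpec:
        return self.splice_spec or gnnk_event()

    def provenance(self, stage: str) -> str:
        params = dataclasses.asdict(self)
        params.pop("splice_spec")
        text = ", ".join(f"{k}={v}" for k, v in sorted(params.items()))
        return f"altdonor {__version__} | stage={stage} | {text}"


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Precedence: explicit overrides > file values > defaults.  The YAML file
    is a flat key/value mapping using the :class:`PipelineConfig` field
    names; the splice spec may be given as a ``splice_spec`` mapping with
    keys chrom/strand/sds1/sds2/sas/gene_id.
    """
    values: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key/value mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    if isinstance(values.get("splice_spec"), Mapping):
        values["splice_spec"] = SpliceSiteSpec(**values["splice_spec"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return PipelineConfig(**values)


def run_inex(
    config: PipelineConfig,
    junction_files: Mapping[str, str | Path],
    metadata_path: str | Path,
    out_dir: str | Path,
) -> CohortTable:
    """Count junctions per sample, merge with metadata, filter the cohort.

    ``junction_files`` maps sample ids to SJ.out.tab paths; ``metadata_path``
    is a TSV with sample_id, tissue_type, tissue_category and gene_tpm
    columns (counts, if present, are replaced by the ones computed here).
    Writes per-sample counts, the filtered cohort and a filter report.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = config.event()

    meta = pd.read_csv(metadata_path, sep="\t", comment="#")
    for colname in ("sample_id", "tissue_type", "tissue_category", "gene_tpm"):
        if colname not in meta.columns:
            raise ValueError(f"{metadata_path}: missing required column {colname!r}")
    meta = meta.set_index("sample_id")

    counts = []
    records = []
    for sample_id, path in sorted(junction_files.items()):
        evidence = junc_mod.read_sj_tab(path)
        c = junc_mod.count_sample_junctions(
            evidence, spec, count_mode=config.count_mode, sample_id=sample_id
        )
        counts.append(c)
        if sample_id not in meta.index:
            logger.warning("sample %s has junctions but no metadata — skipped", sample_id)
            continue
        row = meta.loc[sample_id]
        cat = str(row["tissue_category"])
        records.append(
            SampleRecord(
                sample_id=sample_id,
                tissue_type=str(row["tissue_type"]),
                tissue_category=cat,
                is_cns=bool(row["is_cns"]) if "is_cns" in meta.columns
                else cohort_mod.is_cns_category(cat),
                inclusion_reads=c.inclusion_reads,
                exclusion_reads=c.exclusion_reads,
                gene_tpm=float(row["gene_tpm"]),
            )
        )

    junc_mod.write_sample_counts(counts, out_dir / "sample_counts.tsv")
    cohort = cohort_mod.filter_samples(
        records, tpm_min=config.tpm_min, min_junction_reads=config.min_junction_reads
    )
    cohort_mod.write_cohort(cohort, out_dir / "cohort.tsv",
                            header_comment=config.provenance("inex"))

    dropped = [r for r in records if r.sample_id not in {k.sample_id for k in cohort.records}]
    with (out_dir / "filter_report.tsv").open("w") as fh:
        fh.write(f"# {config.provenance('inex')}\n")
        fh.write("sample_id\ttissue_type\tgene_tpm\ttotal_junction_reads\tretained\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.tissue_type}\t{r.gene_tpm:.6g}\t"
                     f"{r.total_junction_reads}\t{r not in dropped}\n")
    logger.info("retained %d / %d samples", len(cohort), len(records))
    return cohort


def run_compare(config: PipelineConfig, cohort: CohortTable, out_dir: str | Path) -> dict:
    """Distance matrix + dendrogram across tissues and the CNS-vs-other test."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dm = cohort_mod.distance_matrix(cohort, p=config.wasserstein_p)
    cohort_mod.write_distance_matrix(dm, out_dir / "distance_matrix.tsv",
                                     header_comment=config.provenance("compare"))
    dendro = cohort_mod.complete_linkage_cluster(dm)
    (out_dir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")

    results = {}
    groups = cohort.groups(by="cns_flag")
    if set(groups) == {"CNS", "other"}:
        test = cohort_mod.wilcoxon_ranksum(groups["CNS"], groups["other"],
                                           mode=config.wilcoxon_mode)
        results[("CNS", "other")] = test
    else:
        raise ValueError("cohort lacks a CNS or a non-CNS group; cannot run the contrast")
    cohort_mod.write_test_results(results, out_dir / "test_results.tsv",
                                  header_comment=config.provenance("compare"))
    return {"distance_matrix": dm, "dendrogram": dendro, "tests": results}


def run_gsea(
    config: PipelineConfig,
    cohort: CohortTable,
    tpm_path: str | Path,
    gmt_path: str | Path,
    out_dir: str | Path,
) -> list:
    """Rank genes by correlation with the in-ex ratio and run pre-ranked GSEA."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0, comment="#")
    inex = pd.Series(
        {r.sample_id: r.inex_ratio for r in cohort.records}, dtype=float
    )
    ranked = enrich_mod.correlate_genes(tpm, inex)
    enrich_mod.write_ranked_list(ranked, out_dir / "ranked_genes.tsv")

    collection = enrich_mod.read_gmt(gmt_path)
    filtered = enrich_mod.filter_gene_sets(
        collection, ranked, min_size=config.gsea_min_size, max_size=config.gsea_max_size
    )
    if not len(filtered):
        raise ValueError(
            f"no gene set has between {config.gsea_min_size} and "
            f"{config.gsea_max_size} members in the ranked universe"
        )
    results = enrich_mod.gsea_preranked(
        ranked,
        filtered,
        n_perm=config.gsea_n_perm,
        seed=config.gsea_seed,
        p_cutoff=config.gsea_p_cutoff,
    )
    enrich_mod.write_enrichment_results(
        results, out_dir / "enrichment.tsv",
        header_comment=config.provenance("gsea") + f" | seed={config.gsea_seed}",
    )
    return results


def run_motifscan(config: PipelineConfig, fasta_path: str | Path, out_dir: str | Path) -> dict:
    """Scan every FASTA record for YCAY clusters and GU-rich stretches.

    Records shorter than the window are skipped with a warning; the others
    are processed.  Writes a per-record score TSV, a combined bedGraph and a
    combined GU-run BED.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tracks = {}
    all_runs = []
    bedgraph = out_dir / "ycay_scores.bedgraph"
    bedgraph.unlink(missing_ok=True)
    first = True
    for name, seq in motif_mod.read_fasta(fasta_path):
        if len(seq) < config.motif_window:
            logger.warning("record %s is shorter than the %d-nt window — skipped",
                           name, config.motif_window)
            continue
        track = motif_mod.scan_sequence(seq, sequence_id=name,
                                        window=config.motif_window, step=config.motif_step)
        tracks[name] = track
        motif_mod.write_track_tsv(track, out_dir / f"{name}.ycay.tsv",
                                  header_comment=config.provenance("motifscan"))
        motif_mod.write_track_bedgraph(track, bedgraph, append=not first)
        first = False
        all_runs.extend(motif_mod.find_gu_runs(seq, min_len=config.gu_min_len, sequence_id=name))
    motif_mod.write_gu_runs_bed(all_runs, out_dir / "gu_runs.bed")
    return {"tracks": tracks, "gu_runs": all_runs}
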