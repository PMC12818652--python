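"""Drive the whole pipeline on a generated study, file-in / file-out.

Writes a synthetic study (SJ.out.tab files, metadata, TPM matrix, GMT,
FASTA) to a scratch directory, then runs every stage the way the CLI does:
inex -> compare -> gsea -> motifscan.
"""

import tempfile
from pathlib import Path

from altdonor.pipeline import PipelineConfig, run_compare, run_gsea, run_inex, run_motifscan
from altdonor.synthetic import default_config, write_simulation

workdir = Path(tempfile.mkdtemp(prefix="altdonor_demo_"))
manifest = write_simulation(default_config(seed=1), workdir / "study")
print(f"simulated {manifest['n_samples']} samples in {workdir / 'study'}")

config = PipelineConfig()
sj_files = {k: workdir / "study" / v for k, v in manifest["files"]["sj_files"].items()}
cohort = run_inex(config, sj_files, workdir / "study" / "samples.tsv", workdir / "inex")
print(f"retained {len(cohort)} samples after filters "
      f"(TPM >= {config.tpm_min}, >= {config.min_junction_reads} junction reads)")

out = run_compare(config, cohort, workdir / "compare")
test = out["tests"][("CNS", "other")]
print(f"CNS vs other Wilcoxon: p={test.p_value:.3g}, r={test.effect_size_r:.3f}")

results = run_gsea(config, cohort, workdir / "study" / "tpm.tsv",
                   workdir / "study" / "panel.gmt", workdir / "gsea")
for r in results:
    print(f"GSEA {r.set_name}: NES={r.nes:+.2f}, adjusted p={r.p_adjusted:.3g}")

scan = run_motifscan(config, workdir / "study" / "sequences.fasta", workdir / "motifs")
track = scan["tracks"]["planted_clusters"]
print(f"motif scan: max log10 YCAY score {track.max_log_score():.3f}, "
      f"{len(scan['gu_runs'])} GU run(s)")
print(f"all outputs under {workdir}")
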