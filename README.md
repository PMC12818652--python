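# altdonor

Quantification and comparison of **alternative 5′ splice-donor usage** from
RNA-seq splice-junction evidence, built around two-donor/one-acceptor events
such as the *KIT* GN[N/S]K event: two GU donor sites 12 nt apart feed a single
acceptor, so donor choice toggles a four-codon (Gly-Asn-[Asn/Ser]-Lys)
segment of the receptor's juxtamembrane region. The package is for
transcriptomics researchers who already have aligner junction output (STAR
`SJ.out.tab`) and expression tables and want to measure, per sample and per
tissue, which donor is used and what co-varies with that choice.

## What it computes

**In-ex ratio.** For an event with upstream donor SDS1 (exclusion),
downstream donor SDS2 (inclusion) and shared acceptor SAS, junction-spanning
reads are classified by their intron boundaries and summarized per sample as

```
in-ex ratio = ([SDS2&SAS] − [SDS1&SAS]) / ([SDS2&SAS] + [SDS1&SAS])
```

ranging from −1 (all exclusion, GN[N/S]K−) to +1 (all inclusion, GN[N/S]K+),
undefined when a sample has no junction reads.

**Cohort statistics.** Samples are filtered (target-gene TPM ≥ 1 and ≥ 3
junction-spanning reads, both inclusive), then tissue-level ratio
distributions are compared with the exact 1-D Wasserstein distance
W₁ (quantile-function merge, p = 1 by default), complete-linkage hierarchical
clustering of the distance matrix, and the exact Wilcoxon rank-sum test
(shift algorithm over doubled midranks, so ties are handled) with the rank
effect size r = |Z|/√N.

**Correlation-ranked GSEA.** Genes are ranked by the Pearson correlation of
their TPM with the in-ex ratio across samples; pre-ranked GSEA (weighted
Kolmogorov–Smirnov running sum, gene-label permutations, same-sign NES
normalization, BH adjustment) is run with set sizes 20–500, p cutoff 0.01
and a fixed permutation seed.

**Motif scanning.** NOVA-binding YCAY clusters are scored in a 45-nt window
sliding 1 nt at a time: motif pairs/triples score 0/1/2/4/8 by their gap
structure, summed per window and log₁₀-transformed (≥ 0.6 marks a conserved
triple-motif cluster). Maximal GU-rich stretches (≥ 4 consecutive G/U, the
HNRNPM-recognized element) are reported separately.

**Synthetic data.** A first-class generator produces cohorts with
CNS-shifted inclusion probabilities (binomial counts over negative-binomial
depth), expression panels with planted correlation structure, per-sample
`SJ.out.tab` files and FASTA sequences with planted YCAY clusters and GU
runs plus machine-readable truth tables — everything the test suite and the
examples run on.

## Worked example

```python
from altdonor import distance_matrix, filter_samples, wilcoxon_ranksum, complete_linkage_cluster
from altdonor.synthetic import default_config, simulate_cohort

cohort = filter_samples(simulate_cohort(default_config(seed=1)))
res = wilcoxon_ranksum(cohort.ratios(cns=True), cohort.ratios(cns=False))
print(len(cohort), res.p_value, res.effect_size_r)
```

prints (see `examples/02_tissue_stats.py` for the full script):

```
cohort: 99 samples, 7 tissue types
CNS vs other: p=3.96e-29, Z=8.57, r=0.862 (N=99)
```

99 of 100 simulated samples pass the filters; the exact Wilcoxon contrast of
CNS versus other tissues yields effect size r = 0.862 — the simulated CNS
inclusion shift (inclusion probability 0.7 versus 0.2) is recovered as a
strong rank effect. The dendrogram from the same script puts the two CNS
tissues on their own first branch, and `examples/03_gsea.py` recovers the
planted CNS-like gene set with NES = +2.48 at adjusted p = 0.0015.

The other examples cover junction classification (`01`), motif scanning
(`04`) and the file-in/file-out pipeline (`05`). A thin CLI mirrors the
pipeline stages:

```bash
altdonor simulate --out-dir study --seed 1
altdonor inex --sj-dir study/sj --metadata study/samples.tsv --out-dir out
altdonor compare --cohort out/cohort.tsv --out-dir out
altdonor gsea --cohort out/cohort.tsv --tpm study/tpm.tsv --gmt study/panel.gmt --out-dir out
altdonor motifscan --fasta study/sequences.fasta --out-dir out
```

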