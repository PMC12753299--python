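# microdepth

Uneven sequencing (coverage) depth biases metagenome-based estimates of
**intraspecies diversity**. The two workhorse metrics — nucleotide diversity

> π = 1 − [(freq A)² + (freq C)² + (freq G)² + (freq T)²], averaged over
> reference sites with depth ≥ min_cov

and **ANIr** (the mean alignment identity of reads recruited to a reference
genome or MAG, in percent) — react very differently when the same community
is sequenced more or less deeply: π is systematically *under*estimated at
low depth (rare alleles are missed, and the plugin estimator carries an
inherent (n−1)/n bias at depth n), and the bias persists well above the
commonly used 10X threshold, while ANIr is nearly insensitive to depth.

`microdepth` is a tested Python package plus analysis scripts for studying
this, aimed at microbial ecologists and method developers who compare
microdiversity across samples. It provides:

- **`microdepth.synthgen`** — simulate strain-mixture metagenomes with full
  ground truth: an ancestor genome, strains derived by point substitutions
  (pairwise ANI ≥ 95%), log-normal abundances, and reads carrying
  insertion/deletion/mismatch errors from five-parameter profiles
  (error-free, Q20 ≈ 1 error/1,000 bp, Q30 ≈ 1 error/10,000 bp). Emits
  FASTQ, a truth SAM against the ancestor (CIGAR + NM) and a truth table.
- **`microdepth.recruit`** — ingest SAM/BAM, compute per-read gap-columns
  identity, apply the recruitment contract (identity ≥ 0.95 inclusive,
  non-discordant pairing, best match per read), build A/C/G/T pileups.
- **`microdepth.profile`** — per-site and genome-wide π (min_cov 5), ANIr,
  mean depth and breadth.
- **`microdepth.rarefy`** — exact without-replacement subsampling on a
  fraction grid or to fixed target depths; diversity ratios
  (subsample/full) and average absolute relative errors per depth bin.
- **`microdepth.experiment`** — the full strain-counts × error-profiles
  design, observed-π tables for externally mapped samples, TSV + manifest
  reporting. Everything is byte-deterministic under one master seed.

## Worked example

```python
import numpy as np
import microdepth as m

anc = m.generate_ancestor(100_000, 0.5, seed=11)
sset = m.derive_strain_set(anc, 100, (0.0, 0.0249), seed=12)   # ANI >= 95%
ab = m.sample_lognormal_abundances(100, 1.0, seed=13)
sim = m.simulate_metagenome(sset, ab, n_reads=666_667, read_length=150,
                            error_profile=m.Q30, seed=14,
                            out_prefix="scratch/deep")          # ~1000X
reads = m.apply_filters(m.load_alignments(sim.sam, anc))
full = m.profile_genome(reads, anc)
print(full.pi, full.anir, full.mean_depth)

sub, achieved = m.rarefy_to_depth(reads, 55.0, anc.length, seed=100)
print(m.diversity_ratio(m.profile_genome(sub, anc).pi, full.pi))
```

Output from this exact run:

```
0.026432069454119446 98.62151163494836 991.14134
0.9839646907608538
```

Reading: the 100-strain community at ~991X has genome-wide π ≈ 0.0264 and
ANIr ≈ 98.6%. Rarefied to 55X, the recomputed π is only ~98.4% of the
full-depth value — the π diversity ratio is below 1 even though 55X is far
above the 10X rule of thumb, while ANIr moves by thousandths of a percent.
A truly clonal, error-free simulation gives π exactly 0 and ANIr exactly
100%; with Q20/Q30 errors and no biological variation, ANIr drops to ~99.2%
/ ~99.9% and π inflates to ~0.012 / ~0.0012 — sequencing error alone
mimics microdiversity.

The same functionality is exposed on the command line:

```bash
microdepth simulate --genome-length 100000 --n-strains 100 \
    --error-profile q30 --n-reads 100000 --seed 1 --out-prefix sim/deep
microdepth profile --sam sim/deep.sam --ref sim/deep.ref.fasta
microdepth rarefy  --sam sim/deep.sam --ref sim/deep.ref.fasta \
    --fractions 0.01,0.05,0.1,0.5,0.9 --replicates 3 --seed 2 --out rar.tsv
microdepth experiment --config config.yaml --out-dir runs/
```

## Analysis scripts

Numbered drivers under `analysis/` reproduce the study's in silico
analyses at desk scale and write tables under `results/`:

1. `01_clonal_error_profiles.py` — clonal baseline under the three error
   profiles (`results/clonal_profiles.tsv`).
2. `02_rarefaction_bias.py` — 100-strain Q30 metagenome at ~600X subsampled
   on the 1–90% grid; diversity ratios and per-depth-bin error summaries
   (`results/rarefaction_points.tsv`, `results/rarefaction_error_summary.tsv`).
3. `03_full_design.py` — the 12-metagenome design grid
   (`results/full_design/`).

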