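# popscan

Windowed population-genomic scans from VCF genotypes, with a built-in
forward-in-time Wright–Fisher simulator so that every estimator ships with a
recovery test against known truth.

The pipeline mirrors a domestication-genomics analysis:

- **Site filtering** — keep biallelic SNPs with QUAL > 30, missing rate < 0.25,
  and MAF > 0.05 (all strict, applied in that order with per-rule accounting).
- **Windowed diversity** — θπ, Watterson's θw, Tajima's *D*, and SNP density in
  10 kb windows with a 5 kb step.
- **Selective-sweep scan** — Weir–Cockerham FST (ratio-of-sums) and ROD
  (1 − π_dom/π_wild) in 100 kb / 10 kb windows; sweep regions are windows with
  FST > 0.15 that sit in the top decile of FST and have ROD > 0.2, merged when
  overlapping or book-ended, and annotated with overlapping genes (BED/GFF3).
- **LD decay** — pairwise genotype r², distance-binned decay curves up to
  200 kb, and the half-decay distance (50 % of the maximum bin mean, linearly
  interpolated).
- **Gene flow** — the four-population ABBA-BABA D statistic on group allele
  frequencies with a delete-one block-jackknife Z score (|Z| > 3 significant),
  plus Wright's Nm = (1 − FST)/(4·FST).
- **Phylogeny** — diploid p-distances and Saitou–Nei neighbour joining
  (Studier–Keppler update), with outgroup rooting and newick output.
- **Simulator** — multi-deme diploid Wright–Fisher with migration,
  recombination, infinite-sites mutation, deme splits, bottlenecks, admixture
  pulses, and post-hoc sweep injection; fixed seed ⇒ byte-identical output.

## Command line

```bash
# simulate a small dataset
popscan simulate --length 200000 --deme wild:50 --deme dom:50 \
    --sample-size 20 --seed 1 --out-prefix sim

# individual stages
popscan filter --vcf sim.vcf --out filtered.vcf
popscan diversity --vcf filtered.vcf --popmap sim.popmap.tsv --group wild --out div.tsv
popscan scan --vcf filtered.vcf --popmap sim.popmap.tsv --wild wild --dom dom --out-prefix scan
popscan ld --vcf filtered.vcf --popmap sim.popmap.tsv --group wild --out-prefix ld
popscan dstat --vcf filtered.vcf --popmap quartet.tsv --quartet W,X,Y,Z
popscan tree --vcf filtered.vcf --outgroup wild_0 --out tree.nwk

# or everything from a YAML config
popscan all --config run.yaml
```

A minimal `run.yaml`:

```yaml
vcf: sim.vcf
popmap: sim.popmap.tsv
annotation: genes.bed      # optional
wild: [wild]
dom: [dom]
quartets: [[W, X, Y, Z]]   # optional; Z is the outgroup
outgroup: wild_0           # optional, roots the NJ tree
seed: 1
outdir: results
```

All thresholds (qual/MR/MAF, window sizes, FST/ROD cutoffs, LD range) default
to the analysis values above and can be overridden in the config. Each run
writes `manifest.json` with the effective configuration and a hash that is
stamped into every TSV output; identical config + seed reproduces outputs
byte-for-byte. Exit codes: 0 ok, 2 config error, 3 data error.

## Layout

```
src/popscan/
  genotype_io.py    VCF/popmap I/O, site filters, allele frequencies
  simulate.py       Wright–Fisher simulator + sweep injection
  diversity.py      windowed θπ / θw / Tajima's D
  selection_scan.py WC84 FST, ROD, sweep caller, gene annotation
  ld_decay.py       r², decay curves, half-decay distance
  gene_flow.py      D statistic, block jackknife, Wright's Nm
  phylo.py          p-distance, neighbour joining, rooting
  pipeline_cli.py   click CLI (`popscan`)
  calibration.py    seeded validation experiments (shared with acceptance)
  reference.py      brute-force reference implementations (oracles)
```
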