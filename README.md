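# scmito — mitochondrial genomes from single cells

Single-cell whole-genome sequencing always requires amplification (MDA,
eWGA, DOP-PCR, MALBAC), and scATAC-seq libraries carry mtDNA as a byproduct.
Either way, the reads contain enough of the 16.5 kb circular mitochondrial
genome to reconstruct it per cell — if one can (i) separate genuine mtDNA
reads from NUMTs (near-identical nuclear copies of mtDNA), (ii) call
variants with their heteroplasmy fraction under sensible quality/depth
filters, and (iii) quantify how badly each amplification protocol distorted
the coverage. `scmito` implements that reconstruction-and-evaluation
pipeline as a library, a CLI, and a set of analysis drivers, together with a
synthetic-data generator that emulates the protocols' coverage biases so
every stage can be tested against known truth.

For whom: people building or evaluating single-cell mtDNA genotyping /
lineage-tracing workflows who want a fully self-contained, truth-aware
testbed rather than a wrapper around external aligner binaries.

## The methods in brief

* **NUMT filter.** Reads are aligned (seed-and-extend, affine-gap local
  scoring: match +1, mismatch −1, gap open −2, extend −1) against the
  circular mtDNA *and* nuclear decoy contigs in one index; a read is kept
  only when its mtDNA score is **strictly** greater than its best nuclear
  score — equal scores are the NUMT signature and are discarded.
* **Variant calling.** A pileup restricted to bases with Q ≥ 30 after PCR-
  duplicate removal; an allele becomes a call when its supporting depth is
  ≥ 5; indels must sit ≥ 5 bp from a read end; the heteroplasmy fraction is
  AF = supporting / filtered depth. The consensus writes an alternate only
  at AF ≥ 0.8 and splits into contigs wherever filtered depth drops below 5.
* **Haplogroup score.** Against a Phylotree-style table, each haplogroup Hg
  is scored by `P_Hg = Nph / Nph_exp`: observed haplogroup-defining SNPs over
  the defining SNPs whose positions are actually callable in this genome.
  Genomes with < 10% callable breadth are reported unresolved.
* **Coverage uniformity.** Lorenz curve of per-base depth (cumulative
  fraction of genome positions vs cumulative fraction of sequenced bases)
  and its Gini coefficient, `G = 1 − 2·AUC`; 0 is perfectly uniform.
* **Concordance.** Pairwise replicate comparison under AF × depth thresholds
  (All / Common / %Common / bulk-Confirmed), replicate-based precision
  (PPV = shared calls / a cell's calls), Pearson correlation of shared AFs,
  threshold sweeps (AF 1–10%, depth 10–1000), and variant-by-cell tables
  with homoplasmic (AF > 0.95) vs heteroplasmic splits.

## Worked example

```python
from scmito import datasets, simulate as sim
from scmito.align import AlignmentIndex
from scmito.pipeline import reconstruct_cell

ref = datasets.load_reference()          # packaged 16,569 bp synthetic genome
tree = datasets.load_tree()              # toy haplogroup table

# a cell of haplogroup K1a with one 30% heteroplasmy at position 5000
alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref.base(5000)]
geno = sim.CellGenotype(
    "cell1",
    haplogroup="K1a",
    heteroplasmic=frozenset({(5000, ref.base(5000), alt, 0.30)}),
)
hap = sim.apply_genotype(ref, tree, geno)
reads = sim.generate_reads(hap, sim.get_protocol("MDA"), target_depth=100, seed=42)

res = reconstruct_cell(reads, AlignmentIndex(ref, []), ref, "cell1", tree=tree)
print("assembly:", res.consensus.stats())
top = res.predictions[0]
print(f"haplogroup: {top.haplogroup}  P_Hg={top.p_hg:.2f} ({top.nph}/{top.nph_exp})")
for c in res.calls:
    if c.af < 0.95:
        print(f"heteroplasmy: m.{c.pos}{c.ref}>{c.alt}  AF={c.af:.3f}  depth={c.total}")
```

prints

```
assembly: {'breadth_pct': 99.34, 'mean_depth': 62.88, 'n_contigs': 66}
haplogroup: K1a  P_Hg=1.00 (11/11)
heteroplasmy: m.5000A>C  AF=0.387  depth=31
```

The MDA-style lognormal amplification field leaves 99.3% of the genome
callable but fragments it into contigs where the bias dips below 5×; the
haplogroup comes back with a perfect reliability score (all 11 defining
SNPs observed among the 11 callable); the injected 30% heteroplasmy is
recovered at AF 0.39 — within binomial sampling error of truth at the 31
quality-filtered reads covering that site.

The same stages are available from the shell:

```bash
scmito simulate --protocol MDA --cells 5 --depth 100 --seed 42 --outdir work
scmito align --ref work/mt.fa --decoys work/decoys.fa --reads work/cell1.fastq --out work/cell1.sam
scmito call --sam work/cell1.sam --ref work/mt.fa --sample cell1 --outdir work
scmito haplo --vcf work/cell1.vcf --bed work/cell1.bed --tree work/toytree.tsv
scmito qc --sam work/cell1.sam
scmito compare --a work/cell1.vcf --b work/cell2.vcf --af 0.03 --depth 50
```

## Analysis drivers

The numbered scripts under `analysis/` run the individual studies and write
their tables to `results/` (pass a seed as the single argument):

1. `01_protocol_coverage_uniformity.py` — Gini per protocol, Lorenz curves
2. `02_haplogroup_recovery.py` — per-leaf classification at 50×
3. `03_heteroplasmy_recovery.py` — AF accuracy at ~1000×
4. `04_numt_filter.py` — filter operating characteristics vs divergence
5. `05_replicate_concordance.py` — 500× replicates and the threshold sweep
6. `06_published_table_summaries.py` — statistics of the packaged tables

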