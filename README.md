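# ucekit

A toolkit for designing and optimizing ultraconserved-element (UCE) capture
probe sets across a suite of genome assemblies, and for evaluating the
resulting probe sets by in silico capture.

The pipeline mirrors the standard UCE probe-design workflow:

1. pick a **base genome** and take read-mapping intervals of every other
   taxon against it (BED, or SAM reduced to intervals);
2. detect **putative loci** — merged conserved regions shared by the base
   and at least *k* other taxa (the `+k` sharing stringency);
3. tile **temporary baits** (120-mers at 60 bp offset by default) over the
   putative loci and filter them on GC / ambiguity / masking;
4. align baits back to every assembly with the built-in seeded
   Smith-Waterman engine and keep **candidate loci** whose baits match
   uniquely (no paralog-like duplicates) in the required number of taxa;
5. emit per-taxon customized **final probes**;
6. run an **in silico capture test**, extract loci with flanks, and build
   recovery matrices.

On top of the single pass it provides the two optimization experiments —
a base-genome sweep and a bait-design stringency sweep — plus cross-design
comparison (good / problematic-within / problematic-between locus
classification), final optimized-subset construction with legacy probe-set
merging, probe physical QC (GC, melting temperature, linguistic
complexity), assembly metrics (N50/L50/N90/L90, GC%, per-locus depth), and
genetic-distance base-genome ranking (p, JC69, TN93 distances, neighbor
joining, patristic distances).

A synthetic-suite generator (`ucekit.synthetic_suite`) builds multi-taxon
genomes with planted conserved cores, divergence gradients, paralog copies,
repeats and presence/absence structure, together with a ground-truth
registry, so the whole pipeline is exercisable and testable without any
downloads.

## CLI

Everything is under a single `ucekit` entry point (`ucekit --help`):

```sh
# generate a synthetic suite (FASTA + BED + truth registry)
ucekit synth --config suite.yaml --out suite/

# single design pass, step by step
ucekit baits --base suite/t1.fasta --bed t2=suite/t2.bed --bed t3=suite/t3.bed \
             -k 1 --out baits.fasta
ucekit probes --baits baits.fasta --assembly suite/t1.fasta \
              --assembly suite/t2.fasta --assembly suite/t3.fasta --out probes.fasta
ucekit insilico --probes probes.fasta --assembly suite/t1.fasta \
                --assembly suite/t2.fasta --assembly suite/t3.fasta --out-dir insilico/

# experiments and reporting
ucekit sweep-stringency --suite suite/ --base t1
ucekit sweep-base --suite suite/ -k 1
ucekit compare --monolithic A=a/monolithic.fasta --monolithic B=b/monolithic.fasta --out cls.tsv
ucekit finalize --probes probes.fasta --good-loci good.txt --legacy legacy.fasta --out final.fasta

# utilities
ucekit metrics suite/*.fasta
ucekit qc final.fasta
ucekit distance markers/*.fasta --method TN93
ucekit rank-base markers/*.fasta
ucekit recommend --marker markers/m1.fasta --marker markers/m2.fasta
ucekit convert aln.sam aln.bed
ucekit validate suite/t1.fasta suite/t2.bed
```

Example `suite.yaml`:

```yaml
taxa: [t1, t2, t3, t4, t5, t6, t7]
genome_length: 1000000
n_loci: 300
core_length: 300
flank_length: 400
divergence: 0.025
seed: 1
```

## Layout

| module | contents |
| --- | --- |
| `ucekit.seq_formats` | FASTA/BED/SAM I/O, probe & monolithic header grammar |
| `ucekit.assembly_metrics` | N50/L50/N90/L90, GC%, per-locus depth |
| `ucekit.conservation` | interval algebra, putative-locus detection |
| `ucekit.local_align` | seeded local alignment engine + Smith-Waterman oracle |
| `ucekit.bait_design` | bait tiling/filtering, candidate loci, final probes |
| `ucekit.insilico_capture` | in silico capture test, recovery matrices |
| `ucekit.design_compare` | cross-design matching, good/problematic labels, final subset |
| `ucekit.probe_qc` | GC / Tm / linguistic-complexity QC |
| `ucekit.genetic_distance` | p / JC69 / TN93, neighbor joining, taxon ranking |
| `ucekit.synthetic_suite` | synthetic genome suites with truth registry |
| `ucekit.cli_harness` | pipeline orchestration, sweeps, recommendation |
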