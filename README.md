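# igdiv

Analysis toolkit for Ig gene diversification experiments in DT40-style
B-cell lines: clonally corrected SHM/GCV mutation-event calling,
gene-conversion tract classification against a pseudo-V donor repertoire,
bisulfite single-stranded-DNA patch detection, ChIP-seq elongation-index and
metagene analysis, and GFP-loss fluctuation statistics — with a
synthetic-data generator that plants known ground truth for every input.

It is written for researchers quantifying antibody diversification:
activation-induced cytosine deaminase (AID) deaminates C→U on
single-stranded DNA of transcribed Ig loci, producing untemplated point
mutations (somatic hypermutation, SHM) and, in chicken IgL, templated
copying from ~25 upstream pseudo-V donor genes (gene conversion, GCV).
The bespoke computations these experiments need — clonal correction,
exact-match tract attribution, conversion-run calling, pausing/elongation
ratios — live here as a tested library.

## The core quantities

**Mutation-event frequency.** Sequences of each subclone are aligned to the
reference; a mutation seen in more than one sequence of a subclone at an
identical position is counted once (clonal correction). The frequency is

&nbsp;&nbsp;&nbsp;&nbsp;f = (counted events) / (total bp sequenced)

**Gene-conversion classification.** A group of substitutions is one GCV
event only if the mutated stretch exactly matches at least one pseudo-V
donor over a maximal interval carrying ≥ 2 donor-vs-locus differences; a
single donor-matching change is *ambiguous*; the rest are point mutations.

**% ssDNA patches.** In bisulfite-treated DNA, a patch is a run of ≥ 2
successive C→T (top strand) or G→A (bottom strand) transitions, bounded by
the nearest unconverted C/G on each side; the statistic is
100 × patches / bp sequenced.

**Elongation index.** For a coverage track in reads per million (RPM),

&nbsp;&nbsp;&nbsp;&nbsp;EI = density(gene body) / density(promoter-proximal), both in RPM/kb

with proximal = TSS ± 100 bp and body = +101 … end for a short reporter
cassette, and proximal = (−100)–(+300), body = +300 … TTS for annotated
genes. Metagene profiles bin each gene (−100 bp of TSS to TTS) into 100
bins of reads/bp, scale each gene's vector to max 1, and average.

**Fluctuation assay.** Per-subclone GFP-negative percentages (values > 50%
excluded) are summarized by medians and median-ratio fold stimulations,
compared by Mann-Whitney; mutation frequencies by a pooled two-proportion
z-test; expression and genome-wide index data by one-/two-tailed t tests.

## Worked example

Generate all synthetic inputs and run the analyses (each step is a thin
driver over the library; tables land under `results/`):

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_mutation_frequencies.py
python analysis/03_bisulfite_patches.py
python analysis/04_chip_elongation.py
python analysis/05_gfp_fluctuation.py
```

Step 02 prints (seed 1):

```
wt: 142 events / 200000 bp = 7.10 per 10^4 bp; spectrum {'point_mutation': 52, 'gene_conversion': 55, 'ambiguous': 35, 'insertion': 0, 'deletion': 0}
bcl6_null: 24 events / 200000 bp = 1.20 per 10^4 bp; spectrum {'point_mutation': 13, 'gene_conversion': 0, 'ambiguous': 11, 'insertion': 0, 'deletion': 0}
fold wt/bcl6_null = 5.92; z = 9.16, p = 5.17e-20 ***
```

The diversifying line mutates ~6× above the deficient line's background
(planted: 6.5×), with a spectrum mixing point mutations, donor-templated
conversions, and ambiguous single-marker changes; the deficient line shows
no conversions. Step 04 prints the planted elongation-index contrast:

```
wt: proximal 101.1 RPM/kb, body 109.5 RPM/kb, index 1.0825
bcl6_null: proximal 100.9 RPM/kb, body 5.0 RPM/kb, index 0.0498
bcl6_recon: proximal 100.3 RPM/kb, body 27.2 RPM/kb, index 0.2709
fold wt/null = 21.7; fold recon/null = 5.44
```

i.e. a factor that stays with elongating polymerase through the gene body
(EI ≈ 1.1), its ~22-fold collapse toward promoter-restricted binding
(EI ≈ 0.05), and a partial 5.4× restoration. Step 05 recovers the planted
fluctuation folds (9× and 30× DIVAC stimulation of median GFP loss,
Mann-Whitney *** on 10 subclones per arm).

The same operations are scriptable via the CLI, e.g.:

```sh
igdiv simulate clones --seed 7 --out-dir sim/
igdiv mutations classify --clones sim/clones.fasta --locus sim/locus.fasta \
    --donors sim/donors.fasta --out-dir events/
igdiv stats ztest --events1 142 --n1 200000 --events2 24 --n2 200000
```

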