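# sortscreen

Deconvolution of pooled yeast surface-display screens from long-read
amplicon sequencing.

## The problem

A combinatorial surface-display library crosses 20 promoters with 4
secretion signal peptides (SPs) in front of a cargo protein — 80 genotypes
per cargo, built on a Golden Gate modular-cloning grammar (promoter =
slot 2, SP = 3a, CDS = 3b, CBM fusion = 4a, anchor cassette = 4b). Cells
are stained for the displayed protein, FACS-sorted into *low*, *medium*
and *high* fluorescence gates (with an intentionally excluded band between
low and medium), and each sorted pool is PCR-amplified with a forward
(cargo library) and reverse (gate) barcode and sequenced as 2-3 kb
nanopore amplicons. The question is which promoter x SP combinations
drive display, read directly from the per-gate genotype abundances.

`sortscreen` is for people building or benchmarking this kind of sort-seq
readout. It provides both the deconvolution pipeline and a ground-truthed
simulator of the whole experiment, so every step can be validated against
a known answer.

## What it does

- **Part grammar** (`sortscreen.parts`): overhang-validated scarless
  assembly, ELP repeat construction ((VPGVG)5-(VPGAG)2-(VPGGG)3 twice =
  one 100-aa unit), and design-space enumeration (20 x 4 = 80 constructs).
- **Simulator** (`sortscreen.simulate`): genotype -> log-normal
  fluorescence -> gate model with an excluded band; barcoded amplicon
  reads with ~8% substitution/indel noise, random strand, optional
  CDS-truncated ("false-high") and chimeric templates; hidden truth
  recorded per read.
- **Demultiplexing and filtering** (`sortscreen.demux`): error-tolerant
  dual-barcode matching (edit distance <= 4 on 24-nt codes), the
  full-amplicon rule (both barcodes required), the >= 2 kb length filter,
  and orientation by the CBM sequence as 3' marker with chimera detection.
- **Genotype calling** (`sortscreen.calling`): part-level annotation by
  edit-distance placement plus affine-gap local rescoring, GFF3 output,
  and reduction to (promoter, SP, CDS) calls with truncation detection.
- **Quantification** (`sortscreen.quantify`): per-pool promoter x SP
  abundance matrices, top-N tables, heatmap exports, and a cross-gate
  rank score (low 0 / medium 1 / high 2) per genotype.
- **Pipeline** (`sortscreen.pipeline` + the `sortscreen` CLI): one YAML
  config, one global seed, byte-identical reruns.

## Worked example

The numbered scripts under `analysis/` run the full study. With defaults
(3 libraries x 3 gates x 400 reads/pool, seed 20):

```
python analysis/01_design_library.py
python analysis/02_simulate_screen.py
python analysis/03_deconvolve_reads.py
python analysis/04_quantify_enrichment.py
```

`03_deconvolve_reads.py` prints the filter attrition and accuracy:

```
reads in: 3600
dual-barcode assigned: 3403 (94.5%)
>= 2 kb full amplicons: 3403
oriented by CBM marker: 3403
genotype accuracy on 3403 full calls: 100.00%
```

94.5% of reads carry both barcodes within the edit-distance budget (the
rest lost a barcode to simulated read noise); every surviving read is a
full amplicon, and every genotype call matches the simulator's hidden
truth. `04_quantify_enrichment.py` then prints the per-pool top-5 tables
and gate profiles, e.g.:

```
  ELP4 high (n=376): pYTK011_MF 10.6%, pYTK012_MF 8.8%, pYTK010_MF 8.0%, ...
  ELP4 low  (n=375): pYTK025_SUC2 6.1%, pYTK019_SUC2 5.9%, pYTK017_AMY 5.3%, ...

  BLA: 80 genotypes; highest score pYTK010_MF = 2.00; Spearman vs truth profile = 0.998
```

High gates are dominated by strong promoters with the MF/STA1 signal
peptides and low gates by weak promoters with SUC2/AMY — the expected
biology — and the recovered cross-gate rank score reproduces the true
per-genotype gate profile at Spearman ~1.0. Equivalent functionality is
available as CLI subcommands (`sortscreen run-all --config
configs/demo.yaml`, plus `simulate`, `demux`, `call`, `quantify`,
`make-fixtures`).

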