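# doodlekit

Analysis toolkit for the DNA pools produced by *untemplated* ("ab initio",
colloquially "doodling") DNA polymerase synthesis — reactions in which a
thermostable polymerase such as Taq or Vent, given only dNTPs and buffer,
generates single-stranded DNA de novo and amplifies it into pools dominated
by short tandem repeats (GT, AT, AATT, CTATAG, GTATATAC, poly-A, A⁴T⁴, ...).

The package is aimed at people characterizing such pools from nanopore
sequencing, real-time fluorescence assays, and atomic force microscopy
(AFM). It provides, as an importable library:

- **`doodlekit.simulate`** — generators for read pools, fluorescence curves
  and AFM height maps with per-object ground truth, so every analysis stage
  is testable without instrument data;
- **`doodlekit.qc`** — terminal adapter/barcode trimming, concatemer
  flagging (internal adapter ⇒ two ligated fragments read as one), and the
  median Q ≥ 13 / length > 65 nt read filters;
- **`doodlekit.seqstats`** — base composition, the 4×4 base-transition
  probability matrix, and the normalized string autocorrelation
  *r*(*k*) = |{*i* : *s*ᵢ = *s*ᵢ₊ₖ}| / *N* whose peaks at multiples of the
  repeat period identify tandem-repeat reads;
- **`doodlekit.motifs`** — exact tandem-repeat detection with
  length-dependent copy thresholds (≥ 7 consecutive copies for 1–3 nt
  motifs, 6 for 4 nt, 4 for 6–8 nt), motif fraction tables from seeded
  600-read samples, condition fingerprints and their percent/fold changes,
  the random-occurrence probability (1/4)^L of an L-mer, and forward-strand
  genome scans reporting (n·m)/g;
- **`doodlekit.clustering`** — Ward-linkage hierarchical clustering of
  reads on composition + transition + autocorrelation features, split at
  250 nt, with majority-motif cluster labels;
- **`doodlekit.kinetics`** — normalization of SYBR fluorescence curves and
  a continuous two-segment piecewise-linear fit quantifying the two-phase
  synthesis kinetics (breakpoint ≈ 30 min, 3–3.5× rate increase) plus a
  saturation stop-time estimator;
- **`doodlekit.afm`** — per-row cubic flattening of height maps, molecule
  segmentation, skeleton-graph decomposition into a *trunk* (longest path)
  and *branches*, and nm → nt conversion at 0.34 nm per nucleotide;
- **`doodlekit.workflow`** — a configuration-driven end-to-end run
  (QC → stats → motifs → clustering → summary JSON), also exposed as a thin
  `doodlekit` command-line interface.

## Worked example

```sh
python examples/kinetics_fit.py
```

```
breakpoint: 29.5 min   (true 30.0)
slow rate:  2.29e-03 /min
fast rate:  7.78e-03 /min
rate ratio: 3.39            (true 3.25)
stop time:  175.0 min             (true 180.0)
```

A noisy fluorescence curve simulated in the observed kinetic regime is
normalized and fitted: the breakpoint between the slow initial phase and
the fast amplification phase is recovered within half a sampling interval,
the rate ratio lands in the reported 3–3.5× band, and the estimated stop of
synthesis is within one 5-min cycle of the construction's 180 min. The
other scripts in `examples/` (one per capability) print QC reports, motif
fraction tables, cluster labels and purities, AFM trunk/branch lengths with
their recovery errors, and genome-scan tables, each with a comment on what
the numbers mean.

The pipeline can also run end to end from a config:

```sh
doodlekit simulate-pool --preset taq65 --n-reads 2000 --seed 1 --out pool.fastq
doodlekit qc --fastq pool.fastq --out filtered.fastq
doodlekit motifs --fastq filtered.fastq --seed 1 --out fractions.tsv
```

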