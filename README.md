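# bisukit

Bisulfite-sequencing read alignment and methylation calling built on a
bisulfite-aware, Hamming-aware de Bruijn hash index, plus a directional
BS-seq simulator and evaluation harness.

## How it works

* **Hash (`bisukit.bshash`)** — a DNA pattern is collapsed to bits
  (C/T → 0, G/A → 1), split into `w`-bit blocks (all leading blocks
  non-overlapping, the last anchored at the pattern end), and the blocks are
  XOR-ed into a `w`-bit fingerprint. The construction is simultaneously
  *de Bruijn* (overlapping patterns give overlapping fingerprints, so a
  whole text has a well-defined hash), *bisulfite-aware* (C→T and G→A
  substitutions never change the fingerprint), and *Hamming-aware*
  (patterns within Hamming distance `k` have fingerprints within
  XOR-distance `2k`).
* **Index (`bisukit.index`)** — the concatenated, N-randomised reference
  plus a fingerprint → positions table over every length-`m` window.
* **Aligner (`bisukit.align`)** — seed-and-extend: the seed fingerprint's
  radius-`2k` Hamming ball is enumerated, bucket hits are verified with
  BS-aware ungapped extension, and the best placement is reported
  (unique / multiple / unmapped) as SAM. Paired-end FR pairing with
  directional-protocol mate-2 handling (reverse C→T / forward G→A).
* **Caller (`bisukit.methcall`)** — a rank-supported bit-vector marks
  reference Cs/Gs; two blocked, capacity-growing counter arrays accumulate
  primary (C/G) and converted (T/A) evidence in rank space; β =
  primary/(primary+converted); CpG/CHG/CHH context annotation; Bismark-cov,
  BED and EPP-dialect output with optional on-the-fly gzip; target-BED
  support (flank extension, off-target read discard, on-target-only output,
  enrichment statistics).
* **Simulator (`bisukit.simulate`)** — directional paired BS-seq libraries
  with per-cytosine binary methylation states, configurable conversion
  efficiency (default 0.98) and uniform sequencing error, plus
  mapping/methylation evaluation against the recorded truth.

## CLI

```sh
bisukit simulate genome ref.fa --length 1000000 --gc 0.36 --seed 1
bisukit simulate reads ref.fa lib --coverage 24.6 --error-rate 0.01 --seed 2
bisukit index ref.fa ref.idx --bl 30
bisukit align ref.idx lib_1.fastq out.sam --mate lib_2.fastq --seed-errors 2
bisukit call ref.idx out.sam meth.cov --output-format cov --gzip
bisukit evaluate-mapping ref.idx out.sam lib.truth.tsv
```

FASTQ inputs may be gzip-compressed. `--threads` and `--no-auto-trim` are
accepted for interface parity (execution is serial; no trimming is
performed). Target-enrichment options on `call`: `--targets FILE.bed`,
`--extend-targets N`, `--on-target-only`, `--discard-off-target`.

### Output formats

* `cov` (Bismark-compatible): `contig  pos1  pos1  100·β  primary  converted`,
  covered cytosines only.
* `bed`: `contig  start  end  strand  context  primary  converted  β`
  (0-based half-open; `NA` β at zero coverage; all cytosines).
* `epp` (documented in-repo dialect): `contig  pos1  strand  context
  primary  coverage  β`, covered cytosines only.

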