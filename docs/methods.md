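# Methods

This package implements a k-mer genome survey of the kind run on a newly
sequenced, assembly-free organism: short-read QC, 17-mer spectrum profiling
(genome size, heterozygosity, repeat content), GC-depth windowing, SSR
mining, and a sex-marker presence screen, together with a ground-truthed
diploid read simulator used to validate every estimator.

## The k-mer survey model

Let reads be drawn uniformly from a diploid genome of haploid length `G` at
fold coverage `c`. Counting canonical k-mers (a window and its reverse
complement are one species) over all clean reads gives a depth histogram
`species(d)`: the number of distinct k-mers seen exactly `d` times.

* **Peak depth.** Homozygous single-copy k-mers have multiplicity
  approximately Poisson with mean `λ = c·(L−k+1)/L` for read length `L`
  (each read contributes `L−k+1` windows). The histogram mode above the
  low-frequency cutoff estimates this per-k-mer depth.
* **Genome size.** `G ≈ kmer_number / peak_depth`, where `kmer_number` is
  the total k-mer individuals at depth ≥ 6. Depths ≤ 5 are treated as
  sequencing-error k-mers; their individual fraction is the "error rate"
  used in `revised_size = size × (1 − error_rate)`. (The sequencing-level
  base error — hundredths of a percent — cannot account for a
  multi-percent size revision; the discarded-k-mer fraction can, and it is
  what the cutoff actually removes.)
* **Heterozygosity.** A SNP between the two haplotypes turns the ~2k k-mer
  species overlapping it into haplotype-specific species at half depth.
  With `a_half` the fraction of k-mer species in the half-depth component,
  the per-base SNP rate is

      het = a_half / (k · (2 − a_half)),

  which inverts to `a_half = 2k·het / (1 + k·het)`; at `het = 0.37%`
  and `k = 17` this gives `a_half ≈ 0.118`.
* **Repeat ratio.** Exact repeats stack their k-mers at integer multiples
  of the peak. The fraction of k-mer individuals at depth `> 1.8 × peak`
  (among individuals above the cutoff) estimates the repetitive fraction.

### Estimating `a_half`

No standard estimator exists for the half-peak weight, so the package fits
species counts over depths `[6, 1.8·peak]` with a two-component mixture of
Poisson kernels whose means are pinned at `peak/2` and `peak`, solved by
nonnegative least squares; `a_half` is the heterozygous weight over the
total. Pinned means keep the fit linear and deterministic; an overdispersed
negative-binomial kernel (variance `μ(1+μ/size)`, `size = 200` by default)
is available behind `model="nbinom"` for real data whose spectra are wider
than Poisson. Degenerate inputs (no mass in the fit range, zero total
weight) raise estimation errors rather than returning silence.

### Numerical choices

* k is capped at 31 so a k-mer packs into a 64-bit two-bit code; counting
  is vectorised (rolling code update + `np.unique`), and windows containing
  N are dropped.
* Peak ties break to the smaller depth; an optional centred width-3 moving
  average can smooth the histogram before the argmax (off by default —
  at survey depths the mode is well resolved).
* Full precision is kept internally; Mbp and percent values are rounded to
  two decimals only at serialisation.
* The integer peak is the dominant error term in the size estimate: a ±1
  bin at peak depth `p` moves the estimate by `~1/p` (1.5% at 65×). The
  2% recovery tolerance used in validation follows from this, not from
  counting noise.
* The repeat statistic reads slightly low for exact two-copy repeats
  because the repeat component (mean `2λ`) leaks below the `1.8λ`
  threshold by its Poisson spread, and windows straddling repeat
  boundaries are unique-context. Longer repeat units and higher coverage
  shrink both effects.

## Read QC

A pair is dropped when (in order, first failing rule counts): an exact
adapter substring occurs in either mate (no trimming — only whole-pair
drops are implemented, and no adapter is assumed by default); N makes up
**at least 10%** of either mate; or bases under Phred 5 make up **more
than 50%** of either mate. The boundary semantics are deliberate: 10% N
drops, exactly 50% low-quality keeps. Error rate is quality-derived
(mean of `10^(−Q/10)` over bases, as a percent); Q20/Q30 are base
fractions at or above the threshold; GC excludes N from the denominator.

## GC-depth windows

Non-overlapping 10-kb windows over an assembly; trailing partial windows
are dropped so all windows are length-matched; GC is over non-N bases and
all-N windows are emitted with undefined GC but excluded from tables.
Depth is alignment-free: the mean read-set multiplicity of the window's
canonical k-mers. Because a read of length `L` covers a genomic k-mer with
probability `(L−k+1)/L` relative to a base, the optional `read_length`
argument applies the `L/(L−k+1)` edge correction so the track estimates
fold coverage. A pre-computed depth track can be supplied instead via the
TSV interface.

## SSR mining

Perfect tandem repeats of primitive 1–6-base units with minimum repeat
numbers 10/6/5/5/5/5 (mono…hexa), found by vectorised `s[i]==s[i+u]`
run-length analysis; N breaks runs; partial trailing units are not
counted; runs whose unit is a power of a shorter unit are reported at the
shorter unit. Loci separated by ≤ 100 bases merge into a compound locus
(counted once in totals, with member motifs retained); a `remove` mode
drops such clusters instead, since mining pipelines differ on this point.
Loci with under 100 bp of flank on either side are removed (primer-design
flanks); `min_flank=0` disables. Motif classes are canonical under
rotation and reverse complement, rendered `"X/revcomp(X)"` (e.g. AC/GT,
AGG/CCT). Coordinates are 1-based inclusive, MISA-style.

## Marker screening

Presence in a read set is called by canonical k-mer containment (fraction
of the marker's k-mers present), defaulting to a 0.5 presence threshold;
absence requires containment below `1 − threshold`. Sex-specific = present
in one sex and absent in the other, both directions reported. Containment
rather than alignment is used against read sets because reads are
unassembled; against assembled targets the best seed-anchored global
alignment (match +1, mismatch −1, gap −2; all exposed) yields a percent
identity (matches / alignment columns) and a location. Real
sex-determination gene sequences are not bundled; screening is exercised
on synthetic cassettes planted into simulated genomes (labelled synthetic
wherever they appear).

## The simulator

`SimulationSpec` defaults describe the sequencing design the survey
targets: paired-end 150 bp, insert 350 bp, coverage 70×, per-base error
3×10⁻⁴, GC 41.8%, SNP heterozygosity 0.37%, repeat fraction 27%
(TE-scale 2-kb exact two-copy units). Haplotype A is i.i.d. with the
target GC; repeats are planted by copying one unit-length slot onto
another disjoint slot (exact copies, so their spectrum signature is
analytically checkable); haplotype B applies i.i.d. biallelic
substitutions. Fragments are drawn uniformly from a random haplotype;
mate 2 is reverse-complemented; per-read constant Phred scores mix the two
integers bracketing `−10·log₁₀(err)` so the encoded mean error equals the
error rate exactly (error-free reads get Q60). Separate seeded streams
per stage make genomes stable under read-stage changes, and identical
spec+seed reproduces byte-identical FASTQ. `inject_artifacts` corrupts
exact pair fractions with ≥10% N or >50% sub-Q5 bases and records which,
so QC tests can assert the dropped set exactly.

What the simulator does **not** emulate: indels (the heterozygosity model
assumes substitutions), PCR duplicates and adapter contamination,
quality-by-cycle decay, GC-coverage bias, and any real repeat-family
structure — its repeat model is a stand-in, not a claim about any species.
Passing recovery tests therefore show estimator correctness under the
model's assumptions, not robustness to every artefact of real libraries.

## Validation scale

Tests and the acceptance script run desk-scale versions of the study
conditions: megabase genomes at 74× for parameter recovery (heterozygosity
within ±0.05 percentage points of 0.37%; genome size median error ≤ 2%
over five seeds), 400–500-kb genomes elsewhere, and oracle equivalence
suites (naive dictionary k-mer counting on ≤ 10-kb inputs; regex
backreference SSR enumeration over 100 random 10-kb sequences; exhaustive
tiny-alignment enumeration). Published in-table arithmetic (genome-size
division, effective-rate and percent-share ratios) is reproduced exactly
from the printed inputs.
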