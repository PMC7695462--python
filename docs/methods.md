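# Methods

## Assay model

A D-loop on a donor duplex exposes one strand (the "top"/displaced
strand, by convention the reference sequence itself) as single-stranded
DNA. Non-denaturing bisulfite converts cytosines to uracil on
single-stranded DNA only; after PCR and circular-consensus long-read
sequencing, a read sampled from the top strand shows the D-loop as a
dense tract of C→T conversions in reference coordinates, while a read
sampled from the bottom (template) strand shows its own cytosines' rare
background conversions as G→A. Both strands are represented on a single
reference axis: top-strand cytosines at reference C positions,
bottom-strand cytosines at reference G positions. Coordinates are
0-based half-open internally; human-readable tables also carry 1-based
inclusive columns.

## Conversion tracks (convert)

Per covered reference C: `converted` if the read base is T,
`unconverted` if C, `masked` otherwise — non-T mismatches at a C (and
non-A at a G for the bottom candidate) are treated as sequencing noise,
not evidence either way. Positions within 5 nt of an indel's reference
footprint are masked on both sides (a deletion of [d0, d1) masks
[d0−5, d1+5); an insertion anchored before reference position p masks
[p−5, p+5]). Both conversion tallies are computed after masking; masked
positions never enter window denominators.

Strand assignment: `unknown` if n(C→T) < 6 **and** n(G→A) < 6 (both
tallies below the evidence floor), `unknown` if
|n(C→T) − n(G→A)| ≤ 0.1 × max(n(C→T), n(G→A)) (the ambiguity band is
taken relative to the larger tally — scale-free and symmetric),
otherwise the predominant direction. The length filter keeps reads with
observed aligned span ≥ 50% of the expected amplicon length (boundary
inclusive); the expected length defaults to the reference length and is
configurable per sample.

A consequence of the evidence floor worth knowing: when duplex
background conversion is very low (the simulator's default breathing
rate is 0.005/cytosine), most *footprint-free* reads carry fewer than 6
conversions on either strand and are correctly `unknown` — the
assignable pool is enriched for footprint-bearing reads, which inflates
% Peak relative to the molecule-level D-loop incidence. Real datasets
sit in a higher effective-background regime (sequencing substitutions
add to breathing), where under ~5% of reads are unassignable; the test
suite probes that regime at a background of 0.02/cytosine (~14
conversions per strand per read).

## Peak calling (peaks)

Windows span `w` consecutive unmasked cytosines (cytosine-count
windows, not fixed nt, to neutralise sequence-composition bias) and
move one cytosine at a time across the *whole* read — not only the
homology window, so breathing artefacts outside homology remain
observable. A window is positive when converted/w ≥ t; equality passes
(2/5 = 40% is positive at t40). Maximal runs of consecutive positive
windows become one peak each; a single sub-threshold window terminates
the peak, so two positive windows separated by ≥ 1 negative window
yield two footprints. Peak boundaries are the outermost converted
cytosines within the union of the run's windows — extension beyond a
dense region can only be driven by converted cytosines, never trailing
unconverted ones. Length = end − start (no +1). Reads with fewer than
`w` unmasked cytosines yield no footprint, which is why homologies with
fewer than 50 cytosines (e.g. the 43-cytosine 197 nt homology) behave
anomalously at w50 and shorter windows are then appropriate.

The minimum detectable footprint is the nt span of one `w`-cytosine
window and therefore depends on local cytosine density;
`min_detectable_length` reports the min/max window span over the
homology (≈ 120–200 nt at w50 for the packaged homologies, ≈ 80–100 nt
at w20).

Numerical detail: the positivity test `count ≥ t·w` is evaluated with a
1e-9 slack because t·w (e.g. 0.4 × 5) is not exactly representable in
binary floating point; the brute-force oracle in the tests uses the
same pass-at-equality rule computed independently.

## Topology (refmodel)

Each 10.4 bp of heteroduplex absorbs one negative supercoil, so a
covalently closed donor of length L at supercoiling density σ (< 0)
accommodates |σ|·L nt of heteroduplex: the footprint-length cap in
supercoiled mode is min(homology length, |σ|·L), rounded to the nearest
nt (σ = −0.07, L = 3000 → ~20 supercoils, 210 nt). Linear donors are
capped by homology alone. Positive σ is rejected — the assay is not
defined on positively supercoiled donors. The observed spread around
the cap in real data (nicked plasmids, supercoil-count variance) is not
modelled; the cap is a point value.

## Simulator (simulate)

One read per molecule, emitted pre-aligned in reference orientation
(read mapping is upstream of this package). Per molecule: D-loop
presence ~ Bernoulli(dloop_fraction); length from the configured law
(`fixed`, `uniform_to_cap`, or truncated normal), always clipped to the
topology/homology cap; 3′ edge either uniform or drawn from a linear
ramp rising toward the homology 3′ end (`three_prime_biased`, the
default — a deliberately simple law reproducing the observed 3′
enrichment; the true positional law is unknown). The sequenced strand
is top with probability 1/(1 + bottom_to_top_read_ratio). Top-strand
reads convert each cytosine inside the D-loop with
`conversion_efficiency` and every other cytosine with `breathing_rate`;
bottom-strand reads convert their (always duplex) cytosines at
`breathing_rate`, appearing as G→A. Breathing is i.i.d. per cytosine —
the simplest null consistent with isolated background conversions; it
does not produce the rare *contiguous* breathing patches real data can
show in C-rich regions. 1-nt indels are injected at `indel_rate` per
base (insertion/deletion equiprobable, recorded in the CIGAR) and a
`truncation_fraction` of reads is cut to a uniform 10–50% of the
amplicon, which the length filter later removes. A single
`numpy.random.default_rng(seed)` stream drawn in fixed per-molecule
order makes output byte-identical for a given config.

Defaults are the characterised study conditions: conversion efficiency
0.58/cytosine (measured on a spiked single-stranded control),
breathing 0.005 (near-zero duplex background), bottom:top read ratio
2.0 (PCR bias against uracil-containing top strands plus nicking),
D-loop incidence 0.134 (the headline top-strand footprint frequency on
the 931 nt homology), indel rate 0.002/base and truncation fraction
0.05 (sparse CCS-scale artefacts), supercoiled topology σ = −0.07 on a
3 kb donor with a truncated-normal(210, 50) length law floored at the
100 nt detection limit. `simulate_ssdna_control` models the fully
single-stranded spike-in: every cytosine converts at
`conversion_efficiency`, nothing else.

The simulator does not model: PacBio subreads/CCS polishing,
barcodes/chimeras, substitution sequencing errors, RPA occlusion or
branch migration (their net effects are summarised by the efficiency
and read-ratio knobs), multi-invasion, or contiguous breathing patches.
Passing tests therefore demonstrate the pipeline's correctness under
the assay's stated statistical structure, not robustness to every real
artefact.

## Profiling (profile)

% Peak = 100 × (reads with ≥ 1 footprint) / (total reads on that
strand); undefined (an error, not 0) for zero reads; reported at 2
decimals. Multi-footprint reads count once in % Peak but contribute
every footprint to length and binning statistics. Length statistics use
the arithmetic mean and sample SD (SD undefined for a single
footprint). Positional binning tiles the homology window with
`bin_size`-nt bins anchored at the window start, keeping the final
partial bin; a footprint contributes 1 to every bin its closed interval
[start, end] overlaps by ≥ 1 nt ("non-exclusive"), and values are
divided by the total footprint count — they need not sum to 1. Note a
structural property of non-exclusive binning of finite-length
footprints: bins within one footprint length of the homology 3′ end see
only the upper tail of the 3′-edge distribution, so the binned curve
must dip over the last ~footprint-length even under a strongly
3′-biased position law. Clustering orders footprint-containing reads
by (first footprint start, end, read id) — deterministic and
idempotent. Footprint maps are exported as a parseable text matrix
(round-trips footprint intervals exactly) and a PNG using the
field's colour convention.

## Pipeline sizes and determinism

The packaged end-to-end runs use a synthetic ~2.9 kb donor (931 nt
homology between two seeded-random 1 kb non-homologous flanks — the
real donor plasmid sequence is not public, so the flanks are labelled
synthetic). Test-suite simulations use 120–2000 molecules and the
acceptance self-check 400, sizes at which every stochastic check
(binomial conversion laws, strand ratios, recovery ≥ 90%) has
comfortable margin under its fixed seed. Re-running any stage with the
same config and seed reproduces all output bytes.

## Known limitations

* Footprint calling is threshold-based, not probabilistic; there is no
  per-read FDR — specificity is controlled by the threshold plus the
  assay's internal negative controls (bottom strand, non-homologous
  flanks).
* Boundary placement is limited by local cytosine spacing and by edge
  clipping of threshold windows; lengths near or below the window span
  are overestimated.
* The ±10% strand-ambiguity band is a formalisation of an
  under-specified rule (10% of the larger tally); alternative readings
  (10% of the smaller, of the sum) differ only in a thin band.
* Replicate handling is concatenation; between-sample statistics are
  left to downstream tooling.
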