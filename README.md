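# dloopmap

Single-molecule mapping of D-loops (displacement loops) from
non-denaturing bisulfite footprinting of long-read amplicons.

## The problem

D-loops are the central intermediate of homologous recombination: an
invading single strand pairs with its homologous donor duplex, forming a
heteroduplex and displacing one donor strand. Non-denaturing bisulfite
deaminates cytosine to uracil on *single-stranded* DNA only, so the
displaced strand of every D-loop acquires a tract of C→T conversions
that survives PCR and single-molecule long-read sequencing. Reading
those tracts back per molecule gives the number, position and length of
individual D-loops — information population assays cannot provide.

`dloopmap` implements the computational half of this assay for people
running in vitro recombination reactions (or re-analysing such data):
it consumes per-read alignments of amplicon consensus reads to the donor
reference and produces per-read footprint calls and per-sample
summaries. A ground-truthed simulator of the whole data-generating
process is included, so every stage is testable without any sequencing
data.

## The model

For each read, every reference cytosine the read covers is scored
converted (read base T), unconverted (C) or masked (anything else, or
within 5 nt of an indel). The same is done for reference G positions as
G→A, which is how conversions on the template ("bottom") strand appear
in reference orientation. Strand is assigned from the asymmetry of the
two tallies n(C→T) and n(G→A): a read is `unknown` when both are < 6 or
when they differ by ≤ 10% of the larger, otherwise the predominant
direction wins. Reads shorter than half the expected amplicon length
are discarded.

Footprints are called with a threshold **tXXwYY**: a window of
*w = YY* consecutive unmasked cytosines slides one cytosine at a time,
and is positive when its converted fraction is ≥ *t = XX/100*. Maximal
runs of consecutive positive windows form one peak each — a single
sub-threshold window terminates the peak — and peak boundaries are
trimmed to the outermost converted cytosines covered by the run.
Footprint length is the 3′ boundary minus the 5′ boundary in nt. The
default operating point is `t40w50`.

On a negatively supercoiled donor, topology caps the heteroduplex:
every 10.4 bp of heteroduplex absorbs one negative supercoil, so a
plasmid of length *L* at supercoiling density σ accommodates at most
|σ|·*L* nt of D-loop (≈ 210 nt for a 3 kb donor at σ = −0.07). The
`TopologyModel` carries this arithmetic into both the simulator and the
analysis.

Sample-level outputs: **% Peak** (percentage of reads on a strand with
≥ 1 footprint — the formation-efficiency readout), footprint length mean
± SD, non-exclusive 100-nt positional binning across the homology
window normalised by total footprint count, 5′→3′ read clustering, and
footprint maps (text matrix + PNG; yellow cytosine, green converted,
red in-footprint, grey masked).

## Worked example

```python
from dloopmap import (SimulationConfig, build_donor, call_peaks_all,
                      process_reads, simulate_dataset, summarize_sample)

donor = build_donor("ds98-931")          # 931 nt homology, 1 kb flanks
config = SimulationConfig(n_molecules=500, seed=7)
reads, truth = simulate_dataset(config, donor)
tracks, counts = process_reads(reads, donor)
footprints = call_peaks_all(tracks)      # t40w50 by default
for strand, s in summarize_sample(tracks, footprints).items():
    print(strand, s.n_peak_reads, s.n_total_reads, s.percent_peak)
```

which prints (see `examples/02_simulate_and_call.py`):

```
top   : 5/34 reads with a footprint (% Peak = 14.71), mean length 200 nt
bottom: 0/41 reads with a footprint (% Peak = 0.00), mean length - nt
```

Footprints appear only on the top (displaced) strand, confined to the
homology window, with lengths near the 210 nt supercoiling cap; the
bottom strand is the internal negative control. The `examples/`
scripts walk through topology arithmetic, simulation + calling,
threshold sweeps, and the single-stranded conversion-efficiency
control; the same pipeline is available from the shell:

```bash
dloopmap demo --out demo_run           # small end-to-end run
dloopmap simulate --substrate ds98-931 --n-molecules 1000 --out run/
dloopmap call reads.sam --substrate ds98-931 --threshold t40w50 --out run/
```

Packaged fixtures: the four substrate homology sequences ds98-197,
ds98-607, ds98-915 and ds98-931 (43, 132, 192 and 187 cytosines).

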