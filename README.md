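# occupeak

Ratio-window ChIP-seq occupancy analysis for bacterial genomes: exact-match
strand-collapsed read anchoring, trimmed-mean scaling normalization, R-ratio
peak and unbound-region calling, direct/inverted repeat-pair scanning, and
observed-vs-expected base-pair overlap enrichment — with a synthetic-data
generator that plants known truth so the whole pipeline can be validated
end to end.

## Who this is for

Researchers mapping the genomic occupancy of abundant, weakly
sequence-specific DNA-binding proteins — typically bacterial
nucleoid-associated proteins (NAPs) such as Dps, Fis, H-NS or IHF — where
binding is broad and enrichment is modest (fold changes of 1.5–10 rather
than the sharp peaks of classical transcription factors), and where
multi-mapping reads (rRNA operons, REP elements) carry real signal that
unique-mapping pipelines discard.

## The method

**Anchoring.** Reads are standardized to a fixed length *L* (center-trimmed
to 50 nt by default, after a per-base Phred ≥ 20 filter) and matched to the
genome with *no* mismatches. A read is anchored at the left coordinate of
its matching window on either strand, so a read and its exact reverse
complement count at the same position. Multi-locus reads either contribute
at every locus (default) or are dropped (`unique-only`).

**Normalization and the R ratio.** The immunoprecipitated (IP) profile is
scaled onto the control by the ratio of their 2%-trimmed means (the scaling
method assumes unchanged occupancy at most positions). Counts are then
summed in running windows *w* ∈ {25, 35, 75} bp (default 35) and

&nbsp;&nbsp;&nbsp;&nbsp;R(p) = (IP_w(p) + c) / (ctrl_w(p) + c)

with pseudocount c (default 1).

**Calling.** A *peak* is a containment-maximal interval of ≥ 60 bp in which
≥ 50% of positions have R ≥ 1.5 and whose end positions are above
threshold. An *unbound region* (UR) has R < 1.0 at every position in both
replicate experiments over ≥ 60 bp, outside any exclusion set; regions
separated by < 30 bp merge when all intermediate R ≤ 1.1. The *combined
set* (CS) is the second experiment's peaks minus any peak overlapping a
first-experiment unbound region.

**Repeats and enrichment.** The genome is scanned for direct repeat pairs
(arm *i* = 5–24 bp, spacer *j* = 0–20 bp) and inverted repeat pairs
(*i* = 5–18, *j* = 3–20). Each pair is the holistic unit [p, p + 2i + j),
so the per-cell totals satisfy L_ij = n_ij · (2i + j). Against any interval
set of total length L_set on a genome of G bp, the expected shared base
pairs under independent placement are

&nbsp;&nbsp;&nbsp;&nbsp;E = (L_ij / G) · L_set,

and K_ij = O / E measures excess co-occurrence (K = 1 under independence).
Per-(i,j) K distributions of bound vs unbound sets are compared with a
two-sided Mann–Whitney U test.

## Worked example

Simulate a 20 kb circular genome with two planted occupancy sites (5× at
4000–4180, 3× at 12500–12650) and an origin-proximal copy-number gradient,
then run the full analysis:

```python
from occupeak import (SyntheticSpec, PlantedSite, make_genome, simulate_reads,
                      build_index, anchor_reads, scale_normalize, window_counts,
                      ratio_track, call_peaks, scan_repeats, repeat_enrichment)

spec = SyntheticSpec(
    genome_length=20_000, seed=7,
    planted_sites=[PlantedSite(4_000, 4_180, 5.0), PlantedSite(12_500, 12_650, 3.0)],
    gradient=(0, 1.5, 10_000),
    n_control=400_000, n_ip=400_000,
)
genome, truth = make_genome(spec)
ctrl, ip = simulate_reads(genome, truth, spec)

index = build_index(genome, spec.read_length)
prof_ctrl, prof_ip = anchor_reads(ctrl, index), anchor_reads(ip, index)
ip_scaled, ctrl_scaled, scaling = scale_normalize(prof_ip, prof_ctrl)
rt = ratio_track(window_counts(ip_scaled, 35), window_counts(ctrl_scaled, 35))
peaks = call_peaks(rt)

cat = scan_repeats(genome, "inverted", [5], [3])
res = repeat_enrichment(cat, "inverted", 5, 3, peaks)
```

Output:

```
anchored: control 400000, IP 400000
scaling factor: 1.0497
peak 3743-4386 (643 bp), max R = 4.93
peak 12274-12790 (516 bp), max R = 3.04
inverted (i=5, j=3) pairs: n = 14, footprint = 182 bp
overlap with peaks: O = 13 bp, E = 10.5 bp, K = 1.23
```

Both planted sites are recovered (peak maxima near the planted factors; the
calls extend beyond the planted intervals by roughly half a sonication
fragment, as expected for end-anchored reads). The scaling factor corrects
the gradient-induced imbalance between the libraries, and the repeat
enrichment block shows the K-statistic machinery on the same data: 14
inverted pentamer pairs with 3-bp spacers, 182 = 14 × 13 bp of footprint,
observed vs expected overlap with the peak set, K = O/E.

The same stages are exposed as a CLI (`occupeak simulate | prep | anchor |
tracks | callpeaks | repeats | enrich | run-all`); `run-all` takes a YAML
config, writes BED/bedGraph/TSV outputs and a manifest echoing every
parameter, and is byte-reproducible for a fixed seed.

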