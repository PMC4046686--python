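# peakdeconv

Model-based ChIP-seq peak calling by learned peak-shape deconvolution.

ChIP-seq profiles a chromatin-binding factor (or a histone modification) by
sequencing the 5' ends of immunoprecipitated chromatin fragments.  Most peak
callers ask where read counts deviate from background; `peakdeconv` instead
exploits the *shape* of a binding event.  It learns a representative binding
pattern — a Gamma density in genomic distance, discretized at 10-bp bins and
rescaled to unit maximum, the *kernel* g(x; k, θ) — from the strongest
regions of the profile itself, then expresses the genome-wide binned
coverage y as a sparse non-negative superposition of shifted kernel copies,

    y(x) ≈ Σ_i  β_i · g(x − x_i; k, θ),   β_i ≥ 0,

fitted window by window (20-kb windows overlapping by one kernel support)
with greedy matching pursuit and joint non-negative least-squares refit.
Each retained placement (x_i, β_i) is a candidate binding site whose
coefficient β_i is the peak height in read-count units.

Confidence is non-parametric: for every site the profile around it (with the
site's own fitted component removed) is bootstrap-resampled in kernel-length
blocks, each pseudo-profile is deconvolved again, and the maximum spurious
coefficient per replicate forms a null distribution.  Sites receive
empirical p-values against 5-, 10- and 15-kb local backgrounds and one
genome-wide background, combined with Fisher's method
(−2 Σ ln pᵢ ~ χ² with 2k df).  A control sample, when supplied, can veto a
site (the control fits the kernel at least as well) or sharpen its
confidence.  **No significance threshold is applied**: the full site list
is reported with all descriptors, plus a quantile table to support user
thresholding.

The package also infers the read-elongation (fragment) length from
strand-specific coverage, and ships a simulator that generates IP/control
read sets with exact ground truth, so every stage is testable without
external data.

## Worked example

```bash
# 1. simulate a 2-Mb chromosome with 50 binding sites (ground truth saved)
peakdeconv simulate --n-sites 50 --length 2000000 --seed 7 --out-prefix demo

# 2. call peaks: auto fragment length, learned kernel, bootstrap confidence
peakdeconv call-peaks demo.ip.bed demo.chrom.sizes --control demo.control.bed \
    --elongation auto --seed 7 --out-prefix demo
```

The log reports the inferred elongation and learned kernel:

```
inferred elongation: fwd=181 rev=183 combined=182 (from 32/37 regions)
learn_kernel: shape=492.004 scale=3.920 after 2 iterations (converged=True)
called 51 sites -> demo.peaks.tsv
```

`demo.peaks.tsv` holds one row per site (first rows shown; the header lines
embed the full configuration and seed):

```
chrom   start   end     summit  height   p_local_5k  p_local_10k p_local_15k p_global  p_combined   p_corrected
chrSim  13550   15820   15471   57.881   0.00990099  0.00990099  0.00990099  0.990099  0.000532518  6.93486e-05
chrSim  74080   76350   76001   49.9133  0.00990099  0.00990099  0.00990099  1         0.000536773  6.98605e-05
```

`height` is the fitted coefficient β (read-count units); `summit` is the
1-based position of the kernel mode; the p-value floor 0.0099 = 1/(1+100)
comes from the add-one estimator with the default 100 bootstrap replicates,
and `p_combined` is their Fisher combination (p_global near 1 is expected
for strong sites — the global null deliberately retains genuine peaks, so
discrimination comes from the local windows).  Against the saved truth
table, all 50 planted sites are recovered within 50 bp at
`p_combined ≤ 0.01` with no spurious significant call.

The same pipeline is available as a library:

```python
import peakdeconv as pdc
reads = pdc.read_bed("demo.ip.bed", pdc.read_chrom_sizes("demo.chrom.sizes"))
result = pdc.call_peaks(reads, {"chrSim": 2_000_000},
                        config=pdc.RunConfig(elongation="auto", seed=7))
result.table().head()
```

Other subcommands: `coverage` (wiggle/bedGraph tracks), `learn-kernel`
(kernel as shareable JSON), `summary` (p-value quantile table).

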