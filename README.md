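# nmdtools

Tools for studying nonsense-mediated mRNA decay (NMD) at the transcriptome
scale: classify transcript isoforms as NMD substrates by the 50-nt rule, call
NMD targets and factor-dependence groups from knockdown fold-change tables,
compare groups with ECDF/Kolmogorov–Smirnov statistics, and quantify exon
junction complex (EJC) footprints over canonical deposition sites from
RIPiT-Seq-style alignments. A fully deterministic synthetic-data generator
provides annotations, count matrices, footprint reads and reporter decay
courses with known ground truth, so every stage is testable without
downloading sequencing data.

## Who this is for

RNA biologists and computational groups dissecting which transcripts the NMD
pathway degrades, which NMD factor (e.g. a UPF3 paralog) each target depends
on, and how EJC occupancy relates to decay efficiency.

## The methods at the core

**50-nt rule classification.** A coding transcript is PTC⁺ (carries an
NMD-inducing configuration) if its 3′UTR begins more than 50 nt upstream of
an exon–exon junction, or if more than one junction lies downstream of the
stop codon; coding transcripts lacking both features are PTC⁻. The analysis
group pairs PTC⁻ isoforms with PTC⁺ isoforms of the same gene, so indirect
expression effects cancel and only NMD-specific effects separate the groups.
The boundary dialect (> 50 vs ≥ 50) is configurable; distances are evaluated
in spliced-mRNA coordinates.

**Target calling.** NMD⁺ transcripts satisfy adjusted *P* < 0.05 and fold
change > 1.2 in at least two of three factor-knockdown contrasts; NMD⁻
transcripts change less than 1.2-fold in either direction in at least two.
Factor-dependent targets of a single knockout contrast show significant
≥ 1.5-fold upregulation; independent targets change ≤ 1.2-fold. Per-gene NMD
efficiency is the highest fold change among the gene's PTC⁺ isoforms, binned
up / no-change / down.

**Group statistics.** Fold-change distributions of paired groups are compared
as ECDFs with the two-sample KS test, D = sup|F₁ − F₂| with the asymptotic
Kolmogorov *p* at effective size n₁n₂/(n₁+n₂). Rank-sum/signed-rank tests,
Pearson correlation, total-least-squares regression, and exponential decay
fits through (t = 0, fraction = 1) with t½ = ln 2 / k round out the toolkit.

**EJC footprints.** The EJC is deposited ~24 nt upstream of exon–exon
junctions. Canonical sites span −39 to −9 nt from the 3′ end of every
non-last exon (31 nt, strand-aware, truncated at short exons, merged across
isoforms per gene). Gene-level signal counts reads overlapping any canonical
site once per gene, averages over the number of merged sites ("intron
count"), filters genes at canonical-region RPKM ≤ 5, and supports
expression-normalized occupancy and meta-exon profiles anchored at exon
boundaries.

## Worked example

Simulate a dataset with known truth, then run the pipeline end to end:

```sh
nmdtools simulate --out-dir demo --seed 1 --n-genes 100
nmdtools run-all --gtf demo/annotation.gtf --counts demo/counts.tsv \
    --reads demo/footprints.bed --out-dir demo_out
```

prints

```
{
  "n_ptc_plus": 75,
  "n_ptc_minus": 50,
  "n_genes": 60,
  "ks_D": 0.8133333333333334,
  "ks_p": 1.1576905260731838e-17,
  "n_dependent": 3,
  "n_independent": 94,
  "n_ejc_genes": 100,
  "meta_argmax_3p": -24
}
```

Reading the output: of the expressed transcripts, 75 are PTC⁺ and 50 are
their same-gene PTC⁻ controls across 60 genes. The simulation injects a
1.5-fold knockout effect into PTC⁺ transcripts, and the KS comparison of the
two fold-change ECDFs detects it decisively (D = 0.81, p ≈ 1e-17). Three
transcripts pass the stringent significant-and-≥1.5-fold dependence rule at
these sample sizes, 94 are called independent (≤ 1.2-fold change), and the
meta-exon footprint profile peaks at −24 nt from exon 3′ ends — the canonical
EJC deposition site the reads were simulated around. Reporter decay fits are
available too:

```sh
$ nmdtools half-life --decay-tsv demo/decay.tsv
t1/2 = 61.75 min (k = 0.0112/min)
replicates: 62.49, 59.73, 63.04  SEM: 1.0230036712965378
```

(the generating half-life was 60 min with 5% multiplicative noise).

Every stage is also available as a library call (`nmdtools.classify_transcript`,
`nmdtools.call_nmd_targets`, `nmdtools.ks_two_sample`,
`nmdtools.derive_canonical_sites`, ...) and as individual subcommands:
`classify`, `de`, `call-targets`, `dependence`, `efficiency`,
`compare-groups`, `ejc-sites`, `ejc-quant`, `meta-exon`, `half-life`,
`simulate`, `run-all`.

## Documentation

`docs/methods.md` describes the models, conventions (coordinate systems, the
±1 dialects of the 50-nt rule and the canonical window), the synthetic
generator's assumptions and limits, and the numerical choices.
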