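# p73kit

Reusable, tested implementations of the bespoke computations behind a study
of p73 in skin biology: how much of each *TP73* isoform a tissue expresses,
which single cells co-express p73 and p63, which genes define the
fibroblast-to-keratinocyte reprogramming axis, and which of those genes
carry a nearby p63/p73 binding site — plus the closed-form staining, wound
and qPCR scores used alongside them. Every stage ships with a seeded
synthetic-data generator that plants a known truth, so the whole pipeline
is verifiable without downloading any external dataset.

## What it computes

**Isoform usage from splice junctions** (`p73kit.gene_model`,
`p73kit.isoform_usage`). *TP73* expresses N-terminal variants from two
promoters (TA from exon E3, ΔN from exon E3′, both splicing into E4) and
C-terminal variants (α, β, γ+ε, ζ, δ) by alternative 3′ splicing. Each
variant class has a diagnostic exon–exon junction, and reads spanning it
are the evidence. With junction read counts J:

    TA% = 100 · J(E3–E4) / [J(E3–E4) + J(E3′–E4)]

C-terminal class shares are computed the same way over the four junctions
leaving E10 (E10–E11, E10–E12, E10–E13, E10–E14); the E10–E11 share covers
both α and β and is split proportionally by the resolver junctions E12–E13
(α) and E12–E14 (β). Percentages are computed per sample, then averaged
across samples with the number of covered samples reported.

**Single-cell QC and co-expression** (`p73kit.sc_coexpression`). Cells with
fewer than 900 detected genes, fewer than 75,000 total counts, or more than
12% ERCC spike-in reads are excluded (boundaries strict). Counts are
log-normalized, value = ln(1 + 10⁴·count/total), and a cell expresses a
gene when its value is ≥ 0.5 (or ≥ 1 in TPM mode). Per-cluster cross-tabs
report the percentage of cells in each joint p73/p63 status.

**Reprogramming signature** (`p73kit.reprogram_signature`). PCA of a
sample × gene expression matrix; the fraction of variance on PC1, the top
250 genes by |PC1 loading|, and their partition into up- and down-regulated
sets along the reprogramming axis.

**Binding annotation** (`p73kit.peak_annotation`). A gene is called bound
when peaks from ≥ k of n cell types (default 2 of 3) mutually overlap, the
overlapping peaks are motif-positive, and the shared interval lies within
50 kb of the gene's TSS.

**Scores** (`p73kit.scoring`). H-score = 3·(%3+) + 2·(%2+) + 1·(%1+);
wound area = (length/2)·(width/2)·π; percent closure = 100·(1 − Aₜ/A₀);
ΔΔCt fold change = 2^−[(Ct_t−Ct_r)_sample − (Ct_t−Ct_r)_control].

## Worked example

Generate synthetic junction files for a skin-like isoform mix and quantify
them:

```sh
p73kit simulate junctions --seed 3 --out jdir
p73kit isoform-usage --exons jdir/exons.tsv --classes jdir/classes.cfg \
    --junctions jdir/junctions --dialect sjtab --out usage.tsv --summary summary.tsv
head -3 summary.tsv
```

```
statistic	mean_pct	n_defined
ta_pct	13.352509533611045	100
dn_pct	86.64749046638897	100
```

100 simulated samples at a junction depth of 2,000 reads recover the
planted promoter split (13.3% TA / 86.7% ΔN): ΔN is the dominant promoter,
and `n_defined` confirms every sample had junction coverage. The same
pattern holds for the other stages, e.g.

```sh
p73kit simulate reprogram --seed 3 --out rdir
p73kit signature --matrix rdir/expression.tsv --n-top 250 --transform none --out sig.tsv
```

```
PC1 variance fraction: 0.880 (68 up / 182 down in top 250)
```

The planted reprogramming factor owns 88% of the variance and PC1 finds
exactly that, with the top-250 genes split into the two signed sets.

Python API equivalents live under the same names
(`synthetic_data.simulate_junction_counts`, `isoform_usage.usage_per_sample`,
`reprogram_signature.pca_signature`, ...).

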