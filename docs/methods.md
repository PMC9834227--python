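# Methods

## Scope and model

`dropgeno` treats single-nucleus genotyping as a geometry-plus-counting
problem. A droplet 3' or 5' gene-expression library sequences a fixed-length
read (91 nt for the 3' chemistry, 90 nt for the 5' chemistry) anchored at
the captured end of each transcript. A known single-nucleotide variant is
therefore observable in a nucleus only if (i) a molecule of its gene was
captured in that nucleus, and (ii) the variant lies within one read length
of a capture point along the *spliced* mRNA. Capture points are the
annotated transcript end for the kit in use, plus any internal A-rich
stretch where the poly-dT primer can misprime.

All distances are computed in spliced transcript coordinates on one
canonical transcript per gene (the MANE transcript when a list is supplied,
otherwise the longest, ties broken by transcript id). Coordinates are
0-based: a variant at the cap site has `dist_5p = 0`, and
`dist_5p + dist_3p = L − 1` for a transcript of spliced length `L`. The
choice of spliced rather than genomic distance follows from the mechanism —
capture and read-off happen on mRNA — and matters for any multi-exon gene.

### Allele counting

`count_alleles` bins every passing read overlapping a variant position by
(cell barcode, UMI). A read passes if it is a primary alignment, has both CB
and UB tags, meets mapping-quality (default ≥ 30, chosen to exclude
multimappers in spliced alignments) and base-quality (default ≥ 20)
thresholds, and carries either the ref or the alt base at the position;
alignments whose deletion or splice gap spans the position are ignored. Each
UMI then contributes one vote by majority across its reads, with ties
discarded (an `any`-alt mode is available). Calls are three-way: `alt` if
any alt UMI, else `ref` if any ref UMI, else `no_call`; cells with both
alleles are reported `alt` — a real mosaic carrier transcribes both — and
flagged in a separate mask for audit. Coverage, used by all detection
statistics, is UMI-level (`ref + alt UMIs ≥ 1`), consistent with
UMI-deduplicated expression counting. Barcode GEM-well suffixes ("-1") are
normalized away on both sides of every join.

### Mispriming sites and effective distance

An internal capture site is a maximal A-homopolymer of at least `min_run`
(default 6) nt, or any `window` (default 10) nt interval with A fraction at
least `min_frac` (default 0.8); overlapping hits merge and are trimmed to
their A content, and anything within one window of the 3' end is excluded as
genuine poly-A-tail context. These thresholds are this package's operational
definition — the underlying observation in the field is qualitative — and
all three are exposed as parameters. A site at spliced position `c` is
usable by the 3' chemistry for a variant at `v` when `0 < c − v ≤
read_length` (the read runs `[c − read_length, c)`), and by the 5' chemistry
when `0 ≤ v − c < read_length` (read runs `[c, c + read_length)`). The
effective distance of a variant is the minimum of its kit-matched end
distance and its distance to the nearest usable site, and never exceeds the
former. The symmetric treatment of the 5' chemistry is a deliberate
modelling choice: mechanistically the template-switch read should start at
the cap regardless of where reverse transcription primed, but mid-transcript
variants are empirically recovered in 5' data too, and the symmetric model
reproduces that behaviour with one rule.

### Detection statistics

Detection fraction is the share of all cells on the barcode axis with UMI
coverage of the position. Stratifications report, per distance stratum
(≤ 100 bp, ≤ 1,000 bp cumulative, > 1,000 bp of the kit-matched end) or per
expression stratum (gene mean log-normalized expression > 0.1, > 5), the
fraction of variants detected in at least 5 % of nuclei (threshold
configurable); empty strata report NaN rather than 0. The false-positive
rate on a null panel — variants the sample cannot truly carry — is reported
per variant (share of null variants with ≥ 1 alt cell), because that is the
natural headline number, with a per-cell-call rate alongside; offenders
whose entire alt evidence is one nucleus are flagged. Per-cluster VAF is
`n_alt / (n_alt + n_ref)` over genotyped cells, with an "of all cells"
column emitted alongside since the denominators answer different questions.
All statistics are meant to be computed per sample and per chemistry;
pooling is the caller's explicit decision.

### Expression side

Normalization is `ln(1 + 10⁴ · count / cell_total)`; cells failing the
mitochondrial filter (strictly more than 5 % mito counts removed; exactly
5 % retained) or with zero counts are excluded first. Concordance between
two datasets is the Pearson r (and r²) of per-gene mean log-normalized
expression over the shared gene universe, reported both for all shared genes
and for genes expressed in both (the two can differ when many genes are
silent); per-cluster profiles give a cluster × cluster correlation matrix.
The marker efficacy score of a gene for a marked cluster is
`Σⱼ dⱼ² / Σⱼ dⱼ` with `dⱼ = p_marked − p_j`, where `p` is the proportion of
a cluster's cells expressing the gene above 1 CPM (strictly). The score is 0
when the denominator is 0 (uniform or absent expression) and 1 for perfectly
binary expression; when another cluster out-expresses the marked one the raw
value can leave [0, 1], in which case it is clamped and the raw value
logged, since the nominal range does not cover that case. Clustering itself
is always an input (a barcode → cluster table); only computations downstream
of it live here.

### Developmental origin

Cell types map to germ layers (a default map ships for the major brain cell
types: microglia and lymphocytes mesodermal; neurons, interneurons,
astrocytes, oligodendrocytes and OPCs ectodermal; a high-mito cluster
unknown). A layer carries the variant when its cell types sum to at least
`min_alt_cells_per_layer` (default 2) alt cells — a guard against
single-nucleus false positives, and this package's parameter rather than a
field convention. Two or more carrying layers classify the variant
`pre_gastrulation`, exactly one `lineage_restricted`, none
`insufficient_evidence`. The rule is monotone in added evidence.

## The simulator

The generator emulates exactly the features the analyses rely on:

- a miniature single-chromosome genome whose background sequence contains no
  A-run longer than two bases, so internal poly-A sites exist precisely
  where the configuration injects them;
- one canonical transcript per gene, with multi-exon structure and both
  strands guaranteed present so spliced arithmetic is always exercised;
- per-cell-type negative-binomial expression (default means log-uniform on
  [0.5, 5] with mild per-type variation, dispersion 2 — sparse,
  brain-snRNA-seq-like counts); optional single-type marker genes;
- a mosaic variant carried by a Bernoulli(`mosaic_fraction`, default 0.05 —
  a typical detectable brain-mosaic fraction) subset of cells, optionally
  restricted to chosen cell types; mutant cells place the alt base on
  *every* template molecule of the gene (an alt-homozygous simplification;
  a heterozygous carrier would halve alt coverage without changing any
  qualitative result);
- one capture event per molecule: an internal site (uniform among usable
  sites) with probability `mispriming_rate` (default 0.05), otherwise the
  annotated end, displaced inward by a truncated exponential offset of scale
  `capture_decay`. The default scale is 0 — capture exactly at the annotated
  end — which makes read geometry sharp: a variant is covered iff its
  kit-matched distance is strictly less than the read length. The
  exponential end-bias is available (and tested) for callers who want
  smeared capture, but no empirical distance distribution exists to fit it
  to, so the sharp default is the honest one;
- reads of exactly `read_length` nt (91/90 by kit), spliced across exon
  boundaries into multi-block alignments, written directly as a
  coordinate-sorted, indexed, CB/UB-tagged BAM (the pipeline consumes
  aligner output; simulating FASTQ plus alignment would add a dependency
  without adding coverage of any code path); per-base substitution errors at
  `error_rate` (default 0.001) applied independently per read after the alt
  template substitution; Poisson UMI duplicates (default rate 0.2); UMIs
  drawn uniformly from 4^10 per cell with collisions left uncorrected, as in
  real droplet chemistry.

Every stage is deterministic given `seed`: reference, cells and reads each
draw from an independent generator keyed on (seed, stage), and reruns are
byte-identical (BAMs are compared over their alignment text).

What the simulator does *not* model — ambient RNA, doublets, quality-score
variation, indels, isoform switching, barcode errors — bounds what the tests
can show: passing parameter-recovery tests demonstrates the pipeline's
arithmetic and geometry are right, not that real tissue meets these
assumptions. The three false-positive mechanisms in real data (sequencing
error, mispriming onto a homologous locus, index hopping) are represented
only by the first.

## Numerical and design choices

- Distance strata are cumulative (≤ 100 is a subset of ≤ 1,000), matching
  how the headline fractions are usually quoted.
- `detection_fraction` denominators are all cells on the barcode axis, which
  is the QC-passing cell list supplied as the whitelist.
- Degenerate inputs fail loudly: zero-total cells in normalization, empty
  null sets, empty call tables, missing BAM indexes and zero barcode overlap
  (the classic "-1" suffix mismatch) all raise with directed messages.
- Ties: UMI vote ties are discarded under majority consensus; marker-gene
  rank ties break lexicographically; canonical-transcript length ties break
  by transcript id.
- The pipeline runner isolates stages under separate output directories and
  records a JSON manifest (parameters, inputs, outputs, sha-256 checksums,
  seed, timing); reruns with the same seed reproduce all checksums.

## Problem sizes

The shipped configuration and the acceptance experiments use 250–5,000
cells, 1–12 genes and 1–24 variants per dataset. These sizes are chosen so
the binomial error bars on recovered fractions are a few percent — tight
enough to catch sign and off-by-one errors in geometry, which is what the
synthetic data is for — while the whole suite stays interactive.
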