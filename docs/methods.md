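# Methods

## Scope and coordinate conventions

`pleiogene` analyses cross-cancer (pleiotropic) GWAS signal for the four
hormone-dependent cancers — breast, endometrial, ovarian, prostate — by
combining variant positions, gene models, functional variant scores,
promoter capture Hi-C (PCHiC) interactions and TAD annotations. All
coordinates are 0-based half-open (`[start, end)`) internally and in BED
output; 1-based values appear only in GFF3 files and human-readable
messages. Book-ended intervals merge, matching `bedtools merge`. Unknown
chromosomes in input files are an error rather than silently dropped,
because silent loss would corrupt permutation counts.

## Clustering test

Variants on one chromosome are clustered by single linkage: consecutive
position-sorted variants join a cluster when their gap is ≤ `max_gap`
(default 100 kb, the semantics of `bedtools cluster -d`; a fixed-tiling
mode is available as a sensitivity alternative). The statistic is the
number of clusters containing ≥ 2 distinct cancer labels. The null
re-places every variant uniformly on its own chromosome, jointly for all
cancers each iteration, conserving per-(chromosome, cancer) counts exactly.
The empirical p-value is the fraction of null statistics ≥ the observed one
(no +1 smoothing by default; an add-one variant is provided); when that
count is zero the result is reported as the bound `p < 1/N`. The z-score is
`(observed − null mean)/null SD`, flagged undefined when the null is
degenerate.

Because the statistic is a small integer, the count-based p is
super-uniform under the null (it cannot be uniform, purely for
discreteness). Calibration is therefore assessed on the tie-broken
(randomized) p-value,
`p* = (#{null > obs} + U·(1 + #{null = obs})) / (N + 1)`, `U ~ Uniform(0,1)`,
which is exactly Uniform(0,1) whenever observed and null statistics are
exchangeable. The randomized p is exposed alongside the reported p and is
used only for calibration checks, never for inference output.

By default only index variants enter the clustering test (LD proxies can be
included by flag); region construction likewise extends index variants
only.

## Region construction

Each cancer's index variants are extended to `[pos − flank, pos + flank + 1)`
(flank default 0.5 Mb), clamped at chromosome ends (variants near telomeres
still seed regions) and merged per cancer. Multi-cancer regions are the
maximal segments where ≥ `min_cancers` (default 2) cancers' merged
intervals all cover every base; contiguous qualifying segments are fused
into a single numbered region even when the contributing cancer pair
changes along the segment, and the attached cancer set is every cancer
overlapping the fused segment. Independent-signal counts per (region,
cancer) are distinct `signal_id`s whose index variant lies in the region.

## Variant annotation

Per (variant, gene) pair the location class is assigned with the total
precedence exon > promoter > intron, where the promoter is TSS ± 2 kb with
inclusive boundaries and the TSS is strand-aware (gene start on `+`, gene
end on `-`). A variant is intergenic only with no gene context at all; it
can simultaneously be a promoter variant of one gene and intronic in
another. For variant-level tallies a summary class uses the same
precedence across genes, giving a strict partition
(exonic / promoter / intronic / intergenic).

Score filters operate on externally computed annotations (computing VEP,
SpliceAI, MaxEntScan, RegulomeDB or ChromHMM is out of scope; their outputs
are inputs):

| filter | rule | note |
|---|---|---|
| coding | VEP class ∈ {frameshift, missense, synonymous, utr5, utr3} | carried from the score table, not recomputed |
| splice-altering | SpliceAI Δ ≥ 0.2 **or** \|MaxEntScan\| > 0 | OR of the two tools; applied to intronic variants |
| regulatory | RegulomeDB probability **strictly** > 0.55 | 0.55 is the genome-wide median of the score |
| chromatin support | any relevant biosample in an active state | active set configurable, default TSS/enhancer classes (TssA, TssFlnk\*, EnhA\*, EnhG\*, EnhWk) |

Missing scores never qualify — conservative by design, so absent evidence
cannot create candidates. The MaxEntScan column's exact meaning (raw score
vs reference/alternate difference) is left to the data provider; the filter
takes the absolute value of whatever is supplied.

## PCHiC linking and the TAD test

Interactions are bait/other-end restriction-fragment pairs with a CHiCAGO
confidence score; score ≥ 5 (inclusive) is high confidence. Replicate
concordance is Spearman's ρ over the union of fragment-pair keys with
missing counts as zero, undefined when fewer than three keys are shared.

A distal link (variant → gene) requires: summary class intergenic (an
intronic-distal mode is available but off by default, since a variant
inside one gene looping to another's promoter is a different mechanistic
claim), the regulatory filter passed, and the variant's fragment being the
other end of a high-confidence interaction whose bait overlaps the gene's
promoter. Cell lines aggregate over supporting interactions; any cell line
qualifies (links carry the cell-line set so users can post-filter by
matching tissue). "Within TAD" uses fragment midpoints — fragments can
straddle TAD boundaries and the midpoint is the least surprising
tie-break.

The TAD enrichment test restricts to TADs whose midpoint lies in a
multi-cancer region and interactions with both fragment midpoints inside
one region; the statistic is the number of such interactions with both
midpoints inside one TAD. The null circularises each region: its TADs are
rotated by a uniform random offset modulo the region length, a TAD pushed
past the region end wrapping to the region start, so every TAD's size is
conserved exactly. **The rotation is joint** — one common offset per region,
preserving the observed TAD mosaic. An independent-offsets mode (each TAD
shifted separately, as boundary-shuffling pipelines do) is provided for
comparison but is not the default, for a statistical reason: independently
shifted TADs overlap and leave gaps, which both deflates the null mean
(an interaction inside two overlapping TADs still counts once) and inflates
the null variance relative to the observed tiling; in generator experiments
with no planted TAD effect the independent-shift p-values were grossly
non-uniform, while the joint rotation is exactly exchangeable under
interactions placed independently of TADs and empirically calibrated.
TADs larger than their region cannot be rotated size-preservingly; the
operation errors by default and can be told to skip them (the pipeline
skips, with a log line). Interactions spanning two regions are attributed
to the bait midpoint's region.

## Candidate gene calling

Evidence categories per (gene, cancer): coding classes from exonic
variants; `promoter`; `splicing` (intronic + splice filter);
`intronic_regulatory` (intronic + regulatory filter);
`distal_reg_within_tad` (distal link with within-TAD support). A gene with
qualifying evidence from ≥ 2 distinct cancers is a candidate; presence of a
single qualifying variant suffices (no variant-count weighting — the rules
are presence/absence). Every candidate carries an audit trail mapping each
(cancer, category) to supporting variant IDs. A coding-only mode
(exon/promoter/splicing channels) yields a strict subset of the full call,
mirroring the initial-versus-integrated two-stage structure of the
analysis. lncRNA calling applies identical rules with biotype lncRNA and a
single `exon` category in place of the VEP coding classes. Genes
overlapping several regions are reported with all their region IDs.
ChromHMM support is aggregated over a gene's evidence variants,
restrictable to the biosamples matching the evidencing cancers.

Enrichment for a gene category (COSMIC census membership, drug targets)
uses the one-sided (greater) Fisher's exact test with the background of all
protein-coding genes at the multi-cancer regions; both the sample odds
ratio `ad/bc` (flagged undefined when `bc = 0`) and the conditional-MLE
odds ratio are reported. For a z-scaled effect display, a matched
resampling null draws, per region, as many genes (without replacement) from
that region's gene pool as the region contributed candidates, 10,000 times
by default; a label-permutation null over the background is the alternative
mode.

## Synthetic data generator

The generator emulates the study conditions; all outputs are pure functions
of (config, seed), byte-identical on repetition.

| parameter | default | what it controls |
|---|---|---|
| `n_chromosomes` × `chrom_length` | 8 × 50 Mb | genome size (scaled-down genome; see limitations) |
| `variants_per_cancer` | 196/17/60/258 | the four cancers' index-variant counts |
| `pleiotropy_fraction` | 0.5 | probability a non-breast variant is co-located near a random breast variant |
| `co_locate_window` | 50 kb | co-location window |
| `n_genes`, `lncrna_fraction` | 400, 0.2 | gene models (2–10 exons, random strand, TSS consistent with strand) |
| `fragment_mean_length` | 4 kb | exponential-ish restriction-fragment tiling (no gaps/overlaps) |
| `tad_mean_length` | 500 kb | TAD tiling (uniform 0.5–1.5 × mean) |
| `interaction_count` | 1000 | promoter-baited interactions |
| `interaction_decay_mean_fragments` | 75 | geometric distance decay of other ends (≈ 300 kb), long enough that the within-TAD fraction is informative |
| `within_tad_enrichment` | 3 | odds multiplier for same-TAD pairs (cross-TAD proposals accepted with probability 1/factor) |
| `regulatory_fraction` | 0.3 | fraction of noncoding variants drawn above the 0.55 probability threshold |
| `score_pass_fraction` | 0.8 | fraction of interactions drawn above CHiCAGO 5 |

An optional in-silico HindIII digest (`digest_sequence`) cuts a supplied
sequence at every AAGCTT occurrence (A^AGCTT) for users who want
sequence-derived fragment maps.

**Planted-truth mode** designates `n_true_genes` true pleiotropic targets.
Each true gene receives a promoter variant for one cancer (placed upstream
of the TSS, inside the ±2 kb window, with active chromatin states) and, for
the second cancer, either an exonic missense variant or — every third
gene — an intergenic regulatory variant (probability 0.9) inside the gene's
TAD within 400 kb of the TSS, looped to the promoter fragment by a
high-confidence interaction. All planted variants are index variants, so
each pair also seeds a multi-cancer region around its gene; planted
variants consume their cancer's quota, keeping totals exact. In planted
mode the default background `pleiotropy_fraction` is 0.1: cross-cancer
co-location is modelled as driven by the planted target genes, with
background sharing residual. COSMIC/drug-target membership is assigned at
10% background rate and 50% among true genes, giving the enrichment tests
a real signal to find. Recovery (precision/recall of called candidates
against the truth table) is the headline synthetic benchmark.

What the generator does **not** emulate: LD structure (every variant is its
own signal; proxies are not simulated), realistic gene density or
clustering, sequence content, biological TAD nesting/hierarchy, and
cell-line-specific interaction landscapes. Passing tests therefore show
the pipeline's logic and statistics are correct under controlled
conditions, not that real-data results would be identical.

## Numerical choices and problem sizes

- Permutation defaults: clustering 10⁶ in the CLI stage default (the
  pipeline driver and tests use 10³–10⁴); TAD test and matched resampling
  10,000. Test-suite calibration experiments use 100–200 generator
  replicates at 300–500 permutations each, and power checks use 10,000
  (clustering) and 2,000 (TAD) permutations — sizes chosen to keep the whole
  suite a few minutes on one CPU while leaving Monte-Carlo error well below
  the asserted margins.
- The synthetic genome is 400 Mb (8 × 50 Mb) rather than 3.1 Gb: variant
  density is correspondingly higher than genome-wide reality, which makes
  chance co-location (and hence the permutation nulls) more demanding, not
  less; all calibration checks are run at this density.
- The clustering null is evaluated with a vectorised counter (sorting
  super-positions with inter-chromosome spacers wider than `max_gap`), so a
  10⁶-permutation run on ~530 variants takes on the order of a minute.
- Degenerate nulls (SD = 0) yield flagged-undefined z with a still-valid
  empirical p; empty inputs yield observed 0 and p = 1.
- Ties in sorting are harmless: coincident variants always share a cluster,
  and counting is input-order invariant (asserted by test).

## Known limitations

- The joint-rotation TAD null conditions on the observed TAD mosaic; it
  tests interaction placement relative to boundaries, not boundary
  placement itself. The independent-shift mode matches published
  boundary-shuffling descriptions but is not calibrated (see above) — its
  p-values should be read qualitatively.
- Fisher's exact test treats genes as exchangeable within the background;
  gene length and promoter bait density are not modelled as covariates
  (the matched resampling null controls for per-region gene counts only).
- UTR classes come from the score table (as VEP emits them), not from the
  gene models, so a UTR variant's location class is exonic while its
  evidence category is utr5/utr3.
- Candidate calling attributes a multi-region gene's matched-null draw to
  its first region.
- LD-aware shuffles and annotation-matched nulls (GAT/regioneR style) are
  out of scope by design.
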