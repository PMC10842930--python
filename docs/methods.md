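# Methods

## Data model

A read is an *exon chain*: ordered, disjoint genomic blocks (0-based
half-open) plus the junctions between them. Junctions are stored as the
genomic interval of the spliced-out intron `(left, right)`; donor and
acceptor are strand-dependent views (plus strand: donor = `left`). An
annotation holds genes, transcripts and exons with derived per-gene donor
sets, acceptor sets, junction sets and merged exonic intervals; per-gene
sets are the union over that gene's transcripts. Chains are built from
SAM/BAM records: M/=/X/D CIGAR operations extend a block, N opens a new
one, I/S are ignored for the reference projection. Junctions are taken
from the alignment verbatim — the pipeline assumes upstream junction
correction (or error-free simulation) and uses exact coordinate matching
everywhere, which keeps every downstream count reproducible.

## Isoform catalog and classification

Multi-exon chains merge when chromosome, strand and the full junction
chain agree; the representative spans the union of member 5′/3′ ends, so
FSM/ISM calls are invariant under terminal-end variation. Mono-exon
chains merge when their blocks overlap. Isoforms with fewer than
`min_support = 2` reads are dropped.

Classification precedence: (1) *fusion* when exonic blocks overlap exons
of two or more same-strand genes whose annotated spans are mutually
disjoint — the disjointness requirement keeps overlapping-gene loci from
spuriously calling fusion; (2) assignment to the same-strand gene with
maximal exonic overlap (ties: smaller span, then gene id — deterministic
output), then FSM if the junction chain equals some transcript's chain,
ISM if it is a contiguous proper sub-chain (the intron-retention-free
notion: non-contiguous subsets fall through), NIC if all donors and
acceptors are annotated for the gene, else NNC; (3) *antisense* on
opposite-strand exonic overlap only; (4) *genic* inside a gene span with
no exonic overlap; (5) *intergenic*. Mono-exon isoforms: ISM when fully
inside one annotated exon, genic inside a gene, else
intergenic/antisense by the same rules (a declared choice; references
differ on mono-exon handling).

## Events and quantification

Events are discovered from the catalog, not from raw reads, so
single-read noise below the support threshold cannot create events.
SE: an internal exon whose flanking junction pair occurs consecutively in
some isoform while the direct (skipping) junction is also observed.
A5SS/A3SS: two observed junctions sharing exactly one boundary; the
shorter intron is the inclusion form; which label applies follows from
strand (shared left boundary on plus strand = shared donor = A3SS).
Junction pairs already explained by exon skipping are not re-emitted as
alternative-site events. IR: any annotated or observed junction whose
intron is fully covered by a single block of some isoform.

Read assignment per event returns inclusion, exclusion or ambiguous; a
read contributes at most once per event. IR inclusion (retention)
requires one block to cover the intron plus `min_overhang = 5` bases on
both sides, which also stops terminal read blocks from calling retention
unless they clear both boundaries — a guard against internal-priming-like
truncation artifacts. PSI (PIR for IR) is
`inclusion / (inclusion + exclusion)` per cell type, undefined below
`min_reads = 10`; reads without a barcode, or with a barcode absent from
the cell map, are excluded from cell-type quantification (they still
count for the catalog and for coordination).

## Differential splicing and variability

Counts are pooled within each cell-type group (reads treated as
independent; no per-cell overdispersion model — this matches the
read-level PSI definition). Events with ≥ 10 informative reads in both
groups are tested on `[[incA, excA], [incB, excB]]` with a two-sided
Fisher exact test; BH adjustment is applied per comparison; a call
requires `|ΔPSI| ≥ 0.05` and adjusted `p < 0.05`. The same machinery
applied to IR events yields differential intron retention (ΔPIR at the
same cutoffs). Variability per event is the max minus min PSI over cell
types with defined PSI (≥ 2 required): high ≥ 0.75 (the switch-like
regime), medium ≥ 0.25, low otherwise; the 0.25 boundary is a package
choice, the 0.75 cutoff is the standard switch-like threshold. The set of
eligible cell types is an explicit parameter.

Statistical primitives: Fisher exact p and the sample odds ratio ad/bc
(scipy); BH/BY step-up (statsmodels; BY multiplies by the harmonic
number, used where arbitrary dependence across pairs is expected);
Pearson r with the t-based two-sided p (scipy). Mann–Whitney U is
computed from midrank sums; for pooled n ≤ 12 the p value is the exact
permutation probability of `|U − n_x n_y / 2|` at least as extreme
(our own enumeration — the scipy exact method declines ties), otherwise
the normal approximation with tie and continuity corrections.

## Exon-pair coordination

Eligible cassettes have pooled support ≥ 20 reads, pooled PSI strictly
in (0.05, 0.95), and do not overlap the gene's genomically first or last
annotated exon. For every eligible pair within a gene, reads with an
unambiguous call at both exons fill the 2×2; pairs never co-observed are
not tested. The p value is Fisher's exact test on the raw counts; the +1
pseudocounts enter only the reported odds ratio, so significance and
effect size are decoupled exactly as the decision rule separates them.
FDR is Benjamini–Yekutieli across all tested pairs; classes at
`|log2(OR)| ≥ 1` and `FDR < 0.001` (log base 2 is the package's choice
where "log-odds ratio" is ambiguous; the base is a parameter). No
adjacency constraint is imposed on mutually exclusive calls.

## Intron features

Splice-site strength is a PWM log-odds score in bits over the standard
windows (donor −3..+6 = 9 nt; acceptor −20..+3 = 23 nt), trained from
all annotated junctions with +1 pseudocounts per base and position,
against genome-wide mononucleotide background; windows are extracted
strand-correctly (reverse-complemented on minus-strand genes). Training
fails below 50 usable sites. The scorer is pluggable: any object with the
same window contract (e.g. true maximum-entropy tables) can replace it;
scores are monotone "strength" measures, not calibrated to any external
score scale. GC is computed over the exact intron interval with N bases
excluded from the denominator. Conservation is the mean of a per-base
track over covered bases, with the covered fraction reported; any
bedGraph-style track works. Group comparisons use the two-sided
Mann–Whitney U with group medians reported.

## Enrichment

All interval logic is half-open with overlap meaning ≥ 1 shared base.
Gene-set enrichment intersects the target with the universe and requires
the foreground to be a subset of it. DNM burden compares probands vs
siblings on {inside regions, outside}; group totals are the supplied
variant lists (the denominators are explicit inputs — they cannot be
inferred from region counts). Flank expansion (default 300 bp for
flanking-intron burden, 0 for exonic burden) is clipped at neighboring
annotated exon boundaries so flanks stay intronic. The splice-affecting
variant filter keeps score strictly > 0.2 within 400 bp of an annotated
exon boundary; splice-effect scores are consumed as input, never
computed. ΔPSI concordance between two matched comparisons reports
Pearson r and the sign-concordance fraction with exact zeros excluded.

## Simulator

The generator defines the study conditions; its defaults are fixed, not
tuned. Genome: 4 chromosomes, 100 genes on both strands, 5–8 exons of
80–250 bp, introns 150–600 bp, all canonical GT–AG, donor/acceptor
windows imprinted from consensus (`CAG|GTAAGT`, pyrimidine tract + AG)
at match probability 0.90/0.85. Five cell types in two classes emulate a
neural differentiation experiment: ExN 0.25 and InN 0.20 (neurons), NPC
0.25 and DivNPC 0.20 (progenitors), OPC 0.10.

Planted structure, with read depths chosen so each analysis sees its
stated operating point: 12 differential cassette exons (PSI 0.50 in
neurons vs 0.20 in progenitors, ΔPSI = 0.30, ~2400 reads/gene giving
≈ 500 informative reads per pooled group); 30 null cassettes (PSI 0.50
everywhere, 320 reads); 8 coordinated pairs (marginals 0.5, joint odds
ratio θ = 16, ~360 reads giving 200+ unambiguous spanning reads) and 12
independent pairs (θ = 1); 12 retained introns (PIR 0.40 in neurons vs
0.05 in progenitors) that are simultaneously planted shorter (80–220 bp),
GC-richer (0.58 vs 0.45 background) and with weaker donors (consensus
match 0.45); 26 plain genes. Joint inclusion is sampled by solving
`p11(1−pA−pB+p11) = θ(pA−p11)(pB−p11)` for the cell probability inside
the Fréchet bounds (θ = 1 reduces to independence; pA = pB = 0.5, θ = 16
gives p11 = 0.4 exactly). The coordinated pair's two cassettes are
non-adjacent so every combination isoform leaves both exons' flanking
junctions callable.

Noise: 25% of reads are 5′-truncated by whole exons (creating ISM
chains), 2% receive one donor shifted 4–12 bp off every annotated site
(creating NNC), and 45% of reads are emitted without a barcode,
emulating the partial assignment rate of droplet-barcoded long-read
libraries. Reads are error-free at the base level and written directly
as coordinate-sorted SAM with exact CIGARs: the package's scope begins
at aligned reads, so a sequencing-error model would only test the
upstream aligner. Every isoform structure the noise-free generator can
emit (full, skip, retained, pair combinations) is annotated in the GTF,
which makes the noiseless closure property exact: all multi-exon
isoforms must classify FSM. Everything is deterministic given the seed;
truth tables record per-event parameters and expected calls.

What the simulation does not emulate — and hence what passing tests do
not show: base-call and alignment error, junction wobble, non-canonical
splice sites, internal priming artifacts, per-cell count structure and
expression variation, transcriptome-scale gene density, and overlapping
gene loci. Recovery rates on this simulator validate the statistical
machinery and bookkeeping, not robustness to upstream noise.

## Numerical choices and degenerate inputs

Exact junction matching throughout (a junction-correction window exists
in the I/O layer but defaults to 0). Ties in gene assignment broken
deterministically. Fisher on empty margins returns p = 1; the sample
odds ratio may be 0, infinite, or NaN (0/0) and is reported as such; the
coordination odds ratio is always finite and positive by construction.
Events with all-zero pair matrices are dropped before testing.
All-identical Mann–Whitney samples return p = 1 with a warning. GC of an
all-N sequence and conservation of an uncovered interval are undefined
and flagged rather than zeroed. Mono-exon truncation products are
retained and merge by overlap.

## Pipeline problem sizes

The default simulation (100 genes, ~53k reads) runs the full pipeline in
a few seconds on one CPU; the statistical-oracle sweep (all ~136k
2×2 tables with total ≤ 40) and the 100-replicate feature study complete
in about a minute together. These sizes were chosen to make the planted
operating points (500 reads/group, 200 spanning reads) exact while
keeping a complete run interactive.

## Known limitations

FLAIR-style isoform-model quantification is replaced by a defined
per-event 2×2 Fisher test on pooled counts — reproducible and
oracle-checkable, but blind to isoform-level dependencies between
events. IR is called from contiguous long-read coverage rather than
short-read intronic depth ratios; the two metrics agree in direction but
not numerically. The PWM scorer shares windows and monotonicity with
maximum-entropy splice models but not their score scale. Alternative
first/last exons and polyadenylation events are out of scope, as are
barcode whitelisting, UMI deduplication and alignment itself.
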