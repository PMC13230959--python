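# Methods

This note documents the models and procedures implemented in `phagehost`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Intergenomic similarity and taxon clustering

Two genomes' similarity is the VIRIDIC-style quantity

    sim(a, b) = 100 * (I_ab + I_ba) / (L_a + L_b),

where `I_xy` is the number of identically matched nucleotides of `x`
against `y` summed over a non-overlapping set of local alignment fragments.
The alignment engine is a deterministic seed-and-extend: exact k-mer
anchors (`k = 11`) are grouped by diagonal, chained when separated by at
most 100 bp, extended outward through exact matches, and scored by direct
character comparison (`N` never counts as identical). Fragments shorter
than 30 bp are discarded (suppresses spurious micro-matches); fragments are
then selected greedily by descending identical-position count, with later
fragments trimmed to the uncovered remainder of both genomes and recounted,
so no position is double-counted. All three constants are keyword
arguments.

This engine targets substitution-level divergence on co-linear genomes, the
regime the simulator produces; it searches the forward strand only and is
verified in the tests against an exhaustive dynamic-programming oracle on
planted-block fixtures. No claim is made of numeric agreement with a
blastn-based pipeline on real, rearranged genomes — only threshold-level
agreement (which side of 70/95 a pair falls on) within the simulated
divergence bands.

Genus and species ranks are two cuts of one complete-linkage dendrogram on
the distance `100 − sim`: genera at distance 30 (similarity ≥ 70, inclusive)
and species at distance 5 (similarity ≥ 95, inclusive). Complete linkage
means every pair inside a cluster meets the threshold. Because both ranks
cut the same tree, species nest inside genera by construction; the
invariant is asserted anyway. Cluster labels are assigned deterministically
by the lexicographically smallest member ID; merge-order ties are resolved
by scipy's deterministic linkage implementation.

SNP distance between two aligned sequences counts positions where both
characters are in `{A,C,G,T}` and differ; gap and `N` columns never count.

## Clade-diagnostic SNP scoring and primer design

Given a strain × position allele matrix and clade labels, each polymorphic
site is scored for a target clade with

    sensitivity = (# target strains carrying alt) / (# target strains called)
    specificity = (# non-target strains not carrying alt) / (# non-target strains called)

Missing calls (`N`, `-`) are excluded from numerator and denominator. The
alternative allele is the modal allele among called target strains, the
reference allele the modal allele among the rest. "Optimal" retention is
interpreted strictly — core-gene sites with sensitivity and specificity
exactly 1.0 — because only that guarantees a clade-diagnostic amplicon;
`min_sensitivity`/`min_specificity` relaxations are exposed for noisier
panels.

Retained SNPs become nodes of a proximity graph with edges between
same-replicon sites at most 300 bp apart (the maximal amplicon length;
edges farther apart cannot share an assay), weighted by bp separation. The
graph delimits candidate windows; edge weights are not otherwise used in
selection.

Primer design enumerates forward/reverse windows of 25–40 bp containing at
least two diagnostic positions, paired so the amplicon (forward-primer
start to reverse-primer end, primers included) spans 180–300 bp, with an
18–30 bp probe window strictly between the primers containing at least one
diagnostic position. Enumeration is restricted to canonical windows
anchored at a diagnostic position (starting on one or ending immediately
after one): any window can be slid onto an anchor without losing contained
positions, so the maximal-count, tightest-geometry representatives are all
retained. Candidates are ranked by total diagnostic positions in the two
primers (descending), then amplicon length (ascending), then leftmost
start; infeasibility yields an empty list, never an error. Primer
thermodynamics (Tm, GC clamp, dimers) are intentionally out of scope — the
criteria implemented are purely positional — and every emitted candidate is
flagged `thermodynamics=unchecked`.

Phage assays use presence/absence instead: marker families present in 100%
of the target phage set and 0% of the complement.

## Pangenome, RGPs and the MGE census

Gene families present in ≥ 90% of genomes (inclusive) are persistent.
Regions of genomic plasticity (RGPs) are re-implemented directly from their
definition — maximal runs of consecutive non-persistent genes per contig,
kept when spanning ≥ 3 kb and ≥ 3 genes — rather than wrapping a pangenome
tool; the two minima mirror that tool class's defaults and are
configurable.

Each RGP receives exactly one MGE class by fixed flag precedence:
plasmid origin → complete satellite segment → prophage (viral call, or
quality in {complete, high, medium, low} with ≥ 1 viral gene) → integrase →
unclassified. The precedence follows the order the rules are conventionally
stated; exclusive classes make the class counts additive. Classification is
total, order-invariant and idempotent. Detection flags themselves (plasmid
origin, satellite segments, viral quality tiers, integrases, defense
systems) enter as pre-computed annotations — emulated by the population
generator — because detection is external-model territory; the computation
here is the census and its statistics.

Predicted prophages are retained only strictly above class-specific size
floors: 25 kb (*Caudoviricetes*), 10 kb (*Tectiliviricetes*), 4 kb
(*Faserviricetes*); unknown classes are skipped with a warning.

Cargo screening takes the best local-alignment hit per query protein and
applies per-database floors: 70% identity / 50% coverage for metal/biocide
resistance and virulence factors, 30% / 50% for antimicrobial resistance.
Coverage is the aligned fraction of the reference sequence. Densities are
hits per kbp of region; the non-mobile genome is the genome minus all RGP
spans.

Group densities are compared with a tie-corrected Kruskal–Wallis H-test;
pairwise contrasts use Dunn's rank-sum z-tests with Benjamini–Hochberg
adjustment over all pairs (the step-up property is checked against a
from-scratch oracle in the tests). The compact letter display uses
insert-and-absorb over the pairwise non-significance graph at α = 0.05,
with groups ordered by descending median so lettering is deterministic.

## wGRR and plasmid inference

Protein identity is computed by global alignment (unit match score, zero
mismatch score, gap open −0.5, extend −0.1) as matches over alignment
columns — a deterministic definition chosen because the quantity must be
exactly reproducible in tests. Candidate hits below identity 0.35 are
discarded before bidirectional-best-hit resolution (common wGRR practice;
configurable). A pair is a BBH when each protein is the other's unique best
hit, ties broken lexicographically; the result is a partial matching,
asserted on every call. Then

    wGRR(A, B) = 100 * sum over BBH of identity / min(|A|, |B|),

using the minimum-cardinality denominator. A plasmid family is present in a
strain iff its best wGRR against the family's references is strictly
greater than 50; the argmax reference (lexicographic on ties, logged) is
the closest plasmid. Read remapping to reconstruct hypothetical plasmids is
out of scope: the operations consume protein repertoires directly. Copy
number is the mean element read depth divided by the mean chromosomal
depth.

## ddPCR quantification and time series

Wells with fewer than 10,000 droplets are rejected (inclusive at exactly
10,000). Quantification inverts Poisson partitioning: with positive
fraction `f`, `λ = −ln(1 − f)` copies per droplet, concentration
`λ / droplet_volume` and `copies_per_reaction = concentration ×
reaction_volume`. Defaults: droplet volume 0.85 nL, reaction volume 20 µL,
5 µL of template per reaction for the copies/mL conversion — typical
instrument values, all configurable. The limit of quantification defaults
to 1 copy per reaction. Saturated wells (all droplets positive) are flagged
and quantified with a half-droplet correction; callers should treat them as
lower bounds.

Replicate summaries are geometric: mean and 95% Student-t interval on the
log10 scale, back-transformed. Non-positive values cannot enter a log mean;
by default they are excluded and counted, with an optional
substitute-at-LOQ mode. Summaries whose geometric mean falls below the LOQ
carry a flag that suppresses error bars downstream rather than fabricating
them.

Series statistics operate on per-date means of log10 quantifications across
replicate oysters. Autocorrelations use the unadjusted (n-denominator)
estimator to a maximum lag of 10 sampling dates; partial autocorrelations
come from the Levinson–Durbin recursion. Cross-correlations are computed
for lags −10…+10 with `r[k] = corr(a_t, b_{t+k})`, so a positive argmax lag
means the second series follows the first; `ccf(a,b)[k] = ccf(b,a)[−k]`
exactly. The Lomb–Scargle periodogram uses the floating-mean model on
ordinal day numbers with standard normalization, frequencies from `1/T` to
`n/(2T)` at grid step `1/(5T)` (oversampling 5). A white-noise false-alarm
level is provided via the single-frequency beta law with an effective
number of independent frequencies `n_freq/oversampling`. Trends are cubic
smoothing splines with the penalty chosen by generalized cross-validation
over a logarithmic grid (the smoother trace is computed exactly from its
action on unit vectors, so the chosen parameter can be reported).
Coefficients of variation are sd/mean of the log10 series — the scale on
which the other series statistics operate.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analyses assume, at
desk scale, with site-independent substitutions uniform over the three
alternative bases and no indels — which keeps every similarity and SNP
oracle exact.

*Bacterial population* (defaults: 8 clades × 8 strains, 20 core genes of
900 bp, 6 private SNPs per clade, background substitution rate 10⁻⁴/site):
every clade carries private SNPs at globally disjoint positions, fixed
within the clade and absent outside it, so their truth sensitivity and
specificity are 1 by construction. The default `clustered` SNP layout
places each clade's SNPs in two nearby windows of one core gene — the
SNP-dense geometry a diagnostic-assay designer looks for — so primer design
is feasible end-to-end; a `uniform` layout is available. The first clade is
seawater-associated and the rest oyster-associated, with mobile-element
counts drawn Poisson at 1 vs 6 per strain respectively, emulating the
habitat asymmetry in MGE load; the class mix of planted elements (32%
plasmid, 44% prophage, 5% satellite, 19% integrase among classified)
follows the proportions of a coastal-Vibrio MGE census. Accessory gene
blocks appear in the gene-order and annotation tables (each ≥ 4 genes,
≥ 3 kb) but not in the FASTA sequences, which carry the core genome only.

*Phage family* (defaults: 16 genomes of 10 kb, genera of 4 split into
species of 2): a star phylogeny per species nested in a star per genus.
Within-species divergence defaults to 0.02 substitutions/site (pairwise
similarity ≈ 98), within-genus to 0.15 (≈ 85), and genera are independent
random sequences (similarity ≈ 0); configurations whose bands cross the
70/95 thresholds are rejected. Per-genus private gene families are emitted
for marker-gene selection.

*ddPCR series* (defaults: 35 uneven dates over a 79-day summer season, 10
replicate oysters per date, log10 mean 3.0, log10 sd 0.5, LOQ 200
copies/mL, 15,000 droplets of 0.85 nL): replicates are log-normal around a
constant, sinusoidal, or lag-coupled trend; coupling uses a white-noise
driver so the cross-correlation peak is unambiguous at the planted lag.
Droplet counts are Binomial(total, 1 − e^(−λ)) — exactly the model the
quantification inverts, which is what makes the 2%-recovery check a test of
the inversion, not of distributional luck.

Not emulated: recombination, indels, genome rearrangement, coalescent
genealogies, read-level sequencing error, assembly artefacts, and real
annotation-tool false calls. Passing tests therefore demonstrate
correctness of the computations under their stated models, not robustness
to those real-data complications.

## Problem sizes and numerical choices

Test and acceptance runs use reduced problem sizes chosen to exercise every
code path with comfortable statistical margins: 12–16 phage genomes of
4–10 kb (partition recovery over 20 seeds), 24–100 bacterial strains,
200-well Monte-Carlo for the Poisson inversion, 50–100 seeds for lag
recovery, and 2,000 replicates for the Kruskal–Wallis and
coverage calibrations. Degenerate inputs (constant series, empty
repertoires, zero-length regions, unsorted gene tables, misordered
thresholds) raise validation errors rather than propagating NaNs; the few
undefined-but-legal cases (single usable replicate, saturated wells) return
flagged results instead.

## Known limitations

- The similarity engine assumes co-linear, forward-strand homology; it will
  underestimate similarity for inverted or shuffled genomes.
- Global-alignment protein identity with unit scores is not a
  substitution-matrix similarity; wGRR values are comparable within this
  package but not bit-for-bit with aligner-based pipelines.
- Primer design checks geometry only; candidates must still pass
  thermodynamic screening elsewhere.
- The compact letter display depends on the adjusted-p threshold alone; it
  does not re-run the omnibus test per subset.
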