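# Methods

## The assay being modelled

COBRA-seq reduces a methylome to counts at restriction sites. Bisulfite
treatment deaminates unmethylated cytosine to uracil (read as T);
5-methylcytosine resists and reads as C. Digesting bisulfite-converted DNA
with an enzyme whose recognition site contains a cytosine (TaqI, T/CGA)
therefore cuts only where that cytosine was methylated. Library chemistry
(dual-biotin on the adapter-2 end, streptavidin depletion after digestion,
ligation of adapter 1 to the CG overhang) removes uncut molecules, so the
library contains only methylated sites and read counts measure *relative*
methylation per site. This package implements the computational side:
site prediction, read cleaning and counting, feature accounting, the
count-model simulation, and a synthetic-data generator that emulates the
protocol.

## In silico digestion

**Conversion model.** A `MethylationAssumption` declares which cytosine
contexts are treated as methylated and hence conversion-protected. The
vertebrate default protects `CG`; `ALL` (protect everything) serves CpN
enzymes such as CviQI or Sau3AI in organisms with non-CpG methylation;
`NONE` models fully unmethylated DNA. Context is read strand-locally from
the next 1–2 bases (H = A/C/T); an `N` or the sequence end never completes
a context, so such cytosines convert — a conservative, deterministic
choice. Conversion is idempotent for any fixed assumption.

**Site scanning.** Both strands of the converted genome are scanned for
IUPAC recognition matches (overlapping matches included; genome `N`
matches no recognition letter). Conversion can create sites (plus-strand
CCGA → TCGA) and such creation is generally strand-asymmetric: the minus
strand at the same locus reads TCGG and has no site. CpG dyads under each
occurrence footprint are extracted from the *unconverted* sequence and
identified by their plus-strand C position, counted once however many
sites list them.

**Coordinates.** 0-based, half-open everywhere internally; BED/bedGraph
output is 0-based half-open and SAM conversion happens at the pysam
boundary. A cut site's `coord` is where a kept read's proximal base
aligns. For an occurrence starting at `s` with recognition length `L` and
top-strand cut offset `k`: forward reads start at `s + k` (first remnant
base) and reverse reads end (inclusive, rightmost aligned reference base)
at `s + L - 1 - k`. The reverse formula follows from the duplex cut
geometry of palindromic, symmetrically cutting enzymes: for TaqI the
bottom-strand remnant's 5' base sits at the dyad's G, so the read's last
three reference-forward bases are the plus-sense TCG ending on that G.
All shipped cleavable enzymes are palindromic symmetric cutters; Hpy99I
(CGACG/, empty remnant) is included for site accounting only and is
refused by the cleaner and the read simulator.

**Fragment filter.** A site passes iff the fragment a read would sequence
into — from the cut coordinate to the next cut on the same strand, or the
chromosome boundary — is strictly longer than `min_fragment` (default
70 bp). Small downstream fragments are lost in library clean-up, so their
sites cannot yield reads. The filter is monotone: raising the threshold
never increases the accessible-dyad fraction.

**Accessibility.** A CpG dyad is accessible iff at least one passing site
interrogates it; the report gives accessible/total dyads and a per-context
breakdown of interrogated cytosines (all `CG` under the vertebrate
assumption; `CHG`/`CHH` appear for CpN enzymes under `ALL`). The same code
path scales from the test fixtures to a full reference genome; whole-human
runs are a CLI invocation away but are deliberately outside the test
suite's problem sizes.

## Feature annotation

CpG islands come in as BED intervals; shores are the 2 kb flanks minus the
islands themselves (half-open flanks: a dyad exactly 2,000 bp from an
island edge is ocean); everything else is ocean. Promoters are symmetric
TSS ± 4 kb windows (TSS strand decides which gene end is the TSS, but the
window ignores strand) and take precedence over gene bodies, making
promoter/genebody/intergenic an exact partition — both partitions must sum
to the dyad total, and the tests enforce this. Enhancers are an overlay
flag, not a partition member. Interval stabs use numpy `searchsorted` over
merged interval arrays; classification is independent of input interval
order. Coverage reports give, per class, the fraction of the feature
covered and the composition of the accessible set, plus an explicit
mismatch count for accessible positions missing from the catalog.

## Read cleaning and counting

A record is kept iff:

1. mapped, primary, non-supplementary (secondary/supplementary dropping,
   duplicate dropping and a MAPQ floor are configurable; duplicates are
   kept by default because deduplication would bias enrichment counts at
   saturating depth, and no MAPQ threshold is applied by default);
2. its remnant trimer matches: forward reads compare their first three
   bases against the surviving remnant prefix (CGA for TaqI), reverse
   reads their last three against the reverse-complement suffix (TCG),
   within bounded Levenshtein distance `max_edit` (default 1, allowing one
   sequencing error). Degenerate remnants are compared by minimum distance
   over all concrete expansions. Soft-clipping is not modelled; the
   aligned sequence start is used;
3. its proximal coordinate equals a predicted cut coordinate. Because the
   post-PCR library molecule is a duplex, an occurrence detected on
   *either* converted strand can template reads in both orientations, so
   forward starts are checked against the forward coordinates of all
   occurrences and reverse ends against all reverse coordinates. This
   matters exactly at conversion-created sites, which exist on one strand
   only; without it their complement-strand reads would be wrongly
   discarded.

Rejected records remain in the output stream with the unmapped bit (0x4)
set. Survivors are tallied per (chrom, strand, coord) — per-strand tallies
are primary, the strand-summed view is derived — and exported as sorted
bedGraph. Reads failing only the coordinate check can optionally be
tallied in a separate "rescued" table (real libraries show reads at sites
absent from the reference); they are never merged into the main counts.

An accounting identity holds always: input = kept + Σ dropped. A useful
consequence of the duplex rule: for TaqI, every cytosine of TCGA is
CpG-context by construction, so even incomplete conversion cannot produce
a read at an unpredicted coordinate — whereas Sau3AI's terminal cytosine
can sit in non-CpG context, and its conversion failures do produce
off-site reads, which the cleaner drops.

Inter-library concordance aligns two count tables over the union of their
sites (absent = 0), transforms log10(count + 0.5), and reports squared
Pearson correlation; fewer than two shared sites is an error, never a
silent zero.

## Count-model simulation

The paper-level contrast is between methods that sample both fractions
(M+U) and methods that enrich methylated fragments (M-only):

- **M+U**: per-site depth n ~ Poisson(μ); methylated reads
  m ~ beta-binomial(n, β; ρ) with intra-site correlation ρ (ρ = 0 is
  binomial); estimate beta_hat = m/n, *missing* (never imputed 0) when
  n = 0. The estimator is conditionally unbiased and converges as μ grows.
- **M-only**: count ~ negative binomial with mean s·μ·β and size φ,
  realised as a Gamma–Poisson mixture so non-integer φ is exact; variance
  is mean + mean²/φ and β = 0 gives a structural zero with probability 1.

Defaults: n_sites = 200,000 and μ = 24.6 (the M-fraction coverage used for
the published simulation figure); φ = 2.0 as a moderate overdispersion
default chosen so fixture-generated COBRA counts fall within the model's
dispersion envelope (empirical overdispersion estimates are not published);
s = 1. The default beta distribution is a three-component Beta mixture
(weights 0.4/0.2/0.4, shapes (1,10)/(2,2)/(10,1)) — bimodal with heavy
mass near 0 and 1 like a typical 450K array profile, but an
implementation default, not a measured distribution. The concordance
sweep draws one beta vector per run and reuses it across coverages so
rows are comparable; the M-only "estimate" is the relative rate
count/(s·coverage), for which r² is the meaningful summary.

## Synthetic-data generator

What it emulates, per molecule: fragment length uniform on 150–500 bp
(the observed sonication range) at a uniform genomic position and random
strand; each overlapping CpG dyad methylated by an independent
Bernoulli(β) draw, symmetric across strands of the dyad; bisulfite
conversion of each unmethylated cytosine with probability 0.994 (the
observed near-complete conversion rate; methylated cytosines never
convert — no over-conversion is modelled); digestion of the converted
molecule at surviving concrete recognition matches (scanning the molecule
strand is duplex-complete because supported enzymes are palindromic);
and emission of exactly one read of up to 100 bp from the surviving cut
nearest the randomly assigned adapter-2 end, reading into the retained
piece — an explicit simplification of the Y-adapter/biotin-depletion
geometry that is adequate because downstream tools only require reads to
start at true cut coordinates. Retained pieces shorter than 40 bp (the
upstream read-length filter) are skipped and counted, as are uncut
molecules. Sequencing errors are uniform substitutions (default 0.1 %);
indels are not simulated — the Levenshtein tolerance is exercised by
targeted decoys instead. Decoy channels inject labelled secondary
records, correct-trimer reads at non-site coordinates, and reads whose
remnant trimer is mutated to an exact chosen edit distance.

SAM records are written directly by the generator with SAM-standard
coordinates and flags (reverse reads flag 16, reference-forward
sequences), so no aligner is involved anywhere in the tests. All outputs
are byte-identical for a fixed seed.

The closed-form count expectation used as a test oracle is
(molecule coverage) × Π β over the site's dyads × conversion-success
factors for each base the match requires to convert. It ignores
competition between nearby sites for the same molecule, so quantitative
recovery is asserted on uniform-accessibility genomes (one isolated site
per 600 bp block, farther apart than the longest fragment); on such
genomes observed counts correlate with the expectation at r > 0.95 once
counting noise is small (≈200 molecules per locus) and track true beta
with Spearman ρ > 0.9 already at 50 molecules per locus.

What the generator does *not* model — and hence what passing tests do not
establish about real data: PCR amplification bias and efficiency
differences between loci, adapter sequence read-through, copy-number
variation, FFPE damage, over-conversion of methylated cytosines, and
aligner behaviour (mapping ambiguity, soft-clipping). The all-unmethylated
enrichment check is run at conversion efficiency 1.0: with realistic
incomplete conversion, rare unconverted CpGs at genuine sites legitimately
yield kept reads, which is protocol-faithful but not what that check
probes.

## Problem sizes and numerical choices

Test and acceptance runs use 30–60 kb synthetic genomes, 10⁴–2×10⁵
molecules per library, and 10⁴–2×10⁵ simulated sites — sizes at which
every stochastic assertion has comfortable Monte-Carlo margin while the
whole suite stays fast. "High depth" for the inter-library concordance
experiment means ≈80 kept reads per site-strand key. Monte-Carlo
assertions use 3-standard-error bands; the digestion engine is checked for
*exact* agreement (coordinates and strands) against an independent naive
expand-and-slide oracle, and the cleaner for exact closure (every
error-free fixture read kept and assigned to its true site). Ties and
degenerate inputs: empty sequences convert to themselves; an empty count
table exports an empty bedGraph; concordance on fewer than two shared
sites or constant counts raises instead of returning a number.
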