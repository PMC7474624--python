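# Methods

## Strain-unique k-mer reference

Let G = {g₁, …, g_S} be the closed universe of consortium genomes. For odd k
(15 ≤ k ≤ 63; default 31), every k-mer containing only A/C/G/T is collapsed to
its canonical form, the lexicographic minimum of the k-mer and its reverse
complement, so read strand never matters. For k ≤ 31 canonical k-mers are
packed 2 bits per base into uint64 and handled as sorted numpy arrays; longer
k falls back to string keys.

A canonical k-mer is *strain-unique* if it occurs in exactly one genome
(counting distinct genomes, not copies — a k-mer repeated within one genome
is still unique to it). The *informative length* of strain i,
U_i = |{positions p in g_i : the k-mer starting at p is strain-unique}|,
plays the role of an effective genome length. Maximal runs of unique start
positions are exported as 0-based half-open BED intervals; a hard-masked
FASTA keeps only bases covered by at least one unique k-mer window; a JSON
manifest records k, L_i and U_i and round-trips losslessly through the
loader, which revalidates U_i.

## Read classification and abundance scaling

Reads are 3′-trimmed while the terminal base quality is below Q20 and dropped
when shorter than k. Samples are subsampled without replacement to exactly
100,000 reads (seeded, input-order stable) so depth never confounds
comparisons between samples.

Classification is vectorized: all reads are concatenated with single `N`
separators, canonical k-mers are computed once over the concatenation
(separator-spanning windows are invalid by construction), located in the
sorted unique-k-mer array by binary search, and accumulated into a
reads × strains hit matrix. A read is assigned to the strain with the most
unique-k-mer hits if that maximum is ≥ 3 and not tied; otherwise it is
unassigned. Unassigned reads are reported, never silently dropped:
assigned + unassigned = subsampled depth.

Counts are scaled to relative abundance by informative length:
a_i = (c_i/U_i) / Σ_j (c_j/U_j). Dividing by U_i removes the bias by which a
strain with a longer (or more distinctive) genome sheds more classifiable
reads per cell; a_i therefore estimates cell proportions. Scaling by raw
genome length L_i is available as an alternative mode. A strain is called
present when a_i ≥ 10⁻⁴ and c_i ≥ 5 reads. Absolute abundances are
a_i × D where D is microbiota density.

## Microbiota density and diversity

Density is D = DNA yield (ng) / fecal mass (mg). Pre/post changes are tested
with a paired t test on per-mouse differences; group contrasts use Welch's t.
Shannon diversity is H = −Σ a_i ln a_i over strains with a_i > 0.

## Engraftment and persistence

For a transplant with recipient consortium R, donor consortium D, and
presence calls pre and post transplant: the engraftment fraction of a mouse
is |{d ∈ D : present post}| / |D| and the persistence fraction is
|{r ∈ R : present pre and post}| / |R|. Strains in R ∩ D are ambiguous; the
default policy excludes them from both numerator and denominator, and an
alternative attributes them to the recipient. Strain counts report n_pre,
n_post, their difference, and turnover. Cohort summaries give group
mean ± SE per recipient × donor pair and a one-way ANOVA across groups when
at least two groups have ≥ 2 mice.

## Balanced subcommunity design

Given S strains, community size c and replication r with c | S·r, the design
is an m × S binary matrix (m = S·r/c) with every row summing to c and every
column to r, minimizing first the maximum pairwise co-occurrence
max_{i<j} C_ij (C = XᵀX off-diagonal) and then Σ C_ij². Construction
alternates two seeded start heuristics (partition-into-rounds when c | S,
greedy fill otherwise) followed by first-improvement pair-swap descent, over
multiple restarts; the target max ⌈r(c−1)/(S−1)⌉ is a counting lower bound.
For (S, c, r) = (16, 4, 2) this yields 8 communities with no strain pair
co-occurring more than once, matching the exhaustive optimum on small
instances.

## Strain–phenotype attribution

For each strain, mice (or community means) are split by whether their
community contains the strain, and a Welch t test compares the two groups.
Strains without contrast (in all or no communities) or with fewer than two
observations per arm are flagged rather than tested. Strains with identical
membership columns are marked confounded — the design cannot distinguish
them, and they share identical statistics. Raw p-values receive
Benjamini–Hochberg correction; an across-community one-way ANOVA (effect
size η²) tests for any community structure. Abundance–phenotype and
density–phenotype relationships use OLS with the overall F test on
1 and n−2 degrees of freedom.

## Statistical conventions

Welch's t uses the Welch–Satterthwaite degrees of freedom. Tukey–Kramer HSD
computes q = |x̄_i − x̄_j| / √(MSW/2 · (1/n_i + 1/n_j)) with p from the
studentized-range distribution. A paired test with all-zero differences
returns t = 0, p = 1; constant nonzero differences raise a degenerate-data
error rather than reporting infinite confidence. Regression refuses constant
predictors. Group summaries report mean ± SE and flag n = 1 groups as having
undefined SE.

## Synthetic truth

Generators plant known truth for every claim: genomes share identical
inserted blocks (mimicking conserved regions) to stress uniqueness; reads
are drawn with probability ∝ composition × genome length, equiprobable
strands, and substitution errors; phenotypes are baseline + Σ effects +
Gaussian noise clipped to [0, 100]; densities are lognormal with a per-mouse
random effect splitting variance equally between and within mice; transplant
cohorts plant per-strain engraftment and persistence probabilities. All
generators are driven by a single integer seed and are deterministic.
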