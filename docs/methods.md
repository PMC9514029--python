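# Methods

`ervscreen` implements a comparative-genomics screen for endogenous
retrovirus (ERV)-derived genes that have been domesticated by their host:
ORFs that show retroviral domain similarity, are conserved between two
related species, are not already annotated genes, have no ortholog in
outgroup genomes, and evolve under purifying selection. This note
documents the models behind each stage, the defaults and why they were
chosen, what the synthetic data generator does and does not emulate, and
the numerical choices that make runs reproducible.

## The screen

**ORF extraction.** An ORF is a maximal run of non-stop codons in one of
the six reading frames, bounded by stop codons (or, by default, a contig
end), at least 240 nt long. The flanking stops are not part of the
reported span. Runs touching contig ends are included because a
stop-to-stop extractor that drops them silently loses telomere-proximal
ORFs; `require_both_stops=True` restores the strict behavior. A run of
more than 10 consecutive N-containing codons splits an ORF so that
assembly gaps cannot stitch unrelated frames together; isolated ambiguous
codons translate to `X` and do not terminate the ORF.

**Domain scan.** Peptides are scanned with profile HMMs built from seed
alignments of retroviral domains. The model is a simplified Plan7-style
local profile: match states with Laplace-smoothed column emissions
(columns with ≥ 50% residues become match states), insert states that
emit the background distribution (0 bits), delete states, uniform entry
into any match state (−log2 M bits) and free exit from any match state.
Scoring is Viterbi (maximum, not Forward) in log-odds bits. E-values come
from a Gumbel null fitted by the method of moments (λ = π/(σ√6),
μ = mean − γ/λ) to the Viterbi scores of `n_random = 1000` random
background peptides of length 400, and E = n_sequences × P(S ≥ s). The
default threshold, E < 1e-5, mirrors standard domain-scan practice. A
planted diverged domain copy scores hundreds of bits above the null, so
the threshold's exact calibration error (a method-of-moments tail
extrapolation) has a wide safety margin.

**Cluster-size filter.** Young ERV families have many nearly identical
genomic copies; any ORF in a cluster of more than 10 peptides at ≥ 50%
identity is removed. Clustering is greedy and incremental in the CD-HIT
style: sequences sorted longest-first (ties by id), each joins the first
cluster whose *representative* it matches at threshold, identity defined
as identical aligned residues divided by the shorter sequence's length
under a global alignment with free end gaps (BLOSUM62, gap open 11,
extend 1). Membership is tested against the representative only, so a
fragment matching one region of the representative joins the family even
if it shares nothing with other fragments.

**Cross-species pairing.** Surviving peptides of species A are aligned
against those of species B by Smith–Waterman (BLOSUM62, 11/1, executed by
Biopython's PairwiseAligner). Bitscores and E-values use the
Karlin–Altschul formulae with the published gapped BLOSUM62 constants
λ = 0.267 nats, K = 0.041; exact parity with BLAST's composition-based
statistics is a non-goal — only the threshold semantics matter. Pairs
need E < 1e-50 and ≥ 200 bits (the bitscore cut is configurable and an
automatic largest-gap rule is provided); assignment is greedy by
descending bitscore with each ORF used at most once. Pairing is
one-directional (A queries against B) as in the original design of such
screens; a reciprocal-best-hit mode can be composed from two runs.

**Known-gene exclusion.** A pair is removed if either ORF overlaps an
annotated gene whose name is on the user's exclusion list, or if either
peptide hits a known-protein database at E < 1e-5. Both mechanisms are
active because annotation catalogs and protein databases have different
blind spots. ORFs inside introns of genes *not* on the list are retained
— domesticated ERV genes often live inside host gene introns.

**Lineage specificity.** Each candidate peptide is searched against each
outgroup genome by translated alignment over all six-frame stop-split
segments. Hits with query cover (alignment length / query length) ≥ 0.6
are candidate orthologs; a candidate is called `ortholog_found` only if
such a hit lies within 1 Mb of the marker-gene locus on the same contig,
where the marker locus is the highest-scoring translated hit of the
marker protein. The cover threshold separates full-length orthologs from
the ubiquitous short RT-domain matches to unrelated ERVs; the 1 Mb
proximity default conservatively separates an intronic/adjacent ortholog
from distant paralogous loci and is configurable. A missing marker gives
the verdict `marker_absent`, never an exception.

## Selection statistics

dN/dS follows the Nei–Gojobori counting method. Synonymous sites per
codon: at each position, the fraction of non-stop single-nucleotide
changes that are synonymous (stops excluded from the denominator);
nonsynonymous sites are the complement, so S + N = 3L exactly.
Differences per codon pair: synonymous/nonsynonymous step counts averaged
over all orderings of the differing positions, excluding pathways through
stop codons (falling back to the unweighted average if every pathway
passes through a stop). Proportions pS = Σsd/S and pN = Σnd/N get the
Jukes–Cantor correction d = −(3/4)ln(1 − (4/3)p), flagged undefined when
p ≥ 3/4.

The codon-based Z-test of neutrality resamples codon columns with
replacement (`n_boot = 1000`, seeded). The default standard error is the
bootstrap standard deviation of the *difference* dS − dN. The textbook
form sqrt(Var(dS) + Var(dN)) is available as `variance="independent"`
but ignores the positive covariance between the two replicate estimates
arising from joint resampling, and is measurably conservative (empirical
size ≈ 0.02 versus ≈ 0.036 for the difference variance at the default
simulation conditions). For the purifying alternative,
Z = (dS − dN)/SE and p is the upper normal tail.

Calibration of the test's size is assessed under the mutation model the
NG86 counting itself assumes: uniform substitutions among the non-stop
alternatives at each position (ts/tv = 1). With a transition bias of 2
the NG86 estimator is known to inflate dS under neutrality — a property
of the estimator, not of the test — which would be misread as liberal
behavior if calibrated under the biased process. Power and estimator
recovery are checked under the realistic ts/tv = 2.

Percent identity is 100 × identical positions / alignment length;
columns gapped in both sequences are dropped first, a gap opposite a
residue counts in the denominator.

## Tree test

Paralog/ortholog topology is tested with Poisson-corrected protein
distances (d = −ln(1 − p) over shared ungapped columns) and canonical
Saitou–Nei neighbor joining with deterministic tie-breaking by label
order. Negative branch lengths are clamped to zero with the deficit
moved to the sibling branch, preserving the path length between the
joined pair. Rooting the tree on a retroviral seed-consensus outgroup,
the screen asks whether each gene's cross-species pair is monophyletic:
if all pairs are, the duplications that created the paralogs predate the
species split. Distance-based inference replaces likelihood tree
building deliberately — it is fast, fully deterministic and
oracle-checkable against additive matrices; no bootstrap support values
are computed. A simple gap-fraction column filter (threshold 0.5) is
provided in place of heavier alignment-trimming tools. When no multiple
alignment is available the pipeline derives pairwise Poisson distances
from pairwise global alignments; with the indel-free generator these
coincide with the aligned-columns definition.

## Tandem-repeat evidence

The self-dotplot lists all position pairs sharing a k-mer (k = 12 by
default, forward and reverse-complement), i < j, diagonal excluded. A
tandem triplet with unit length u produces off-diagonal bands at offsets
u and 2u; a random sequence of 10 kb yields only the ~n²/4^k expected
isolated chance matches with no repeated offset.

## The synthetic genome pair

The generator emits, deterministically from a seed: an ancestor with a
marker gene ("GRIP2"-like: two exons of 200 codons around a ~7 kb
intron), a tandem triplet of 600-codon domesticated ORFs on the minus
strand inside that intron (each a non-RT head of 400 random residues
plus an RT region descended from the RT seed consensus at 15% amino-acid
divergence, catalytic motif YVDD ablated to YVNN by default), one
ASPRV1-like decoy gene (a conserved ERV-derived protease-like gene that
is already annotated), and 30 young-family elements of 2 kb on a second
contig, each carrying a 300-codon gag-like ORF at 98% mutual nucleotide
identity. Two contigs of ≥ 40 kb and ≥ 75 kb hold everything; random
background of this size contributes a few hundred chance ORFs ≥ 240 nt
per genome, which serve as the neutral decoy class.

Speciation evolves the ancestor down two independent branches. Neutral
regions mutate per site at half the configured pairwise synonymous
divergence (default dS = 0.15, so 0.075 per branch) with ts/tv bias 2.
Coding regions evolve by rejection sampling: Poisson(rate × length)
proposed point mutations, the replacement base drawn from the non-stop
alternatives (see above for why the process is conditioned on sense
codons), synonymous changes always accepted, nonsynonymous accepted with
probability ω (0.1 for domesticated and decoy, 0.05 for marker exons, 1
for young elements). Young ORFs evolve with ω = 1 but still reject
stops: the screen's young class is, by definition, the set of chance
ORFs that have *not yet* been disrupted by nonsense mutations, so the
generator conditions on that event rather than emitting broken ORFs.
Tandem paralogs diverge from their shared prototype at a proposal rate
of 0.25 per site before speciation, placing the duplications clearly
before the species split.

Three simplifications matter for interpreting green tests. Divergence is
indel-free, so truth-table coordinates lift over unchanged and codon
alignments are trivial; real orthologs need alignment and their
coordinate bookkeeping is harder. The stop codons flanking planted ORFs
are held fixed during mutation so ORF boundaries stay exact; in real
genomes ORF boundaries drift. And the background is uniform-composition
random sequence with no repeat landscape, so the screen's false-positive
behavior on real repeat-rich genomes is not probed — passing tests
demonstrate the decision logic and the statistics, not robustness to
genomic complexity. Codon evolution by rejection sampling slightly
underestimates multiple-hit effects, a negligible bias for dS ≤ 0.3.

The outgroup genome is the ancestor evolved at 0.5 substitutions per
neutral site with the domesticated triplet and decoy excised, the marker
retained under strong constraint, and a partial RT relic planted on the
other contig — so a correct screen finds RT similarity there but rejects
it on query cover and marker proximity. Variants with a planted ortholog
near the marker and with the marker destroyed exercise the other two
verdicts.

## Problem sizes and determinism

Default problem sizes (two ~40–85 kb genomes, 600-codon candidate genes,
1000 calibration peptides, 1000 bootstrap replicates, 100-replicate
topology and 500-replicate calibration experiments) were chosen so the
complete analysis reproduces on a laptop-class single core in about a
minute per screen; every random draw flows from an explicit integer seed
through `numpy.random.default_rng`, and re-running any entry point with
the same configuration is bit-identical.
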