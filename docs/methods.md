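# Methods

This note documents the models, conventions and numerical choices behind
`htrscan`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate conventions

GFF3 is 1-based inclusive on disk and `GeneModel.cds_segments` keeps that
convention; nothing downstream consumes raw coordinates except intron
counts. Intron counts are **CDS-only** (UTR introns ignored): the variant
rules concern the coding gene structure. When a gene has several
transcripts, the transcript with the longest CDS represents the locus
(ties: lexicographically smallest transcript id), matching the removal of
predicted alternative splice variants. Genes annotated without CDS
features carry `intron_known = False` and are classified from their
signature alone (flag `signature_only`, medium confidence).

Canonical H3 numbering is 1-based on the **mature** protein, initiator
Met excluded — the frame in which K4/K9/K27/K36 and the signature
positions 31/41/87/90 are conventionally named. Candidates that retain
an initiator Met have it excluded from the N-terminal overhang count.

## Homology scan

Local alignment is exact Smith–Waterman (Gotoh three-state recurrence,
BLOSUM62, gap of length L costing 11 + L), with a fixed traceback
tie-break (diagonal, then up, then left) so spans are deterministic.
E-values use the Karlin–Altschul formula with the standard gapped-BLAST
constants λ = 0.267, K = 0.041; the database size n is the scanned
proteome's residue total. These constants are implementation choices, not
fitted values. The scan iterates: sequences whose best e-value passes the
threshold (default 10⁻¹⁰) join the query set, in synchronous rounds,
until no new sequence is found; a subject's recorded best hit is its
highest-scoring alignment against any query available up to its discovery
round. Six-frame genome search (TBLASTN-style) is deliberately out of
scope: inputs are annotated proteomes.

The "incomplete" filter is coverage-based, the one quantitative proxy we
impose on an otherwise undefined notion: the local alignment must cover at
least 80% (configurable) of the query's histone-fold core, taken as
canonical 45–135 on mature-query coordinates. Measuring coverage against
the core rather than the full query keeps N-terminally degenerate H3-like
genes — a real class — out of the discard pile.

## Alignment and position mapping

The progressive aligner builds a neighbor-joining guide tree on pairwise
p-distances and merges profiles with average sum-of-pairs BLOSUM62
scoring and affine gaps; pairwise global alignment penalizes end gaps.
There is no iterative refinement and no manual curation step — alignment
is fully deterministic.

`map_to_reference` aligns a candidate globally to the canonical reference
and reads candidate indices per canonical position. The **N-terminal
overhang** is measured as the candidate's length excess ahead of the
first mapped histone-fold position (canonical 45): a global aligner may
scatter the gaps for a divergent CenH3 tail across the canonical tail
region instead of stacking them at the start, so counting residues
"before canonical position 1" literally would miss true tails. Anchoring
the count at the core start measures the same quantity when gaps do land
at the start and is robust when they do not. Candidates aligning fewer
than 20 reference positions are rejected as unmappable.

The bundled reference (`data/h3_reference_synthetic.fasta`) is a
**synthetic** 135-residue stand-in that occupies the coordinate frame of
a mature plant H3.3 — correct lysines and H3.3 signature at the named
positions, random elsewhere. It exists so that no biological sequence is
hard-coded as ground truth; real analyses should supply the organism's
own mature H3.3.

## Classification

Decision order: (1) any CenH3 evidence → CenH3; (2–4) matching signature
with agreeing intron evidence → H3.1 / H3.3 / H3.1A; unknown introns →
signature decides alone at medium confidence; a matching signature
contradicted by intron evidence is flagged `signature_intron_conflict`
and falls to H3-like; (5) everything else → H3-like. CenH3 priority
reflects that a diverged CenH3 can spuriously present signature-like
residues through gaps, while clade/tail evidence is stronger.

H3.1A is assigned wherever its signature and intronlessness hold — its
restriction to nonflowering plants is an observation, not a rule. An
alternative metazoan rule set (positions 31/87/89/90; A-S-V-M vs
S-A-I-G) is available behind a switch and off by default.

CenH3 evidence has two independent sources. The **tail heuristic**: an
N-terminal overhang of ≥ 15 residues together with identity < 0.75 to the
reference over canonical 45–135 (gaps count as mismatches). Both cutoffs
are package defaults — no quantitative threshold exists in the
literature criteria — and are configurable. The **clade test**: the
candidate shares a bootstrap-supported (≥ 70 by default) clade with a
known CenH3 anchor, excluding all known non-CenH3 sequences. Clades are
read off the midpoint-rooted tree: NJ trees are unrooted and the seed
node can land inside the very clade being sought; midpoint rooting is the
standard display rooting and makes the clade set well-defined. Supports
are bipartition properties and are looked up rooting-invariantly.

## Phylogeny

Distances: pairwise deletion; Poisson correction d = −ln(1 − p) or gamma
d = α((1 − p)^(−1/α) − 1), α defaulting to 1.0. A full rate-matrix
protein model (JTT-class) was judged out of proportion for desk scale;
the gamma correction is the documented substitute. Saturated pairs
(p ≥ 1 − 10⁻⁹) and pairs with no comparable columns raise errors;
bootstrap replicates hitting them are skipped and counted in the reported
skip rate.

NJ follows Saitou–Nei with two determinism rules: join ties break to the
smallest index pair in node-creation order, and negative branch lengths
clamp to zero with the deficit moved to the sibling so the pair distance
is preserved. Additive matrices are recovered exactly (topology and
lengths). Bootstrap supports are bipartition frequencies over successful
replicates; internal edges of length zero in the base tree are treated as
unresolved and carry no support (identical sequences would otherwise
collect tie-break artifacts). Maximum likelihood and model selection are
out of scope.

## Selection

NG86 counting: per-codon fractional synonymous sites s = Σ (synonymous
third of each position), with changes into stop codons counted as
nonsynonymous so s + n = 3 exactly; substitution counts averaged over all
orderings of the differing positions, pathways through stop codons
excluded with uniform reweighting of the survivors. In the rare corner
where every pathway is blocked, all pathways are used and steps touching
a stop count as nonsynonymous. Proportions pS, pN get the Jukes–Cantor
correction −(3/4)ln(1 − 4p/3); p ≥ 3/4 is a hard "saturated" error (a
single-codon comparison with one synonymous difference saturates by
construction — counts for such pairs are available via
`pathway_changes`). Group dN and dS are means over all unordered pairs,
skipping saturated pairs with a warning; ω is undefined when dS = 0.

Site-wise selection is SLAC-style counting: ancestral codons by Fitch
parsimony (gap leaves are wildcards; ties resolve to the
lexicographically smallest codon, so results are reproducible), per-site
Nd/Sd summed over branches by pathway averaging, and the synonymous share
tested one-sided in both directions against the site's expected
synonymous fraction, S/(S+N) over its observed codons. Because
pathway-averaged counts are fractional, the binomial tails use the
regularized-incomplete-beta continuous extension, which coincides with
the exact binomial on integers. Site calls use raw P < α (default 0.05)
as is conventional for this test; Benjamini–Hochberg q-values are
reported per site but do not drive the call. This counting machinery
replaces likelihood-based global model fitting entirely — that is the
central methodological substitution in the package, chosen so the whole
computation is self-contained and exactly testable against enumeration
oracles.

## Codon simulator

`evolve_codons` is a continuous-time Gillespie simulation over sense
codons: single-nucleotide moves only, rate κ for transitions and 1 for
transversions, ×ω when nonsynonymous, zero into stops; the generator is
normalized to one expected substitution per codon site per unit time at
the ancestor composition, so branch lengths are expected substitutions
per codon site. κ defaults to 1: NG86 counting assumes no
transition/transversion bias, so estimator-consistency checks (ω = 1 in,
ω ≈ 1 out) are meaningful at κ = 1, and the known downward bias of NG86
under κ > 1 can be studied by setting κ explicitly rather than being
baked into every test.

Simulated study conditions: pairwise recovery uses 200-codon pairs at
divergence 0.3 (100 replicates per ω); site-wise tests use 10 taxa × 135
codons — the length of the histone fold frame — on random-join trees
with exponential branch lengths of mean 0.5 substitutions/codon site.
The depth emulates an anciently diverged family sampled across a wide
species range; it also matters statistically: a counting test needs
roughly three changes at a site before P < 0.05 is attainable at
synonymous fractions near 1/4, so shallow trees cannot show site-wise
purifying selection regardless of its strength.

## Synthetic genomes

`synth_genome` plants labelled genes derived from a seeded synthetic
reference: H3.1 (A31 F41 S87 A90, intronless), H3.3 (reference signature,
1–2 introns), H3.1A (A31 Y41 S/Q87 L90, intronless), CenH3 (a common
ancestor with a 25-residue random N-tail and a core mutated at an exact
35% of positions 45–135, plus 8% per-gene drift — descent from one
ancestor makes the CenH3s a real clade), and H3-like (≥ 1 signature
position forced outside both consensus sets, optionally N-truncated,
optionally K27M). Background mutation (2%) never touches the eight
protected positions except where the class definition dictates. Decoys
are random proteins, far below the e-value threshold by construction.

CDSs are back-generated per residue with uniformly random synonymous
codons, **inherited from a single reference codon assignment** with a
10% per-codon silent-swap rate: genes in one genome share codons by
descent, keeping within-family synonymous divergence realistic and
unsaturated (independent randomization per gene would saturate every
pair). GFF3 gene models realize each intron plan with 60–200 nt introns
on random strands; no genomic nucleotide sequence is emitted, since
six-frame search is out of scope.

Expression matrices plant four archetypes over a 10-tissue two-group
panel (6 dividing-like, 4 differentiated-like): constitutive (flat),
dividing-high (+Δ log₂ in dividing tissues, Δ = 2 by default),
heterogeneous (a single-differentiated-tissue spike, deliberately
structured so it can be neither flat nor dividing-high), and not-detected
(below the detection floor of 1.0). Log-normal noise, sd 0.2 log₂ units.
The archetype caller works on the linear-scale row: the coefficient of
variation (< 0.25 ⇒ constitutive) is computed on linear values, where a
flat log-normal profile stays comfortably below the cutoff while any
group effect exceeds it, and the group contrast (> 1 log₂ unit ⇒
dividing-high) on log₂(x+1).

The two-clade bootstrap fixture (`synth_two_clade_alignment`) gives the
planted CenH3 clade deliberate internal structure with the anchor basal:
synapomorphies support only anchor-free subclades, so the smallest
supported clade containing the anchor is the full planted clade. A flat
star of taxa with private noise is *not* used: exactly tied resampled
distances meet NJ's deterministic tie-break and manufacture spurious
high supports for arbitrary pairs — a real artifact of bootstrap-on-NJ
with unresolvable data, worth knowing about when interpreting supports
on near-identical sequences.

## Expression clustering

Distances are 1 − Pearson correlation on median-centered log₂ values,
average linkage (scipy), the canonical Cluster 3.0 defaults — the
original tool's exact settings are not recoverable, so these are declared
choices. Zero-variance genes (constant after centering) are an error
naming the gene, since their correlation is undefined. Genes below the
detection floor are excluded and reported; "possible pseudogene" is
reported, never asserted.

## What passing tests show — and what they do not

The synthetic genomes have clean, fully informative signals: correct
signature residues, consistent intron annotations, decoys unrelated to
H3. Perfect classification recovery on them validates the *rules and
plumbing*, not performance on real genomes, where annotation errors,
partial gene models and genuinely ambiguous paralogs will lower both
precision and recall. Likewise the ω-recovery and site-selection checks
validate the estimators under the model they assume (κ = 1, no
recombination, tree known); on real data the tree is estimated and codon
usage is biased, and NG86 is known to be conservative. Headline counts
from any particular set of real genomes depend on the genome versions
scanned and are not reproduced here.

## Known limitations

Heuristic-free O(mn) alignment limits proteome scale (desk scale is the
design point; numba keeps it fast enough). No ML/Bayesian phylogenetics,
no codon-model likelihood fitting, no branch-site tests, no
recombination detection, no microarray normalization. The clade test
depends on midpoint rooting being sensible (a pathological rooting can
hide the clade, though the tail heuristic still catches typical CenH3s).
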