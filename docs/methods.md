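# Methods

`dictycomp` re-implements, as a deterministic desk-scale pipeline, the
comparative analysis by which developmentally essential genes (DEGs) of
*Dictyostelium discoideum* (DD) are classified across five dictyostelid
genomes (DD, *D. purpureum* DP, *D. lacteum* DL, *Polysphondylium
pallidum* PP, *D. fasciculatum* DF) and three unicellular amoebozoan
genomes (*Physarum polycephalum* PhyP, *Acanthamoeba castellanii* AC,
*Entamoeba histolytica* EH).  This note records the models, the
parameters that matter, and the design choices made where the design
was genuinely open.

## Species phylogeny

All classification is relative to a fixed rooted species tree

```
((((((DD,DP),DL),(PP,DF)),PhyP),AC),EH)
```

with group 4 = {DD, DP}, branch II = {DD, DP, DL} and branch I =
{PP, DF}.  The published phylogeny carries no branch lengths; the
simulator uses 0.3 substitutions/site on every branch and 0.6 on the
pendant branches of the three unicellular species.  These values were
chosen once so that homology search and distance trees are informative
(pairwise identities well above the twilight zone within Dictyostelia)
without approaching saturation, and are not tuned thereafter.

## Homology and best bidirectional hits

Pairwise similarity is Smith–Waterman local alignment with affine gaps
(BLOSUM62, gap open 11 / extend 1 — the standard protein-search
defaults; the original study does not state its parameters).  The
ambiguity residue X scores 0 against everything.  Hits are ranked by
raw score (ties: higher identity, then lexicographic subject id);
E-value calibration would require a database-size model that adds
nothing to the mutual-best criterion that consumes the ranking.  A best
bidirectional hit (BBH) is a pair of genes, each the other's top-ranked
match; the default reporting floor is a raw score of 40.

## Gene trees

The original workflow inferred Bayesian protein trees; this package
substitutes a deterministic distance pipeline and additionally accepts
externally built trees as Newick, so the downstream classification —
the part this package exists for — can be run on either.  Distances are
p-distances over the columns of the implied alignment (columns with
more than 50% gaps ignored), Poisson-corrected d = −ln(1−p) and capped
at d = 3.0 for p ≥ 0.95.  Trees are built by Saitou–Nei neighbor
joining; a negative estimated branch length is clamped to zero with the
deficit moved to its sister branch, preserving the fitted path length.
Trees are midpoint-rooted (root at the midpoint of the longest
leaf-to-leaf path; if the midpoint falls exactly on a node the root is
placed with a zero-length stub on the path edge toward the farther
end).  Node support is the bootstrap fraction of replicate NJ trees
containing the split, from column resampling of the implied alignment
(default 50 replicates in the pipeline, seeded).

Because the bundled simulator introduces no indels, equal-length family
sequences stack into an alignment directly.  Unequal-length input falls
back to a star alignment against the longest sequence, dropping columns
inserted relative to it; for seriously gappy real families an external
aligner plus Newick import is the supported route.

## Orthology calling

Internal nodes of the rooted gene tree are tagged
duplication/speciation by the species-overlap rule: a node is a
duplication iff two of its children's species sets intersect.  For a
focal DD gene, the homolog in each species whose last common ancestor
with the focal is a speciation node is the ortholog candidate (closest
path length wins, ties by id); homologs diverging at a duplication are
paralogs.  The LCA is the deciding node: if its support is below
`support_min` (default 0.7 — the study says only "well resolved"), the
call degrades to `homolog_unresolved`, which also absorbs ortholog
candidates whose called set fails the species-tree congruence check
(every well-supported split of the gene tree restricted to the called
set, leaves renamed to species, must exist in the species tree
restricted to the same species; with no well-supported informative
split the check passes vacuously and is flagged unresolved).  A
root-to-tip length exceeding 3× the family median raises the
aberrant-branch-length flag.

Two deliberate interpretations are worth stating.  First, orthology is
decided by the type of the LCA node, not by the presence of any
duplication anywhere on the connecting path: a homolog behind a
lineage-specific duplication of the focal gene is a co-ortholog, and
the per-species call should find it.  The path-crossing variant
misclassifies exactly these co-orthologs and measurably destroys recall
against the event-log ground truth.  Second, species-overlap tagging is
used instead of full LCA-mapping reconciliation.  The two rules agree
on every gene tree that is a true duplication/loss history without
losses (verified against a brute-force reconciliation oracle in the
test suite), and they make the same class of errors on lossy
histories.  They can disagree on topologies that no duplication/loss
history generates — e.g. a gene tree ((A,D),(B,C)) under species tree
(((A,B),C),D), where overlap sees no duplication but LCA-mapping infers
one; such conflicts are the signature of tree-estimation error, and
resolving them is what the congruence check and support gate are for.

## LGT validation

A gene is screened as a lateral-transfer candidate when its best
non-amoebozoan hit is prokaryote and it is absent from all three
unicellular amoebozoan genomes.  Validation follows the two-criterion
logic: (i) the prokaryote homolog's best eukaryote hit falls back in
the candidate's lineage (the BBH criterion), and (ii) the candidate's
sister group is purely prokaryote in trees built by two independent
methods — here NJ on Poisson-corrected and on raw p-distances; two
user-supplied Newick trees work identically.  The validation tree
contains the focal-species genes plus the family's closest prokaryote
and eukaryote homologs, mirroring how such trees are assembled in
practice; including the full dictyostelid subfamily would bury the
sister signal under within-subfamily depth.  The sister test is strict
(every sister leaf prokaryote), which reproduces all printed verdicts.

The verdict is three-valued: **yes** iff both tree methods agree on a
prokaryote sister and either the BBH criterion holds or the
contaminant exception applies (a gene that looks like a bacterial
contaminant of eukaryote databases is accepted when it is present in
all five dictyostelid genomes and transcribed — contaminants are
neither); **no** iff both tree methods reject; otherwise **unlikely**
(the transfer, if any, predates Dictyostelia).  An "unclear" method
cell is encoded as a failed criterion plus a free-text note; notes
never affect verdicts.

## Expression profiles and divergence

Stage-resolved read counts over the seven canonical stages (growth,
early aggregation, late aggregation, tipped mound, slug, early
culmination, fruiting body) are normalized per sample as
`raw / total_reads × 2 × avg_read_length`, then rescaled to
percent-of-maximum, making profile shapes comparable across species and
library sizes.  Foreign time courses are mapped onto the seven stages
through an explicit, editable stage map (a 24-h two-hourly default
ships with the package); multiple points per stage are averaged before
rescaling.  Replicates are averaged after normalization, before
percent-of-max.  Cell-type data are expressed as percent of the summed
(pre)stalk + (pre)spore counts.

Profile divergence between two species is the mean absolute
percent-of-max difference scaled into [0, 1]; a silent (all-zero)
series is maximally distant from an expressed one.  The threshold θ
defaults to 0.25 and is reported with every result, since "clearly
different" is irreducibly a judgment call.  Species are grouped by
single linkage at θ; the largest group defines the reference pattern,
and a species outside it is flagged divergent when its profile differs
from at least two other species.  The naive rule "flag any species
differing from ≥ 2 others" flags *both* sides of a 2-vs-3 split (a
group-4 shift would flag all five species), which makes the
phylogenetic pattern labels unreachable; anchoring flags to the
majority group restores the intended minority-pattern semantics.  The
flagged set maps to a pattern: none → conserved; one → one species;
{DD,DP} or {DL,PP,DF} → group 4 vs groups 1–3; {PP,DF} or {DD,DP,DL} →
branch I vs branch II; anything else → other.

## Enrichment and summaries

Term enrichment in a gene set is the frequency ratio
`(k/n)/(K/N)` with a one-sided exact hypergeometric p-value
P(X ≥ k) and Benjamini–Hochberg adjustment across terms.  Annotations
propagate to ancestor terms through a user-supplied edge table (on by
default; exact-term mode available).  Membrane classes partition
proteins into soluble / TM-only / SigP-only / both from their
signal-peptide and transmembrane predictions.  Summary builders tally:
orthologs and domain/expression-conserved homologs over 1–5 dictyostelid
genomes; divergence-pattern counts; per-species counts of proteins
carrying either or both domains of a pair (a protein with both counts
once, under "both"); and the limited-conservation table (genes confined
to DD, group 4 or branch II, with S/T annotation and the
secreted-or-exposed percentage rounded half away from zero).
Reported percentage tables sum to 100 within rounding wherever the
classes are exhaustive.

## The synthetic-data generator

The simulator provides ground truth for every inference stage.  Per
family: a single copy enters at the species-tree root and evolves by a
birth–death process (duplication rate 0.1, loss rate 0.05 per unit
branch length by default; exponential waiting times); an extinct family
is resampled and the resample logged, so dataset size is exact.
Sequences (default 200 residues) descend from a uniform-random root
with per-branch substitution probability 1 − exp(−t) per site, uniform
over the other 19 residues — no rate heterogeneity, no indels, the
simplest process that exercises the inference.  True orthologs are
exactly the pairs whose LCA in the pruned gene history is a speciation.

Transfers (per-family probability 0.05 by default) copy a donor
sequence from a simulated prokaryote family onto the Dictyostelia stem,
after which it duplicates and mutates natively; donor pools carry four
prokaryote relatives (0.15 subs/site from the donor) and a eukaryote
clade (stem 1.3, radiation 0.3), so a transferred gene is markedly
closer to prokaryote than to eukaryote homologs — the regime the
validation logic assumes.  Native families instead receive one
opisthokont outgroup homolog at 1.2 subs/site.

Expression profiles are unimodal curves (Gaussian shape, σ = 1 stage)
peaking at a family-specific stage, scaled by per-sample library
factors (log-normal, σ = 0.3) and read as negative-binomial counts with
dispersion 0.1 (mild overdispersion typical of count data; dispersion 0
switches to noise-free rounded means).  With probability 0.3 one clade
— a single species, group 4, or branch I, chosen uniformly — has its
peak shifted by 2–3 stages.  Architectures are 1–4 tokens at the root
with per-branch gain/loss probability 0.03 each.

What the simulator does **not** emulate: indels and alignment
uncertainty, rate variation across sites and lineages, gene conversion,
incomplete lineage sorting, genuinely absent gene models, and
annotation noise.  Passing the recovery benchmarks therefore
demonstrates that the classification logic is correct under its own
assumptions, not that the pipeline is robust to every pathology of real
proteomes — for real data the Newick-import route with externally built
trees is the recommended path.

## Benchmarks and problem sizes

The recovery benchmarks (also recomputed by `scripts/acceptance.py`)
use: 500 families at duplication 0.1 / loss 0.05 for ortholog-call
precision and recall, scored per (focal gene, species) slot against the
event-log truth; 100 stem-transfer replicates and 100 transfer-free
families on duplication/loss-free trees for LGT sensitivity and
specificity (a transfer whose DD descendant was lost is undetectable by
a DD-centric screen and excluded from the denominator); 1,000 families
at θ = 0.25 for expression-pattern recovery; and a zero-rate control
that must give a pure one-to-one orthology readout.  Measured values at
these sizes: precision ≈ 0.999, recall ≈ 0.95–0.96, sensitivity
≈ 0.95–1.0, specificity 1.0, pattern accuracy ≈ 0.95.

## Numerical and degenerate-input conventions

Branch lengths serialize with 17 significant digits (exact float round
trip).  Missing internal-node supports are treated as resolved
(support 1.0), so imported trees without supports classify rather than
stall.  All-zero expression series are flagged silent, never divided
by zero; empty membrane sets and never-seen genome terms report NaN
with an undefined flag.  Families too small for a tree (< 3 genes)
classify by single-copy presence.  All randomness flows from explicit
seeds; per-family bootstrap seeds derive from the run seed via SHA-256,
so outputs are byte-identical across runs and processes.
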