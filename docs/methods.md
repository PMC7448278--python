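# Methods

## The similarity model

Two biosynthetic gene clusters are compared on two complementary axes.

**Backbone identity.**  The backbone enzymes (NRPS, PKS, DMAT) are the
clusters' scaffold builders; their catalytic domains evolve slowly enough
that sequence identity between them tracks whether two clusters make
related metabolites.  For every backbone-domain type present in both
clusters (whitelist: `AMP-binding`, `Condensation`, `PCP`, `PP-binding`,
`PKS_KS`, `PKS_AT`, `DMAT`, `TE`; configurable), each copy in one cluster
is matched to at most one copy in the other, greedily by best pairwise
identity, and the **median** identity over all matched pairs of all shared
types is the identity component *I*.  Unmatched extra copies are ignored;
if no type is shared, *I* = 0.  Greedy matching rather than an optimal
assignment keeps the procedure order-independent after sorting and easy to
verify against exhaustive enumeration on small cases; on realistic inputs
(clear homolog structure) the two coincide.

Identity itself is defined from a deterministic pairwise global
(Needleman–Wunsch/Gotoh) alignment: BLOSUM62 substitution scores, affine
gaps costing 10 to open and 0.5 per additional residue, end gaps penalized.
Identity = identical columns / total alignment columns, end gaps included,
so a truncated domain scores below a full-length match.  Pairwise
alignment (rather than one joint multiple alignment) was chosen for
determinism and testability; on closely related backbones the difference
surfaces only in low decimal places.

**Domain-content Jaccard.**  The protein-domain arrays of the two clusters
are deduplicated into sets and compared as `J = |A∩B| / |A∪B|`.  Two empty
sets are defined to have J = 0 — an uninformative pair contributes no
similarity.  This captures shared tailoring machinery that backbone
identity misses.

**Combined score.**  `S = w_id·I + w_jac·J` with default weights 0.8 / 0.2
(weights must sum to 1).  Identity dominates because backbone relatedness
is the stronger predictor of product similarity; the Jaccard term breaks
ties between clusters with similar backbones but different accessory
content.

## Family calling

Distance is `d = 1 − S`.  Families are DBSCAN clusters on the precomputed
distance matrix at `ε = 0.55` — equivalently, cluster pairs with score
≥ 0.45 are neighbors — with `minPts = 2`.  Choices worth noting:

* **minPts = 2** makes DBSCAN exactly the connected components of the
  ε-threshold graph, matching the "network subgraphs = families,
  leftovers = singletons" reading of the method, and making the result
  checkable against a brute-force component finder (done exhaustively for
  n ≤ 7 in the tests).
* **Inclusive neighborhood** (`d ≤ ε`): the boundary pair at score 0.45
  falls inside a family.
* `1 − S` is not a metric (triangle inequality can fail); DBSCAN is always
  run on the precomputed matrix, never on embedded coordinates.
* Noise points are reported as singletons; family labels are contiguous
  integers in first-appearance order.

**UPGMA** dendrograms use the same distance: iteratively merge the closest
pair, new node height = merge distance / 2, distances to the merged node =
size-weighted average of the children's distances.  Ties are broken by the
lexicographically smallest leaf label in the candidate nodes, making the
tree (and its Newick serialization, 12 significant digits on branch
lengths) fully deterministic.  The implementation is cross-checked against
scipy's average linkage in the tests; it is written in-package because the
tie-break and height conventions are part of the contract.

## Enzyme-family mining

Per-domain hmmsearch hits (domtblout) are filtered with three inclusive
criteria: model accession equals the target family (default PF01231, IDO),
subject protein length ≥ 350 residues, full-sequence E-value ≤ 1e-30.
"Minimum"/"maximum" thresholds are read inclusively; the full-sequence
(not per-domain) E-value is used, matching hmmsearch's primary ranking,
and "subject length" is the full protein length (`tlen`), not the envelope
— both are configurable, and the envelope-vs-full-length choice can move
borderline counts.  Copy numbers per genome count distinct proteins, so a
protein hit by two domain rows counts once.  Since domtblout has no genome
column, the writer/reader carry `genome=<id>` in the description field.

## Specificity codes

A query adenylation domain is globally aligned to a reference synthetase
sequence (the gramicidin S synthetase A-domain is the field's conventional
reference) and the query residues in the alignment columns of configured
1-based reference positions are reported, `-` where the query is gapped.
The default positions are the ten canonical binding-pocket positions of
the Stachelhaus-code literature (235, 236, 239, 278, 299, 301, 322, 330,
331, 517 in GrsA numbering); they are configuration, not hard-coded
science — any reference plus position list works.  Codes are compared by
simple positional identity with gaps matching nothing.  Substrate *naming*
(e.g. calling a pocket anthranilate-binding) is deliberately out of scope:
the package outputs codes and code-identity matrices, not predictions.

## Masses and isotope labels

Monoisotopic masses are summed from a built-in table (H 1.0078250319,
C 12 exactly, N 14.0030740052, O 15.9949146221, S, P, plus heavy isotopes
²H 2.0141017781, ¹³C 13.0033548, ¹⁵N, ¹⁸O).  `[M+H]+` supports two
conventions: **H-atom** (add 1.0078250319; default) and **proton** (add
1.0072764666, electron-corrected).  The H-atom convention is the default
because it reproduces the common shorthand used for printed [M+H]+ values
(e.g. C17H15N3O3 → 310.1192 at 4 dp; the proton convention gives
310.1186).  ppm error is `(observed − calculated)/calculated × 1e6` and is
always reported from the package's own conventions.

Label scenarios are explicit data, not inferred chemistry: each shipped
scenario states how many atoms were labeled and how many are retained
through the biosynthetic transformation, with a prose retention note.  The
two built-ins encode the anthranilate ring-¹³C₆ feed (6 labeled, 6
retained → +6 Da) and the tryptophan ring-D₅ feed (5 labeled, 4 retained →
+4 Da: IDO ring cleavage makes the indole C2 the formyl carbon of
N-formyl-kynurenine, and that deuteron leaves on deformylation to
kynurenine).  Retention maps are data because the biology, not an
atom-mapping algorithm, determines them.

## Synthetic data

The generator emulates the statistical structure the score assumes:
families share a mutated archetype backbone and a core domain set;
singletons share neither.

* **Identity control**: members mutate the family archetype at per-site
  rate `1 − √target` (substitutions only, always to a different residue,
  no indels), so two members match at ≈ the target identity (plus a
  ≈ rate²/19 collision term).  Backbone lengths are uniform on 300–600
  residues, the scale of real A-domains.
* **Jaccard control**: a family core of backbone-domain names plus 6
  tailoring domains, with `m = core·(1−J)/(2J)` private domains per member
  (distinct within a family), gives pairwise Jaccard `core/(core+2m)` —
  met in expectation, not exactly; tests check medians at documented
  tolerances.
* **Separation**: family cores and singleton domains are drawn from the
  pool without replacement, archetype architectures rotate (NRPS
  A-T-C-A-T-C-T, PKS, DMAT, ...), and archetype sequences are independent
  random draws, so between-family identity/Jaccard sit near the random
  baseline (≲ 0.2 each, combined score ≈ 0.15, far below the 0.45 family
  threshold).
* The hit-table generator plants policy-passing rows (the first exactly on
  both inclusive boundaries) among decoys that each violate one recorded
  criterion (too short, E-value too high — the first just past the
  boundary — or wrong accession).

Everything is driven by one `numpy` generator seeded from the config;
outputs are byte-identical across reruns.  What the generator does *not*
model: indels and alignment-length variation, rate heterogeneity, gene
order/synteny, shared tailoring content between real related families, and
hmmsearch score correlations.  Passing the recovery tests therefore shows
the pipeline is correct under its own assumptions, not that ε = 0.55 is
optimal on real genomes.

## Problem sizes and numerics

Tests run at desk scale by design: family-recovery suites use 2–5 families
of 3–4 members plus singletons (8–17 clusters, ≤ ~140 alignment pairs);
the DBSCAN-vs-components equivalence is exhaustive over random matrices up
to n = 7; the alignment oracle covers random pairs up to length 8 against
an independent three-state affine-gap dynamic program.  Distance-matrix
symmetry is validated to 1e-12; score clamping guards floating-point drift
at the [0, 1] edges; UPGMA and DBSCAN inherit exact tie behavior from the
deterministic constructions above.

## Known limitations

* The canonical input is the JSON manifest; there is no antiSMASH GenBank
  importer.
* Profile-HMM scoring itself (hmmsearch) is consumed, not reimplemented;
  likewise no maximum-likelihood phylogenetics or bootstrapping.
* Specificity codes from pairwise alignment can disagree with a joint
  multiple alignment near gappy regions.
* Isotope work covers monoisotopic bookkeeping only — no isotope-pattern
  fine structure, mzML parsing, or MS² annotation.
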