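# Methods

`paralognet` compares the protein-protein interaction (PPI) networks of a
family of paralogous hub proteins — the seven human 14-3-3 isoforms (beta,
gamma, epsilon, eta, sigma, theta, zeta) are the motivating case — by their
partner sets, directed wiring, post-translational modification (PTM)
composition, domain content and Gene Ontology (GO) enrichment.  This note
records the models, the defaults and the design choices behind each stage,
and what the synthetic-data tests do and do not establish.

## Network model

The full network is an undirected graph over proteins identified by
normalized UniProt-style accessions (uppercased, isoform suffixes such as
`-2` stripped, so gene-product level analysis sees one record per protein).
Edges come from a tab-separated interaction table and are deduplicated as
unordered pairs; self-interactions are dropped, since hub homodimerization
does not bear on cross-paralog comparisons.  Each node carries a
`ProteinRecord`: length, domain annotations, intrinsic-disorder segments,
PTM sites, GO terms, localization labels, an NLS flag and an optional kinase
group.  All residue coordinates are 1-based inclusive.

A paralog's *partners* are the direct neighbours of its hub node.  The
optional kinase layer adds one extra hop from partners, restricted to
kinase-tagged neighbours and substrates of kinase partners; the "clients"
count is the union of all seven partner sets.  Network similarity
is the Jaccard coefficient |A∩B| / |A∪B| over partner sets — partner
identity is the only set defined for every isoform, whereas edge sets are
dominated by the hub star.  An empty-vs-empty comparison is defined as 0 and
logged.

Degenerate inputs: unknown protein length falls back to the maximal
annotated coordinate; domain spans beyond a known length are clipped with a
warning; overlapping disorder segments are merged at load.  Malformed rows
(non-integer positions, residue/modification mismatches such as acetylation
on serine, clade identifiers outside 1–1250) are rejected into a per-file
report rather than silently dropped, because the downstream statistics pivot
on residue identity and category membership.

## Edge orientation

Undirected edges are oriented with a categorical naive Bayes classifier, as
a deterministic stand-in for curated direction assignment.  For an ordered
pair (a, b) the class `forward` means a→b.  Default features: relative
degree (greater/less/equal), per-endpoint kinase flags, and per-endpoint PTM
counts binned at training-set terciles.  Conditional category probabilities
use add-α smoothing (α = 1 by default) over the categories seen in training
plus a reserved `unknown` level, so unseen categories keep non-zero mass.
Posteriors over the two classes sum to 1; exact ties orient toward the
lexicographically smaller accession (logged, deterministic).  Curated
kinase→substrate directions override the classifier by default.  The feature
schema is pluggable; no attempt is made to reproduce any specific external
training corpus, because downstream motif analysis only requires a
deterministic, better-than-chance orientation procedure (held-out accuracy
on generated data is ≈ 0.78 against a 0.5 baseline).

## Triad motifs

The 13 weakly-connected isomorphism classes of 3-node digraphs are
enumerated and numbered 1–13 in the standard motif-dictionary order used by
triad significance profiles: 3 is the linear cascade X→Y→Z, 7 the
feed-forward loop (X→Y, X→Z, Y→Z), 10 the mutual pair jointly regulating a
third node.  The classification table is built from the 64 possible 3-node
adjacencies reduced by node permutation and validated at import (54
connected masks partitioning into exactly 13 classes); tests cross-check it
against exhaustive enumeration and networkx's independent triadic census.

Significance uses a switching (double-edge-swap) null applied separately to
the unidirectional and the reciprocal edge subsets, which conserves every
node's in- and out-degree *and* the reciprocal-pair count exactly, rejecting
swaps that would create self-loops, parallel edges or new reciprocal pairs.
The default is 10 successful swaps per edge; networks too rigid to swap are
returned unchanged with a warning.  Per class, enrichment is one-sided:
z = (real − mean)/sd over the ensemble and an empirical
p = (1 + #{random ≥ real}) / (R + 1), so p is never 0 and is bounded below
by 1/(R+1); z is flagged NaN when the null sd is 0.  The default ensemble is
1000 networks with α = 0.05.  Depletion is visible through negative z but
is reported informationally only.

## PTM composition and crosstalk

Every modified residue maps to exactly one structural region: `domain`,
`disordered`, or `other`.  When a curated domain overlaps a predicted
disorder segment, domain wins (domains are the more specific curated
annotation; the precedence is configurable).  Composition tables count
pSer/pThr/pTyr/acetyl-Lys per region; phospho percentages share one
denominator per region — all phospho sites in that region — so the three
percentages sum to 100.

Cross-network comparisons are two-sided Fisher exact tests on 2×2 tables
(network A vs B × property vs not), at the unit the question demands (sites
for composition fractions, proteins for burden and crosstalk).  Raw p-values
are reported, matching the uncorrected pairwise ranges such analyses
conventionally quote; Benjamini–Hochberg q-values are an optional extra
column.  The acetylation burden is compared two ways: Fisher on the fraction
of partners with ≥ 1 acetyl-lysine, and Wilcoxon rank-sum on per-partner
acetyl-site counts.  The second exists because at realistic site densities
most partners carry at least one acetyl-lysine, the binary indicator
saturates, and the partner-level test loses power precisely when the
site-level burden differs most; both matrices are emitted.

Disorder content is compared three ways, reported side by side: an omnibus
Kruskal–Wallis across all seven partner sets, pairwise Wilcoxon rank-sum on
per-partner disorder fractions, and pairwise Fisher on partners binarized at
a configurable disorder-fraction threshold (default 0.5).  The Wilcoxon
implementation uses mid-ranks for ties, exact enumeration up to a pooled
size of 12 and a tie- and continuity-corrected normal approximation above;
Fisher two-sided p sums point probabilities ≤ the observed one with a
1 + 1e-7 tolerance factor (the R convention).

Localization statistics test NLS concentration in a partner subset as a 2×2
(in-subset × has-NLS) Fisher table, alongside the subset fraction, the
mainly-nuclear fraction and the subset's share of all partner NLS.

## Domain and clade analysis

The counting unit is protein-level presence: a partner counts once per
domain type regardless of copy number, because the pairwise Fisher tables
require per-protein binary states; instance counts are retained for
size/abundance fits.  Coiled-coil (CC) and transmembrane (TM) annotations
are excluded by default as super-numerary.  Heat-map data are the raw
relative frequencies over the union of each network's top-10 domains (ties
broken by higher count, then name); whether a renderer normalizes rows or
columns is left to the renderer.  The significance bipartite network links
an isoform to a domain when its presence differs from at least one other
isoform at p ≤ 0.01 (configurable), with a sign comparing the isoform's
frequency to the mean of the others — both significant presence and
significant absence are kept.  Modified-domain profiles count a domain as
phospho- or acetyl-modified iff a matching site falls within its span.
Clade ("domain club") profiles consume an external protein→clade mapping
(1–1250); clades ≥ 1081 are treated as isolated-domain clades (configurable
boundary, since the split is approximate by construction).

## GO enrichment

The ontology is parsed from OBO 1.2; obsolete terms are dropped with a
count, and only `is_a` edges are traversed by default (`part_of` optional).
Annotations propagate to all ancestors under the true-path rule before
testing.  Per term, p is the upper-tail hypergeometric probability
P(X ≥ k) for k annotated among the query of size n, given K annotated in a
universe of N; the universe defaults to the full assembled network (an
external whole-genome universe would require data the pipeline does not
assume).  BH q-values are computed per namespace per query.  An adaptive
threshold can pick the largest p cutoff retaining between 35 and 50 terms
(nearest achievable size, with a warning, when the window is unreachable),
and cross-network comparison tables hold −log10 p for terms significant at
α = 0.05, with untested cells flagged separately from non-significant ones.

## Synthetic data generator

The generator emits every input file plus a ground-truth record, so each
stage has calibration and recovery tests with known answers.  Defaults (the
study conditions all calibration/power results refer to):

| parameter | default |
|---|---|
| protein pool | 800 proteins |
| protein length | log-normal, median 450, σ = 0.6 |
| domains per protein | geometric, mean 1.6; lengths uniform 60–250, non-overlapping |
| disorder | Beta(1.6, 3.4) target fraction, segments in inter-domain gaps, 5% spill-over into domains |
| PTM rates (per residue) | pS 0.02 disordered / 0.004 domain / 0.008 other; pT half of pS; pY 0.002 / 0.003 / 0.002; acK 0.002 / 0.006 / 0.003 |
| partner sets | 120 per hub; base pairwise Jaccard 0.10; theta–beta override 0.273 |
| planted effects | epsilon pY-in-domain ×2.5, zeta acetylation ×2.0, gamma RRM domain ×8, gamma GO-term ×5 |
| kinases | 15% of the pool, Poisson(3) substrates each, group weights roughly matching the human kinome |
| directed layer | kinase→substrate fires 0.9, higher-degree→lower 0.75; 30 planted feed-forward loops |
| GO | 60-term, 3-level toy DAG over two namespaces; leaf annotation rate 0.03 (common terms 0.10) |

Choices worth recording:

* *Per-residue Bernoulli placement.*  Site counts per region are binomial in
  the region's residue count at the configured rate; positions are drawn
  without replacement so no residue carries two modifications.  This is the
  simplest mechanism consistent with phosphosites concentrating in
  disordered segments and acetyl-lysines in ordered regions; it ignores
  sequence motifs, kinase specificity and site clustering.
* *Shared-pool overlap.*  Partner sets are a shared core (sized
  2nJ/(1+J) for base Jaccard J) plus pair-specific extras and disjoint
  private remainders, hitting targets in expectation; infeasible targets
  raise an error stating the achievable range.
* *Effects attach to isoform-exclusive partners.*  Shared-core partners
  belong to every network; boosting them would weaken the contrast the
  effect exists to create.
* *Planted FFL power uses a flat background.*  The full bundle's hub-star
  degree sequence makes its switching null intrinsically FFL-rich, so FFL
  planting there cannot produce enrichment; `planted_ffl_network` provides a
  uniform random background (150 nodes / 400 edges / 30 planted FFLs by
  default) where the signal is clean.  The bundle still plants FFLs for
  location-level ground truth.
* *Acetylation couples to nuclear localization and NLS* (multipliers 2.0 /
  2.5) so the localization statistics have a recoverable signal.

What passing tests on this generator do **not** show about real data: real
interactomes have heavy-tailed degree distributions, study bias, correlated
annotations and motif-specific PTM placement, none of which are modelled;
the generator demonstrates that the *statistics* are calibrated and
powerful under their own assumptions, not that those assumptions hold for
any particular database snapshot.

## Problem sizes used by the test suite

Calibration and power checks run at sizes chosen as a deliberate
compromise between Monte Carlo resolution and suite runtime: Fisher/Wilcoxon
type-I calibration over 150 null bundles (pool 400, 60 partners per hub);
motif type-I calibration over 40–60 degree-matched null networks with
ensembles of 49–59; effect-recovery power over 60 seeds per effect at the
full default conditions, with FFL recovery using ensembles of 199 (minimum
empirical p 0.005 < α = 0.01).  Oracle-equivalence checks are exhaustive:
all 2×2 tables with total ≤ 40, all hypergeometric tails with universe ≤ 25,
and triad censuses on 200 random digraphs with ≤ 12 nodes against brute
force.

## Pipeline and reproducibility

`run_pipeline` chains the stages and writes plain CSVs plus a manifest
holding the config snapshot, input SHA-256 hashes and output hashes.  A
rerun with an unchanged config over unchanged inputs is detected via the
manifest and skipped; any change reruns the pipeline as a whole (per-stage
content-addressed caching was considered and rejected as complexity the
pipeline's ~seconds runtime does not justify).  All randomness flows from
the single config seed through `numpy.random.SeedSequence` spawning, so
identical config + seed gives hash-identical outputs.  Figures are
deliberately not produced; every figure-shaped result (heat-map data,
bubble-plot data, box-plot inputs) is exported as CSV.

## Known limitations

* The naive Bayes features are structural (degree, kinase flags, PTM
  counts); orientation accuracy on real data depends on how informative
  those features are there.
* Motif empirical p-values are bounded below by 1/(ensemble+1); very small
  printed p-values require proportionally large ensembles.
* The Fisher-based comparisons are conservative at small counts (discrete
  test), visible in type-I rates below nominal α in the calibration runs.
* The GO universe is the assembled network, so enrichment is relative to
  the network's own composition, not to a genome background.
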