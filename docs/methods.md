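# Methods

## Scope and model

`sigcensus` implements a deterministic, rule-based census of bacterial
signal-transduction systems.  The unit of evidence is the *resolved domain
architecture* of a protein — an ordered, largely non-overlapping list of
domain hits — plus the protein's position in the genome's gene order.
There is no statistical fitting anywhere in the pipeline: every call is a
rule over domain composition, domain order, sequence motifs, or gene
neighborhood, and identical inputs always produce identical outputs.

The package deliberately consumes *precomputed* domain tables.  Running
hmmscan/BLAST, curating hits against external databases, and building
phylogenies are out of scope; the census starts where those searches end.

### Coordinates and gene distance

Nucleotide and amino-acid coordinates are 1-based inclusive.  Gene order
on a replicon is captured by a 0-based ordinal; the distance between two
genes is the number of *intervening* genes, `|Δordinal| − 1`,
strand-ignored, with genes on different replicons infinitely far apart.
Non-coding and pseudogene records occupy ordinals — "four genes away"
counts all genes, the way a genome browser does.  The boundary convention
for solo HKs is explicit: *more than four genes away* means distance > 4;
an RR exactly four genes away still links.  This convention is isolated in
one place (`Genome.distance` plus the window comparisons) because an
off-by-one here would silently shift every census column.

### Architecture resolution

Raw hits on a protein are filtered greedily by descending bit score; a
candidate is rejected when it overlaps an accepted hit by more than a
configured fraction (default 0.2) of the shorter interval.  Ties in score
break deterministically by (start, end, name).  The result is maximal —
no rejected hit can be added back — and the property suite asserts both
maximality and the overlap bound on random inputs.  The default e-value
threshold (1e-5) is applied uniformly to all domain tables.

### Two-component systems

* HK: at least one HisKA and one HATPase-family hit.
* HHK / HRR: a REC domain whose midpoint lies after the last HATPase end
  (C-terminal → HHK) or before the first HisKA start (N-terminal → HRR).
  Proteins with REC on both termini, or only interior REC domains, are
  labeled HHK with a warning; the biology is ambiguous and the choice is
  a stated convention.
* RR: REC without the HisKA+HATPase pair.  RR outputs are categorized
  cdgmp_enzyme (GGDEF/EAL/HD-GYP present) > dna_binding (any domain in
  the configurable HTH list) > other_unknown; the precedence means a
  REC+GGDEF+HTH chimera counts on the c-di-GMP side (logged).
* Linkage: adjacent HK/HHK–RR pairs; otherwise one-to-one links when each
  side has exactly one candidate within the window (default 4), multi
  links when several.  "RR gene" here and in solo flagging means role RR
  only; HRRs are treated as atypical kinases.
* Atypical clusters: signaling genes (any system) chained while at most
  `max_gap` (default 2) non-signaling genes intervene; chains with at
  least `min_atypical` (default 2) HHK/HRR genes are reported.  The
  parameters are configurable because no formal definition exists for
  these regions; the defaults make dense hybrid-kinase neighborhoods
  detectable without merging across ordinary operon gaps.

### c-di-GMP enzymes

DGCs/PDEs are identified by GGDEF, EAL and HD-GYP domains; every other
domain on the protein (REC, sensory domains, TM annotations) is a partner
domain.  When sequence is available, each GGDEF domain gets an A-site
call: the first exact occurrence of GGDEF/GGEEF/SGDEF/AGDEF in the domain
subsequence is an active site; otherwise a degenerate site is anchored by
a two-stage pattern (`xG[DE][EQ]F`, then `xx[DE]EF`) and the observed
5-mer reported.  The anchor replaces the reference-alignment step a
manual analysis would use, at the cost of reporting an empty motif when a
domain is too diverged for either pattern.  The I-site is an RxxD whose R
lies 1–15 residues upstream of the A-site start (canonically ~5; window
configurable).  A protein with several GGDEF domains is active if any
domain is.  Without sequence, calls are `unknown` rather than guessed.

The six per-genome categories: total DGCs (degenerate GGDEF proteins
included by default, switchable), DGCs with partner, PDEs with partner,
bifunctional GGDEF+EAL/HD-GYP, single-domain enzymes, and active DGCs.
Bifunctional proteins are excluded from the with-partner columns to keep
the categories close to a partition; this convention is documented and
switchable because supplementary tables of published censuses do not pin
it down.  `active_dgc = 0` is the biologically meaningful "no c-di-GMP
production" state even when degenerate GGDEF proteins remain.

### Chemosensory system

Components are identified by diagnostic domains with a documented
precedence (CheA = HATPase+Hpt before the stas_STYK rule can see it;
CheV = CheW+REC before CheW; etc.).  Two calls are context-restricted:
single-REC proteins become CheY, and single-STAS proteins become cluster
members, only when they lie inside a chemosensory cluster — otherwise
they remain an ordinary RR / STAS protein.  This stops the CheY rule from
swallowing every orphan response regulator.

Clusters chain chemosensory genes (and histidine-kinase genes, which some
classes carry in-operon) while at most `max_gap` (default 2) unrelated
genes intervene, and span the full gene range so interleaved hypothetical
genes stay visible to the alignment.  A chain must contain at least one
core che component; singleton chemoreceptors are orphan receptors, not
clusters.

Class assignment aligns the cluster's token string (A/B/.../M/K/S/"."
per gene) against each configured signature, in both orientations,
maximizing matched signature tokens subject to the insertion budget
(unmatched cluster genes inside the matched span, default 2).  The
implementation is a memoized dynamic program; the test suite proves it
equal to exhaustive enumeration on random clusters.  Scoring:

* completeness = (required components matched in the cluster + auxiliary
  rules satisfied) / (n required + n auxiliary).  Required components are
  scored *within the cluster*: a half cluster stays half even when
  another class elsewhere in the genome carries the missing component.
  Only the named auxiliary rules (e.g. F3's CheB lacking REC) search
  genome-wide, since auxiliary components legitimately live outside the
  cluster.
* signature score = mean(alignment fraction, completeness).  Gene order
  must contribute: classes can share a component set and differ only in
  order, so completeness alone cannot separate them.
* best score wins; ties break by configured priority (F3 first); a best
  score below the partial floor (default 0.4) leaves the cluster
  unassigned.

Status bands: full at completeness 1, half in [0.4, 0.8), partial
otherwise — the bands implement a full-circle/half-circle reporting
convention and are configurable.  Clusters containing component tokens
foreign to the winning signature are annotated `mixed_component` rather
than forced into a class.

Signatures are data, not code.  F3 ships from its textual definition
(core cheVAW operon, REC-bearing CheA, auxiliary REC-less CheB).  The
F7/F8/F9/F14 gene orders exist only graphically in the source material;
the shipped strings are best-effort, marked figure-derived in the YAML,
and meant to be overridden — except the F9 default, whose component set
is anchored on the textual half-F9 description (receptor, CheW, CheB,
CheR, no kinase or response regulator).

### ECF, cAMP, STYK, QS, merged pathways

ECF σ factors use exact-set semantics: exactly one σ70-region-2 and one
σ70-region-4.2 domain and nothing else; any extra domain disqualifies.
ECF242 is detected structurally (an ECF gene with a FecR-domain gene
within 4 genes; a TonB-dependent receptor in the window recorded as
supporting evidence); assignment to the broader ECF group nomenclature is
out of scope.  The cAMP cluster is a cyclase (CHASE2 sensor noted) with
at least two of {cAMP-PDE, FecR-domain protein, TPR protein} within 6
genes; a cyclase alone still counts the system present, and CRP-like
regulators in a cyclase-free genome are flagged "CRP without cyclase".
STYK rules: Pkinase → eSTYK; Pkinase+PP2C → bifunctional; HATPase family
without HisKA (and without Hpt, so CheA is excluded) → stas_STYK; PP2C
alone; single STAS.  The QS screen calls a pathway present only when both
a synthase-domain and a receptor ligand-binding-domain hit exist; the
shipped probe list is a best-effort compilation and user-overridable.

Merged-pathway candidates fire on co-occurrence within a window (default
6): PP2C + stas_STYK + STAS + c-di-GMP enzyme; REC-fused PP2C–Pkinase +
STAS + chemoreceptor; ECF components + cAMP/c-di-GMP enzyme.  Rules that
would need transmembrane/periplasmic evidence degrade to
confidence="low" when no TM annotations were provided instead of
refusing to fire.

### Census

One row per genome with a fixed, documented column order.  RR output
proportions are computed over role-RR proteins and are NaN (never 0/0)
when a genome has no RRs; HRR outputs are classified but not pooled.
Per-ecotype aggregation pools RR output categories across the group
(summed counts over summed RRs), not per-genome means, and reports
mean/median abundances; unknown-ecotype genomes form their own group.

## Synthetic data generator

The generator is the package's ground-truth instrument: directives
("implant a solo HK at distance 5", "implant an F9 cluster at half
completeness", "implant a DGC with SGDEF and an intact I-site") are
realized as gene blocks with domain hits emitted directly into the domain
table, plus a per-protein/per-cluster/per-census-column ground truth
record.  Design choices:

* Implant blocks are separated by a margin of background genes (default
  9) exceeding every neighborhood window, so directives cannot interact
  unless one deliberately co-locates genes.  Background genes are
  hypothetical or carry one inert decoy domain that maps to no
  vocabulary role.
* DGC protein sequences use an alphabet without G/D/E/F/R outside the
  implanted motifs, so the implanted A-site (and the RxxD I-site, when
  requested) is provably the only anchor; the `audit` function re-checks
  every emitted genome against its own promises.
* Sequences are only generated for GGDEF-bearing proteins — the only
  sequence consumers are the A-/I-site calls.
* Domain hits are emitted directly rather than via an HMM search,
  keeping tests hermetic.
* Half clusters are supported for signatures without auxiliary rules by
  keeping the longest gene-order prefix whose completeness stays inside
  the half band; half clusters of aux-ruled signatures (F3) are refused
  because their completeness would depend on the rest of the genome.
* `perturb` drops each domain hit independently and/or adds decoy hits,
  for robustness measurement against the closed-form survival
  probability (1−p)^k of a label requiring k hits.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: homology-search noise (partial
hits, wrong boundaries, heterogeneous e-values), domain families outside
the shipped vocabulary, operonic co-orientation structure, overlapping
genes, multi-hit repeat domains (TPR arrays), or genuinely ambiguous
architectures that a human curator would resolve against MiST/SMART/
HHpred.  Real-genome runs therefore inherit the quality of the input
domain annotation in a way the synthetic suite cannot measure.

## Problem sizes in the shipped measurements

The reproduction script builds a 30-genome cohort (~1500 gene slots per
genome) for recovery, 200 smaller genomes (~900 slots) for invariants,
1000 random clusters for the alignment oracle, 2000 proteins per role
for the noise experiment, and 9 fixtures for the symmetry check; the
whole script runs in well under a minute on one CPU.  These sizes were
chosen so that stochastic comparisons (noise recall vs. the binomial
oracle at ±3 percentage points) are dominated by the method, not by
small-sample noise.

## Known limitations

* Half/full completeness bands, neighborhood windows, the overlap
  fraction and the atypical-cluster parameters are conventions, not
  measurements; all are configurable and their defaults documented above.
* The manual re-examination step of published censuses (database
  cross-checks of every candidate) has no algorithmic counterpart here.
* Chemoreceptor heptad (H-class) typing is not implemented.
* ECF group assignment beyond the structural ECF242 detection is not
  implemented.
* The degenerate A-site anchor can miss extremely diverged GGDEF domains
  (reported as degenerate with an empty motif rather than located).
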