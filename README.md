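# sigcensus

A rule-based census of bacterial signal-transduction systems, built for
comparative genomics of phyla such as *Campylobacterota* where signaling
repertoires track ecological niche (hydrothermal-vent specialists,
free-living generalists, host-associated specialists).

Given an ordered gene table (GFF3 or TSV), per-protein domain annotations
(HMMER3 `--domtblout` or TSV) and optionally protein sequences (FASTA),
`sigcensus` classifies every protein into the major signaling systems and
assembles per-genome and per-ecotype census tables:

* **Chemosensory system** — component inventory (CheA/B/C/D/R/V/W/X/Y/Z,
  chemoreceptors), genomic cluster detection, and chemosensory class
  (F-class) assignment by aligning each cluster's gene-order token string
  against configurable class signatures, with full/half completeness
  scoring.
* **Two-component systems (TCS)** — HK (HisKA + HATPase), hybrid kinases
  HHK (C-terminal REC) and hybrid regulators HRR (N-terminal REC),
  response regulators and their output types (DNA-binding HTH, c-di-GMP
  enzyme, other); solo-HK flagging ("more than four genes from any RR");
  HK–RR linkage within a four-gene window; detection of gene clusters
  enriched in atypical HKs.
* **c-di-GMP system** — DGCs (GGDEF), PDEs (EAL / HD-GYP), bifunctional
  enzymes; sequence-level A-site activity calls (GGDEF/GGEEF/SGDEF/AGDEF
  = active, anything else degenerate) and RxxD I-site integrity; the
  six per-genome enzyme categories including *active DGCs*, the column
  that decides whether a genome can produce c-di-GMP at all.
* **ECF σ factors** (exactly σ70-region-2 + σ70-region-4.2 and nothing
  else), the FecI/FecR/FecA "ECF242" neighborhood, the CHASE2-cyclase
  cAMP gene cluster, CRP-like regulators, Ser/Thr/Tyr kinases (eSTYK,
  stas_STYK), PP2C phosphatases, STAS proteins, a quorum-sensing domain
  screen, and candidate pathways that merge two or more systems in one
  neighborhood.

All domain-name dialects (Pfam accession, Pfam name, SMART name) are
handled by a YAML vocabulary; class signatures and QS probes are YAML
data too, so the rules are configurable without touching code.

A first-class synthetic-genome generator (`sigcensus.synth`) produces
gene tables, domain tables and protein sequences with known ground truth
for every rule in the package, which is how the pipeline is tested
offline — no databases or search tools required.

## Worked example

Generate the "free-living generalist" archetype genome and run the full
census on it:

```bash
sigcensus synth --archetype generalist --seed 7 --outdir demo/generalist
sigcensus census --input-dir demo --metadata demo/generalist/metadata.tsv \
                 --outdir demo_out
```

`demo_out/census.tsv` then contains one row for the genome; the key
columns print as:

```
n_total_HK               27
n_HHK                    5
n_HRR                    4
n_solo                   1
n_RR                     27
rr_prop_cdgmp_enzyme     0.037037037037037035
total_dgc                11
active_dgc               9
n_cdgmp_enzymes          13
class_F3                 full
class_F7                 full
class_F9                 half
n_ecf242_clusters        2
n_stas_styk              2
n_combined_pathways      1
n_atypical_clusters      2
```

Reading: the genome encodes 27 histidine kinases of which 5 are hybrid
kinases and 4 hybrid regulators (the atypical HKs sitting in 2 detected
signaling-gene clusters); one HK is solo.  Of 27 response regulators,
3.7% use a c-di-GMP enzyme as output.  11 of the 13 c-di-GMP enzymes are
DGCs, 9 of them with an intact A-site motif, so the genome can make
c-di-GMP.  The chemosensory system has a complete F3 class (the ancestral
cheVAW operon), a complete F7 class and a half F9 class, and the genome
carries two ECF242 (FecI–FecR) clusters, two stas_STYK kinases and one
candidate merged PP2C–stas_STYK–STAS–DGC pathway.

`demo_out/` also holds the per-protein tables (`tcs.tsv`, `cdgmp.tsv`,
`chemo.tsv`, `aux.tsv`), `combined_pathways.json`, `census.json` and the
per-ecotype aggregate `ecotype_summary.tsv`.

## Configuration

* `src/sigcensus/data/vocabulary.yaml` — domain-name → role-token map.
* `src/sigcensus/data/signatures.yaml` — chemosensory class signatures
  (gene order, required components, auxiliary rules, insertion budget).
* `src/sigcensus/data/qs_vocabulary.yaml` — quorum-sensing probes.
* `--config` YAML — thresholds and windows (e-value cutoff, overlap
  fraction, linkage/solo window, cluster gaps, half/full completeness
  band); see `sigcensus.pipeline.PipelineConfig` for fields and defaults.

See `docs/methods.md` for the model, rule definitions, parameter
rationale and known limitations.
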