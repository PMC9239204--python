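"""End-to-end classification of one genome.

Runs every census module in the right order and applies the cross-system
precedence rules that pure per-architecture functions cannot know about:

* chemosensory components are identified first; proteins claimed by the
  chemosensory system (CheA, CheB, CheV, CheY, ...) are excluded from the
  TCS role census, which mirrors how the two systems are censused
  separately even though e.g. CheB is REC-bearing;
* CheY calls (single-REC proteins) survive only inside chemosensory
  clusters — everything else stays a plain response regulator;
* auxiliary STYK rules never see TCS HKs (HisKA guard) or CheA (Hpt guard).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import aux_systems as aux
from . import cdgmp, chemo, tcs
from .model import Genome, ProteinArchitecture
from .vocab import DomainVocabulary

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds in one place (documented defaults)."""

    evalue_threshold: float = 1e-5
    overlap_frac: float = 0.2
    tcs_window: int = 4          # HK-RR linkage and solo flagging
    near_hk_window: int = 4      # REC-bearing enzyme near an HK gene
    ecf242_window: int = 4
    camp_window: int = 6
    combined_window: int = 6
    che_max_gap: int = 2
    atypical_max_gap: int = 2
    atypical_min: int = 2
    partial_floor: float = 0.4
    half_band: tuple[float, float] = (0.4, 0.8)
    isite_window: int = 15
    include_degenerate_in_total: bool = True


@dataclass
class GenomeClassification:
    """Everything the pipeline knows about one genome."""

    genome: Genome
    tcs_roles: dict[str, tcs.TcsRole] = field(default_factory=dict)
    links: list[tcs.TcsLink] = field(default_factory=list)
    solo: dict[str, bool] = field(default_factory=dict)
    rr_outputs: dict[str, tcs.RrOutputCategory] = field(default_factory=dict)
    cdgmp_proteins: list[cdgmp.CdgmpProtein] = field(default_factory=list)
    cdgmp_counts: cdgmp.CdgmpCategoryCounts = field(default_factory=cdgmp.CdgmpCategoryCounts)
    che_components: dict[str, chemo.CheComponent] = field(default_factory=dict)
    che_clusters: list = field(default_factory=list)
    che_assignments: list[chemo.ChemoClusterAssignment] = field(default_factory=list)
    n_chemoreceptors: int = 0
    aux_classifications: dict[str, aux.AuxClassification] = field(default_factory=dict)
    ecf242: list[aux.Ecf242Candidate] = field(default_factory=list)
    camp_clusters: list[aux.CampCluster] = field(default_factory=list)
    crp_without_cyclase: list[str] = field(default_factory=list)
    qs_reports: list[aux.QsPathwayReport] = field(default_factory=list)
    combined: list[aux.CombinedPathwayCandidate] = field(default_factory=list)
    atypical_clusters: list[tcs.AtypicalCluster] = field(default_factory=list)
    signaling_genes: set[str] = field(default_factory=set)

    def aux_pids(self, system: str) -> set[str]:
        return {p for p, c in self.aux_classifications.items() if c.system == system}


def classify_genome(
    genome: Genome,
    architectures: dict[str, ProteinArchitecture],
    vocab: Optional[DomainVocabulary] = None,
    signatures: Optional[list[chemo.FClassSignature]] = None,
    qs_vocab: Optional[dict] = None,
    config: Optional[PipelineConfig] = None,
) -> GenomeClassification:
    """Run the full signal-transduction census on one genome."""
    vocab = vocab or DomainVocabulary.default()
    signatures = signatures if signatures is not None else chemo.load_signatures()
    config = config or PipelineConfig()
    result = GenomeClassification(genome=genome)

    # restrict to architectures of proteins actually on this genome
    archs = {
        pid: a for pid, a in architectures.items()
        if genome.gene_for_protein(pid) is not None
    }

    # ---- raw TCS roles (pure, per-architecture; filtered below)
    raw_roles = {pid: tcs.classify_tcs_protein(a, vocab) for pid, a in archs.items()}
    kinase_gene_ids = {
        genome.gene_for_protein(pid).gene_id
        for pid, r in raw_roles.items()
        if r.role in ("HK", "HHK")
    }

    # ---- chemosensory components first (they take precedence over TCS)
    raw_components: dict[str, chemo.CheComponent] = {}
    for pid, arch in archs.items():
        comp = chemo.identify_che_components(arch, vocab)
        if comp is not None:
            raw_components[pid] = comp
    clusters, components = chemo.find_che_clusters(
        genome, raw_components, max_gap=config.che_max_gap,
        kinase_gene_ids=kinase_gene_ids,
    )
    result.che_components = components
    result.che_clusters = clusters
    result.n_chemoreceptors = chemo.count_chemoreceptors(components)

    # ---- TCS census (chemosensory proteins excluded)
    tcs_roles = {
        pid: r for pid, r in raw_roles.items()
        if r.role != "none" and pid not in components
    }
    result.tcs_roles = tcs_roles
    result.links = tcs.link_hk_rr(genome, tcs_roles, window=config.tcs_window)
    result.solo = tcs.flag_solo(genome, tcs_roles, window=config.tcs_window)
    result.rr_outputs = {
        pid: tcs.classify_rr_output(archs[pid], vocab)
        for pid, role in tcs_roles.items()
        if role.role in ("RR", "HRR")
    }

    # ---- c-di-GMP enzymes
    for pid, arch in archs.items():
        p = cdgmp.identify_cdgmp(arch, vocab, isite_window=config.isite_window)
        if p is not None:
            result.cdgmp_proteins.append(p)
    result.cdgmp_proteins.sort(key=lambda p: p.protein_id)
    result.cdgmp_counts = cdgmp.categorize(
        result.cdgmp_proteins,
        include_degenerate_in_total=config.include_degenerate_in_total,
    )
    cdgmp.flag_near_hk(genome, result.cdgmp_proteins, tcs_roles,
                       window=config.near_hk_window)

    # ---- F-class assignment (needs HK genes for the K token)
    for cluster in clusters:
        tokens = chemo.tokenize_cluster(cluster, components, kinase_gene_ids)
        result.che_assignments.append(
            chemo.assign_f_class(
                cluster, tokens, components, signatures,
                partial_floor=config.partial_floor, half_band=config.half_band,
            )
        )

    # ---- auxiliary systems (chemosensory proteins excluded)
    for pid, arch in archs.items():
        if pid in components:
            continue
        c = aux.classify_aux(arch, vocab)
        if c is not None:
            result.aux_classifications[pid] = c

    fecr_pids = {pid for pid, a in archs.items() if "FecR" in vocab.role_set(a)}
    tonb_pids = {pid for pid, a in archs.items() if "TonB_receptor" in vocab.role_set(a)}
    tpr_pids = {pid for pid, a in archs.items() if "TPR" in vocab.role_set(a)}
    camp_pde_pids = {pid for pid, a in archs.items() if "cAMP_PDE" in vocab.role_set(a)}

    result.ecf242 = aux.detect_ecf242(
        genome, result.aux_pids("ECF"), fecr_pids, tonb_pids,
        window=config.ecf242_window,
    )
    ac_pids = result.aux_pids("AC")
    result.camp_clusters = aux.detect_camp_cluster(
        genome, ac_pids, camp_pde_pids, fecr_pids, tpr_pids,
        window=config.camp_window,
    )
    if not ac_pids:
        result.crp_without_cyclase = sorted(result.aux_pids("CRP_like"))

    result.qs_reports = aux.qs_screen(archs, qs_vocab or {})

    # ---- combined (merged-system) pathways
    cdgmp_pids = {p.protein_id for p in result.cdgmp_proteins}
    tm_available = any(a.has_tm for a in result.aux_classifications.values())
    role_pids = {
        "pp2c": result.aux_pids("PP2C") | result.aux_pids("bifunctional_PP2C_Pkinase"),
        "stas_styk": result.aux_pids("stas_STYK"),
        "stas": result.aux_pids("STAS")
        | {p for p, c in components.items() if c.component == "STAS"},
        "cdgmp": cdgmp_pids,
        "rec_bifunctional": {
            p for p in result.aux_pids("bifunctional_PP2C_Pkinase")
            if result.aux_classifications[p].has_rec
        },
        "mcp": {p for p, c in components.items() if c.component == "MCP"},
        "ecf": result.aux_pids("ECF"),
        "cyclase_enzyme": ac_pids | cdgmp_pids,
    }
    result.combined = aux.detect_combined_pathways(
        genome, role_pids, window=config.combined_window, tm_available=tm_available
    )

    # ---- atypical-HK-enriched clusters over the full signaling gene set
    signaling_pids = (
        set(tcs_roles) | cdgmp_pids | set(components) | set(result.aux_classifications)
    )
    result.signaling_genes = {
        genome.gene_for_protein(pid).gene_id for pid in signaling_pids
    }
    result.atypical_clusters = tcs.detect_atypical_clusters(
        genome, tcs_roles, result.signaling_genes,
        max_gap=config.atypical_max_gap, min_atypical=config.atypical_min,
    )
    return result
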