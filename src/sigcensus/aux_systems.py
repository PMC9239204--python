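"""Census of the sporadic systems: ECF σ factors, cAMP, STYK/PP2C/STAS,
the quorum-sensing screen, and candidate merged-system pathways.

Classification rules
--------------------
* **ECF** — exactly one σ70 region-2 domain plus one σ70 region-4.2 domain
  and *nothing else* (exact-set semantics: any extra domain disqualifies).
* **AC** — adenylate/guanylate cyclase domain; the CHASE2 sensor is noted.
* **CRP_like** — cAMP-receptor-protein-like regulator (cNMP-binding).
* **eSTYK** — eukaryotic-type Ser/Thr/Tyr kinase (Pkinase domain).
* **bifunctional_PP2C_Pkinase** — kinase/phosphatase fusion.
* **stas_STYK** — HATPase-family kinase with no HisKA (so not a TCS HK)
  and no Hpt (so not CheA); phosphorylates single-STAS-domain proteins.
* **PP2C** — PP2C-family phosphatase (includes SpoIIE-type) without Pkinase.
* **STAS** — a single STAS domain and nothing else.

Neighborhood detectors find the ECF242 cluster (σ factor FecI + anti-σ
FecR + TonB-dependent receptor FecA), the four-gene cAMP cluster
(CHASE2-cyclase + cAMP-PDE + FecR outer-membrane protein + TPR protein),
and the merged-pathway candidates seen in gene neighborhoods that combine
phospho-switch (PP2C / stas_STYK / STAS) with c-di-GMP, chemoreceptor or
ECF/second-messenger components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .model import Genome, ProteinArchitecture
from .vocab import DomainVocabulary

log = logging.getLogger(__name__)


@dataclass
class AuxClassification:
    protein_id: str
    system: str
    evidence: list[str] = field(default_factory=list)
    has_rec: bool = False
    has_tm: bool = False
    has_chase2: bool = False


@dataclass
class Ecf242Candidate:
    ecf_gene_id: str
    fecr_gene_id: str
    tonb_gene_id: Optional[str] = None

    @property
    def members(self) -> list[str]:
        m = [self.ecf_gene_id, self.fecr_gene_id]
        if self.tonb_gene_id:
            m.append(self.tonb_gene_id)
        return m


@dataclass
class CampCluster:
    ac_gene_id: str
    member_gene_ids: list[str]
    support_types: list[str]  # subset of [cAMP_PDE, FecR, TPR]


@dataclass
class CombinedPathwayCandidate:
    rule_name: str
    gene_ids: list[str]
    member_roles: dict[str, str]  # gene_id -> role in the rule
    window: int
    confidence: str = "high"  # low when TM/periplasmic evidence is unavailable


@dataclass
class QsPathwayReport:
    pathway: str
    synthase_present: bool
    receptor_present: bool

    @property
    def present(self) -> bool:
        return self.synthase_present and self.receptor_present

    @property
    def partial(self) -> bool:
        return self.synthase_present != self.receptor_present


# ---------------------------------------------------------------------------
# per-protein rules
# ---------------------------------------------------------------------------

def classify_ecf(arch: ProteinArchitecture, vocab: DomainVocabulary) -> bool:
    """True iff the architecture is exactly {σ70_r2, σ70_r4_2}, one each."""
    roles = vocab.roles_of(arch)
    return (
        len(arch.domains) == 2
        and roles.count("sigma70_r2") == 1
        and roles.count("sigma70_r4_2") == 1
    )


def classify_styk(
    arch: ProteinArchitecture, vocab: DomainVocabulary
) -> Optional[AuxClassification]:
    """STYK/PP2C/STAS family rules (TCS HKs and CheA are excluded by the
    HisKA / Hpt guards, so this is safe to run on every protein)."""
    tokens = vocab.role_set(arch)
    has_rec = "REC" in tokens
    has_tm = "TM" in tokens
    names = [h.name or h.accession for h in arch.domains]

    if "Pkinase" in tokens and "PP2C" in tokens:
        return AuxClassification(arch.protein_id, "bifunctional_PP2C_Pkinase",
                                 names, has_rec, has_tm)
    if "Pkinase" in tokens:
        return AuxClassification(arch.protein_id, "eSTYK", names, has_rec, has_tm)
    if "HATPase" in tokens and "HisKA" not in tokens and "Hpt" not in tokens:
        return AuxClassification(arch.protein_id, "stas_STYK", names, has_rec, has_tm)
    if "PP2C" in tokens:
        return AuxClassification(arch.protein_id, "PP2C", names, has_rec, has_tm)
    if tokens == {"STAS"} and len(arch.domains) == 1:
        return AuxClassification(arch.protein_id, "STAS", names, has_rec, has_tm)
    return None


def classify_aux(
    arch: ProteinArchitecture, vocab: DomainVocabulary
) -> Optional[AuxClassification]:
    """Single auxiliary-system label for one protein (None if none apply)."""
    tokens = vocab.role_set(arch)
    names = [h.name or h.accession for h in arch.domains]
    has_rec = "REC" in tokens
    has_tm = "TM" in tokens
    if classify_ecf(arch, vocab):
        return AuxClassification(arch.protein_id, "ECF", names, has_rec, has_tm)
    if "AC" in tokens:
        return AuxClassification(arch.protein_id, "AC", names, has_rec, has_tm,
                                 has_chase2="CHASE2" in tokens)
    if "CRP" in tokens:
        return AuxClassification(arch.protein_id, "CRP_like", names, has_rec, has_tm)
    return classify_styk(arch, vocab)


# ---------------------------------------------------------------------------
# neighborhood detectors
# ---------------------------------------------------------------------------

def _protein_genes_with(genome: Genome, pids: set[str]) -> list:
    return [g for g in genome.genes() if g.protein_id in pids]


def detect_ecf242(
    genome: Genome,
    ecf_pids: set[str],
    fecr_pids: set[str],
    tonb_pids: set[str],
    window: int = 4,
) -> list[Ecf242Candidate]:
    """ECF242 clusters: an ECF σ-factor gene with a FecR-domain gene in the
    window; a TonB-dependent-receptor gene in the window is recorded as
    supporting evidence.  One candidate per ECF gene."""
    fecr_genes = _protein_genes_with(genome, fecr_pids)
    tonb_genes = _protein_genes_with(genome, tonb_pids)
    out = []
    for ecf_gene in _protein_genes_with(genome, ecf_pids):
        near_fecr = [
            f for f in fecr_genes
            if genome.distance(ecf_gene.gene_id, f.gene_id) <= window
        ]
        if not near_fecr:
            continue
        near_fecr.sort(key=lambda f: genome.distance(ecf_gene.gene_id, f.gene_id))
        near_tonb = [
            t for t in tonb_genes
            if genome.distance(ecf_gene.gene_id, t.gene_id) <= window
        ]
        out.append(
            Ecf242Candidate(
                ecf_gene_id=ecf_gene.gene_id,
                fecr_gene_id=near_fecr[0].gene_id,
                tonb_gene_id=near_tonb[0].gene_id if near_tonb else None,
            )
        )
    return out


def detect_camp_cluster(
    genome: Genome,
    ac_pids: set[str],
    camp_pde_pids: set[str],
    fecr_pids: set[str],
    tpr_pids: set[str],
    window: int = 6,
) -> list[CampCluster]:
    """The recurrent four-gene cAMP cluster around each adenylate cyclase:
    cyclase + at least two of {cAMP-PDE, FecR-domain protein, TPR protein}
    within the window.  A cyclase without the cluster still means the cAMP
    system is present (reported by the caller)."""
    support = {
        "cAMP_PDE": _protein_genes_with(genome, camp_pde_pids),
        "FecR": _protein_genes_with(genome, fecr_pids),
        "TPR": _protein_genes_with(genome, tpr_pids),
    }
    out = []
    for ac_gene in _protein_genes_with(genome, ac_pids):
        members, types = [], []
        for kind, genes in support.items():
            near = [
                g for g in genes
                if genome.distance(ac_gene.gene_id, g.gene_id) <= window
            ]
            if near:
                near.sort(key=lambda g: genome.distance(ac_gene.gene_id, g.gene_id))
                members.append(near[0].gene_id)
                types.append(kind)
        if len(types) >= 2:
            out.append(CampCluster(ac_gene.gene_id, [ac_gene.gene_id] + members, types))
    return out


def qs_screen(
    architectures: dict[str, ProteinArchitecture],
    qs_vocab: dict[str, dict[str, list[str]]],
) -> list[QsPathwayReport]:
    """Domain screen for quorum-sensing pathways.

    A pathway is present only when both a synthase-domain hit and a
    receptor ligand-binding-domain hit occur somewhere in the genome.
    """
    observed: set[str] = set()
    for arch in architectures.values():
        for h in arch.domains:
            if h.name:
                observed.add(h.name.lower())
            if h.accession:
                observed.add(h.accession.lower().split(".")[0])

    reports = []
    for pathway, probes in qs_vocab.items():
        syn = any(p.lower() in observed for p in probes.get("synthase", []))
        rec = any(p.lower() in observed for p in probes.get("receptor", []))
        reports.append(QsPathwayReport(pathway, syn, rec))
    return reports


def detect_combined_pathways(
    genome: Genome,
    role_pids: dict[str, set[str]],
    window: int = 6,
    tm_available: bool = False,
) -> list[CombinedPathwayCandidate]:
    """Candidate pathways merging two or more signaling systems.

    ``role_pids`` maps role names to protein-id sets:

    * ``pp2c``, ``stas_styk``, ``stas``, ``cdgmp`` feed rule
      ``pp2c_styk_stas_cdgmp`` (a sensory PP2C and a stas_STYK toggling a
      c-di-GMP enzyme through a STAS phospho-switch);
    * ``rec_bifunctional``, ``stas``, ``mcp`` feed ``rec_pp2c_styk_mcp``
      (a REC-fused PP2C–STYK acting on a chemoreceptor via STAS);
    * ``ecf``, ``cyclase_enzyme`` feed ``ecf_partial_plus_cyclase`` (ECF
      components next to a membrane cAMP / c-di-GMP enzyme).

    All supporting members must lie within ``window`` genes of the anchor.
    Rules needing transmembrane/periplasmic evidence degrade to
    ``confidence="low"`` when no TM annotations were provided.
    """
    rules = [
        ("pp2c_styk_stas_cdgmp", "stas_styk",
         {"pp2c": "PP2C", "stas": "STAS", "cdgmp": "cdgmp_enzyme"}, True),
        ("rec_pp2c_styk_mcp", "rec_bifunctional",
         {"stas": "STAS", "mcp": "chemoreceptor"}, True),
        ("ecf_partial_plus_cyclase", "ecf",
         {"cyclase_enzyme": "enzyme"}, tm_available),
    ]
    gene_sets = {
        key: _protein_genes_with(genome, pids) for key, pids in role_pids.items()
    }

    out, seen = [], set()
    for rule_name, anchor_key, needed, confident in rules:
        for anchor in gene_sets.get(anchor_key, []):
            members = {anchor.gene_id: _ANCHOR_ROLE[rule_name]}
            ok = True
            for key, role_label in needed.items():
                near = [
                    g for g in gene_sets.get(key, [])
                    if g.gene_id != anchor.gene_id
                    and genome.distance(anchor.gene_id, g.gene_id) <= window
                ]
                if not near:
                    ok = False
                    break
                near.sort(key=lambda g: genome.distance(anchor.gene_id, g.gene_id))
                members[near[0].gene_id] = role_label
            if not ok:
                continue
            sig = (rule_name, frozenset(members))
            if sig in seen:
                continue
            seen.add(sig)
            out.append(
                CombinedPathwayCandidate(
                    rule_name=rule_name,
                    gene_ids=sorted(members),
                    member_roles=members,
                    window=window,
                    confidence="high" if confident else "low",
                )
            )
    return out


_ANCHOR_ROLE = {
    "pp2c_styk_stas_cdgmp": "stas_STYK",
    "rec_pp2c_styk_mcp": "REC_PP2C_Pkinase",
    "ecf_partial_plus_cyclase": "ECF",
}
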