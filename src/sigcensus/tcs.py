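"""Two-component system census.

Role definitions (by resolved domain architecture):

* **HK** — at least one HisKA and one HATPase-family domain, no terminal REC.
* **HHK** — hybrid histidine kinase: HK core plus a REC domain C-terminal of
  the last HATPase domain (phosphorelay / autoregulation).
* **HRR** — hybrid response regulator: REC domain N-terminal of the first
  HisKA domain, fused to the HisKA+HATPase transmitter.
* **RR** — REC domain present but no HisKA+HATPase pair.

The REC position test uses the REC hit's midpoint relative to the first
HisKA start (N-terminal) and the last HATPase end (C-terminal).  A protein
with REC domains on both termini, or only interior REC domains, is labeled
HHK with a warning — the underlying biology is ambiguous and the choice is
a documented convention, not a claim.

Neighborhood rules use the intervening-gene distance from
:class:`~sigcensus.model.Genome`: a **solo** HK/HHK gene is more than four
genes away from every RR gene (distance > window, default window 4), and
HK–RR functional links are drawn within the same four-gene window.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional

from .model import DomainHit, Genome, ProteinArchitecture
from .vocab import DomainVocabulary

log = logging.getLogger(__name__)

HK_LIKE = ("HK", "HHK")
ATYPICAL = ("HHK", "HRR")


@dataclass
class TcsRole:
    protein_id: str
    role: str  # HK | HHK | HRR | RR | none
    rec_position: str  # N_terminal | C_terminal | absent
    evidence: list[DomainHit] = field(default_factory=list)


@dataclass(frozen=True)
class TcsLink:
    hk_gene_id: str
    rr_gene_id: str
    link_type: str  # adjacent_pair | one_to_one_within_window | multi_within_window
    distance: int


@dataclass
class RrOutputCategory:
    protein_id: str
    category: str  # dna_binding | cdgmp_enzyme | other_unknown


@dataclass
class AtypicalCluster:
    replicon_id: str
    ordinal_start: int
    ordinal_end: int
    gene_ids: list[str]
    n_signaling_genes: int
    n_atypical_hks: int


# ---------------------------------------------------------------------------

def classify_tcs_protein(arch: ProteinArchitecture, vocab: DomainVocabulary) -> TcsRole:
    """Assign the TCS role of one protein from its architecture."""
    hiska = vocab.hits_with_role(arch, "HisKA")
    hatpase = vocab.hits_with_role(arch, "HATPase")
    rec = vocab.hits_with_role(arch, "REC")

    if hiska and hatpase:
        if not rec:
            return TcsRole(arch.protein_id, "HK", "absent", hiska + hatpase)
        first_hiska = min(h.env_start for h in hiska)
        last_hatpase = max(h.env_end for h in hatpase)
        n_term = any(r.midpoint < first_hiska for r in rec)
        c_term = any(r.midpoint > last_hatpase for r in rec)
        ev = rec + hiska + hatpase
        if n_term and c_term:
            log.warning("%s: REC on both termini; labeled HHK", arch.protein_id)
            return TcsRole(arch.protein_id, "HHK", "C_terminal", ev)
        if c_term:
            return TcsRole(arch.protein_id, "HHK", "C_terminal", ev)
        if n_term:
            return TcsRole(arch.protein_id, "HRR", "N_terminal", ev)
        log.warning("%s: REC inside the kinase core; labeled HHK", arch.protein_id)
        return TcsRole(arch.protein_id, "HHK", "C_terminal", ev)
    if rec:
        return TcsRole(arch.protein_id, "RR", "absent", rec)
    return TcsRole(arch.protein_id, "none", "absent", [])


# ---------------------------------------------------------------------------

def _genes_with_roles(genome: Genome, roles: dict[str, TcsRole], wanted: tuple[str, ...]):
    """(replicon_id, ordinal, gene_id) for coding genes whose role is wanted."""
    out = []
    for g in genome.genes():
        if g.protein_id is None:
            continue
        r = roles.get(g.protein_id)
        if r is not None and r.role in wanted:
            out.append(g)
    return out


class _NeighborIndex:
    """Per-replicon ordinal index for window queries (distance = intervening
    genes, so distance <= window means |Δordinal| <= window + 1)."""

    def __init__(self, genes):
        self._by_rep: dict[str, tuple[list[int], list]] = {}
        for g in sorted(genes, key=lambda g: (g.replicon_id, g.ordinal)):
            ords, gs = self._by_rep.setdefault(g.replicon_id, ([], []))
            ords.append(g.ordinal)
            gs.append(g)

    def within(self, gene, window: int):
        entry = self._by_rep.get(gene.replicon_id)
        if entry is None:
            return []
        ords, gs = entry
        lo = bisect_left(ords, gene.ordinal - window - 1)
        hi = bisect_right(ords, gene.ordinal + window + 1)
        return [g for g in gs[lo:hi] if g.gene_id != gene.gene_id]


def link_hk_rr(genome: Genome, roles: dict[str, TcsRole], window: int = 4) -> list[TcsLink]:
    """Draw HK–RR functional links within a gene-distance window.

    Adjacent HK/HHK and RR genes give ``adjacent_pair`` links; a
    non-adjacent pair where each side has exactly one candidate in the
    window is ``one_to_one_within_window``; everything else in the window is
    ``multi_within_window``.  Each pair is reported once.
    """
    hk_genes = _genes_with_roles(genome, roles, HK_LIKE)
    rr_genes = _genes_with_roles(genome, roles, ("RR",))
    rr_index = _NeighborIndex(rr_genes)
    hk_index = _NeighborIndex(hk_genes)

    near_rr = {k.gene_id: rr_index.within(k, window) for k in hk_genes}
    near_hk = {r.gene_id: hk_index.within(r, window) for r in rr_genes}

    links = []
    for k in hk_genes:
        for r in near_rr[k.gene_id]:
            d = int(genome.distance(k.gene_id, r.gene_id))
            if d == 0:
                link_type = "adjacent_pair"
            elif len(near_rr[k.gene_id]) == 1 and len(near_hk[r.gene_id]) == 1:
                link_type = "one_to_one_within_window"
            else:
                link_type = "multi_within_window"
            links.append(TcsLink(k.gene_id, r.gene_id, link_type, d))
    return links


def flag_solo(genome: Genome, roles: dict[str, TcsRole], window: int = 4) -> dict[str, bool]:
    """Solo flag per HK/HHK gene: True iff every RR gene is > window away.

    Boundary convention: an RR exactly ``window`` genes away means NOT solo
    ("more than four genes away" reads as distance > 4).
    """
    rr_index = _NeighborIndex(_genes_with_roles(genome, roles, ("RR",)))
    out = {}
    for k in _genes_with_roles(genome, roles, HK_LIKE):
        out[k.gene_id] = not rr_index.within(k, window)
    return out


def classify_rr_output(arch: ProteinArchitecture, vocab: DomainVocabulary) -> RrOutputCategory:
    """Output category of an RR/HRR: what the REC domain controls.

    Precedence cdgmp_enzyme > dna_binding: a REC+GGDEF+HTH chimera is
    counted on the c-di-GMP side (and logged).
    """
    tokens = vocab.role_set(arch)
    has_enzyme = bool(tokens & {"GGDEF", "EAL", "HD_GYP"})
    has_hth = "HTH" in tokens
    if has_enzyme:
        if has_hth:
            log.info("%s: both c-di-GMP enzyme and HTH outputs; counted as cdgmp_enzyme",
                     arch.protein_id)
        return RrOutputCategory(arch.protein_id, "cdgmp_enzyme")
    if has_hth:
        return RrOutputCategory(arch.protein_id, "dna_binding")
    return RrOutputCategory(arch.protein_id, "other_unknown")


# ---------------------------------------------------------------------------

def detect_atypical_clusters(
    genome: Genome,
    roles: dict[str, TcsRole],
    signaling_genes: set[str],
    max_gap: int = 2,
    min_atypical: int = 2,
) -> list[AtypicalCluster]:
    """Find gene clusters enriched in atypical HKs (HHK/HRR).

    Signaling genes are chained along each replicon while at most
    ``max_gap`` non-signaling genes intervene; chains containing at least
    ``min_atypical`` HHK/HRR genes are reported, sorted by size.
    """
    clusters: list[AtypicalCluster] = []
    for rep_id, genes in genome.replicons.items():
        chain: list = []
        last_ord: Optional[int] = None
        for g in genes:
            if g.gene_id not in signaling_genes:
                continue
            if last_ord is not None and g.ordinal - last_ord - 1 > max_gap:
                _close_chain(chain, rep_id, roles, min_atypical, clusters)
                chain = []
            chain.append(g)
            last_ord = g.ordinal
        _close_chain(chain, rep_id, roles, min_atypical, clusters)
    clusters.sort(key=lambda c: (-c.n_signaling_genes, c.replicon_id, c.ordinal_start))
    return clusters


def _close_chain(chain, rep_id, roles, min_atypical, clusters):
    if not chain:
        return
    n_atypical = sum(
        1 for g in chain
        if g.protein_id and roles.get(g.protein_id) is not None
        and roles[g.protein_id].role in ATYPICAL
    )
    if n_atypical >= min_atypical:
        clusters.append(
            AtypicalCluster(
                replicon_id=rep_id,
                ordinal_start=chain[0].ordinal,
                ordinal_end=chain[-1].ordinal,
                gene_ids=[g.gene_id for g in chain],
                n_signaling_genes=len(chain),
                n_atypical_hks=n_atypical,
            )
        )
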