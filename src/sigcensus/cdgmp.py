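"""c-di-GMP enzyme census: DGCs, PDEs, A-site/I-site motif calls.

Diguanylate cyclases (DGCs) carry a GGDEF domain; phosphodiesterases (PDEs)
carry EAL or HD-GYP.  A DGC is enzymatically *active* only when its A-site
carries one of the motifs GGDEF/GGEEF/SGDEF/AGDEF; anything else is a
degenerate DGC (often a c-di-GMP binding effector instead).  The allosteric
inhibitory I-site is the RxxD motif a few residues upstream of the A-site.

A genome without a single active DGC cannot produce c-di-GMP at all, even
when degenerate GGDEF proteins remain — the census therefore reports
``active_dgc`` separately from ``total_dgc``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .model import DomainHit, Genome, ProteinArchitecture
from .tcs import TcsRole
from .vocab import DomainVocabulary

log = logging.getLogger(__name__)

ACTIVE_A_SITE_MOTIFS = ("GGDEF", "GGEEF", "SGDEF", "AGDEF")
ENZYMATIC_ROLES = ("GGDEF", "EAL", "HD_GYP")

# Two-stage anchor for locating a *degenerate* A-site without an alignment:
# first a near-consensus pattern, then a looser fallback.
_ANCHOR_PRIMARY = re.compile(r"[A-Z]G[DE][EQ]F")
_ANCHOR_FALLBACK = re.compile(r"[A-Z][A-Z][DE]EF")


@dataclass
class ASiteCall:
    state: str  # active | degenerate | unknown
    motif: str  # observed 5-mer ("" if no anchor found)
    position: Optional[int] = None  # 1-based aa position of the 5-mer start


@dataclass
class CdgmpProtein:
    protein_id: str
    has_ggdef: bool
    has_eal: bool
    has_hdgyp: bool
    a_site: ASiteCall
    i_site: str  # present | absent | unknown
    partner_domains: list[str] = field(default_factory=list)
    has_rec: bool = False
    near_hk: Optional[bool] = None  # only evaluated for REC-bearing enzymes

    @property
    def is_bifunctional(self) -> bool:
        return self.has_ggdef and (self.has_eal or self.has_hdgyp)

    @property
    def is_single_domain(self) -> bool:
        n_enz = int(self.has_ggdef) + int(self.has_eal) + int(self.has_hdgyp)
        return n_enz == 1 and not self.partner_domains


@dataclass
class CdgmpCategoryCounts:
    """The six per-genome enzyme categories."""

    total_dgc: int = 0
    dgc_with_partner: int = 0
    pde_with_partner: int = 0
    bifunctional: int = 0
    single_domain: int = 0
    active_dgc: int = 0


# ---------------------------------------------------------------------------

def call_a_site(sequence: str, ggdef_hit: DomainHit) -> ASiteCall:
    """Call the A-site state of one GGDEF domain from sequence.

    Scans the domain subsequence for the first exact match to an allowed
    active motif; failing that, anchors a degenerate A-site with the
    two-stage pattern and reports the observed 5-mer.  A sequence shorter
    than the hit interval yields ``unknown``.
    """
    if sequence is None or len(sequence) < ggdef_hit.env_end:
        log.warning("%s: sequence shorter than GGDEF hit interval; A-site unknown",
                    ggdef_hit.protein_id)
        return ASiteCall("unknown", "")
    offset = ggdef_hit.env_start - 1
    sub = sequence[offset:ggdef_hit.env_end]
    for i in range(len(sub) - 4):
        if sub[i:i + 5] in ACTIVE_A_SITE_MOTIFS:
            return ASiteCall("active", sub[i:i + 5], position=offset + i + 1)
    m = _ANCHOR_PRIMARY.search(sub) or _ANCHOR_FALLBACK.search(sub)
    if m:
        return ASiteCall("degenerate", m.group(0), position=offset + m.start() + 1)
    return ASiteCall("degenerate", "")


def call_i_site(sequence: str, a_site: ASiteCall, window: int = 15) -> str:
    """Look for the RxxD inhibitory-site motif upstream of the A-site.

    The R may start 1..``window`` residues before the A-site start
    (canonically ~5); returns present/absent, or unknown when no A-site
    anchor exists.
    """
    if a_site.state == "unknown" or a_site.position is None:
        return "unknown"
    a0 = a_site.position  # 1-based
    for k in range(1, window + 1):
        r = a0 - k
        if r < 1:
            break
        if sequence[r - 1] == "R" and r + 3 <= len(sequence) and sequence[r + 2] == "D":
            return "present"
    return "absent"


# ---------------------------------------------------------------------------

def identify_cdgmp(
    arch: ProteinArchitecture, vocab: DomainVocabulary, isite_window: int = 15
) -> Optional[CdgmpProtein]:
    """Return a :class:`CdgmpProtein` iff any enzymatic domain is present.

    All non-enzymatic domains (REC, sensory domains, TM annotations ...)
    are recorded as partner domains.  When the protein sequence is
    available, each GGDEF domain gets its own A-site call and the protein
    is active if *any* of them is; without sequence the calls are unknown.
    """
    roles = vocab.roles_of(arch)
    has_ggdef = "GGDEF" in roles
    has_eal = "EAL" in roles
    has_hdgyp = "HD_GYP" in roles
    if not (has_ggdef or has_eal or has_hdgyp):
        return None

    partners = [
        h.name or h.accession
        for h, r in zip(arch.domains, roles)
        if r not in ENZYMATIC_ROLES
    ]
    has_rec = "REC" in roles

    a_site = ASiteCall("unknown", "")
    i_site = "unknown"
    if has_ggdef:
        calls = []
        for hit, role in zip(arch.domains, roles):
            if role != "GGDEF":
                continue
            c = call_a_site(arch.sequence, hit) if arch.sequence else ASiteCall("unknown", "")
            calls.append(c)
        active = [c for c in calls if c.state == "active"]
        anchored = [c for c in calls if c.position is not None]
        if active:
            a_site = active[0]
        elif anchored:
            a_site = anchored[0]
        elif calls:
            a_site = calls[0]
        if arch.sequence and a_site.state != "unknown":
            i_site = call_i_site(arch.sequence, a_site, window=isite_window)

    return CdgmpProtein(
        protein_id=arch.protein_id,
        has_ggdef=has_ggdef,
        has_eal=has_eal,
        has_hdgyp=has_hdgyp,
        a_site=a_site,
        i_site=i_site,
        partner_domains=partners,
        has_rec=has_rec,
    )


def categorize(
    proteins: list[CdgmpProtein], include_degenerate_in_total: bool = True
) -> CdgmpCategoryCounts:
    """Count the six per-genome categories.

    Bifunctional (GGDEF together with EAL/HD-GYP) proteins are counted in
    ``bifunctional`` only, not in the with-partner columns, keeping the
    categories close to a partition.  ``include_degenerate_in_total``
    controls whether degenerate-GGDEF proteins count in ``total_dgc``
    (default yes).
    """
    c = CdgmpCategoryCounts()
    for p in proteins:
        active = p.has_ggdef and p.a_site.state == "active"
        if p.has_ggdef and (include_degenerate_in_total or active):
            c.total_dgc += 1
        if active:
            c.active_dgc += 1
        if p.is_bifunctional:
            c.bifunctional += 1
        elif p.has_ggdef and p.partner_domains:
            c.dgc_with_partner += 1
        elif (p.has_eal or p.has_hdgyp) and p.partner_domains:
            c.pde_with_partner += 1
        if p.is_single_domain:
            c.single_domain += 1
    return c


def flag_near_hk(
    genome: Genome,
    proteins: list[CdgmpProtein],
    roles: dict[str, TcsRole],
    window: int = 4,
) -> None:
    """Set ``near_hk`` on REC-bearing enzymes: an HK/HHK/HRR gene within
    the window.  Enzymes without REC are left unevaluated (None)."""
    hk_genes = [
        g for g in genome.genes()
        if g.protein_id and roles.get(g.protein_id) is not None
        and roles[g.protein_id].role in ("HK", "HHK", "HRR")
    ]
    for p in proteins:
        if not p.has_rec:
            p.near_hk = None
            continue
        g = genome.gene_for_protein(p.protein_id)
        if g is None:
            p.near_hk = None
            continue
        p.near_hk = any(genome.distance(g.gene_id, k.gene_id) <= window for k in hk_genes)
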