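"""Chemosensory system census: components, gene clusters, F-class calls.

Chemosensory pathways come in conserved *classes* defined by the gene order
and composition of their gene clusters (F1–F17, Tfp, ACF).  This module
identifies the protein components by diagnostic domains, chains them into
genomic clusters, and assigns each cluster to a class by aligning its gene
token string against configurable class signatures (YAML data, not code).

Component identification (diagnostic-domain defaults, precedence in this
order when a fusion matches several):

=========  =======================================================
CheA       HATPase + Hpt (with or without REC)
CheB       CheB methylesterase (with or without REC)
CheV       CheW-type domain + REC (the known CheW–REC fusion)
CheW       CheW-type domain alone
CheR       CheR methyltransferase
CheC/CheX  CheC-family / CheX
CheD/CheZ  CheD / CheZ
MCP        MCP signaling domain (chemoreceptor)
STAS       a single STAS domain and nothing else
CheY       a single REC domain and nothing else — accepted only for
           genes inside a chemosensory cluster, so orphan response
           regulators are not swallowed
=========  =======================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional

import yaml

from .model import GeneRecord, Genome, ProteinArchitecture
from .vocab import DomainVocabulary

log = logging.getLogger(__name__)

# core components: their presence makes a gene chain a chemosensory cluster
CORE_COMPONENTS = {"CheA", "CheW", "CheV", "CheB", "CheR", "CheC", "CheX", "CheD", "CheZ"}

COMPONENT_TOKEN = {
    "CheA": "A", "CheB": "B", "CheC": "C", "CheD": "D", "CheR": "R",
    "CheV": "V", "CheW": "W", "CheX": "X", "CheY": "Y", "CheZ": "Z",
    "MCP": "M", "STAS": "S",
}
TOKEN_COMPONENT = {v: k for k, v in COMPONENT_TOKEN.items()}
TOKEN_COMPONENT["K"] = "HK"  # a histidine-kinase gene inside the cluster


@dataclass
class CheComponent:
    protein_id: str
    component: str
    has_rec: bool = False


@dataclass
class FClassSignature:
    """A configurable chemosensory class definition."""

    class_name: str
    gene_order: list[str]
    required_components: set[str]
    auxiliary_rules: list[str] = field(default_factory=list)
    max_insertions: int = 2
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.gene_order:
            raise ValueError(f"{self.class_name}: empty gene_order")
        order_components = {
            TOKEN_COMPONENT[t] for t in self.gene_order if t != "."
        }
        extra = set(self.required_components) - order_components
        if extra:
            raise ValueError(
                f"{self.class_name}: required components {sorted(extra)} "
                "not named by any gene_order token"
            )


@dataclass
class ChemoClusterAssignment:
    gene_ids: list[str]
    class_name: Optional[str]
    completeness: float
    status: str  # full | half | partial | none
    matched_alignment: list[tuple[str, str]] = field(default_factory=list)  # (token, gene_id)
    notes: list[str] = field(default_factory=list)


def load_signatures(path=None) -> list[FClassSignature]:
    """Load class signatures (package defaults when no path given)."""
    if path is None:
        text = resources.files("sigcensus.data").joinpath("signatures.yaml").read_text()
        data = yaml.safe_load(text)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    sigs = []
    for d in data["signatures"]:
        sigs.append(
            FClassSignature(
                class_name=d["class_name"],
                gene_order=[str(t) for t in d["gene_order"]],
                required_components=set(d["required_components"]),
                auxiliary_rules=list(d.get("auxiliary_rules", [])),
                max_insertions=int(d.get("max_insertions", 2)),
                priority=int(d.get("priority", 0)),
            )
        )
    return sigs


# ---------------------------------------------------------------------------
# component identification
# ---------------------------------------------------------------------------

def identify_che_components(
    arch: ProteinArchitecture, vocab: DomainVocabulary
) -> Optional[CheComponent]:
    """Map one protein architecture onto a chemosensory component.

    Returns None for non-chemosensory proteins.  Single-REC proteins are
    returned as CheY *candidates*; :func:`find_che_clusters` keeps them
    only when they sit inside a chemosensory cluster.
    """
    tokens = vocab.role_set(arch)
    has_rec = "REC" in tokens
    n_domains = len(arch.domains)

    matches = []
    if "HATPase" in tokens and "Hpt" in tokens:
        matches.append("CheA")
    if "CheB_methylest" in tokens:
        matches.append("CheB")
    if "CheW" in tokens:
        matches.append("CheV" if has_rec else "CheW")
    if "CheR" in tokens:
        matches.append("CheR")
    for tok in ("CheC", "CheX", "CheD", "CheZ"):
        if tok in tokens:
            matches.append(tok)
    if "MCPsignal" in tokens:
        matches.append("MCP")
    if tokens == {"STAS"} and n_domains == 1:
        matches.append("STAS")
    if tokens == {"REC"} and n_domains == 1:
        matches.append("CheY")

    if not matches:
        return None
    if len(matches) > 1:
        log.warning("%s matches several che components %s; using %s by precedence",
                    arch.protein_id, matches, matches[0])
    return CheComponent(arch.protein_id, matches[0], has_rec=has_rec)


# ---------------------------------------------------------------------------
# cluster detection
# ---------------------------------------------------------------------------

def find_che_clusters(
    genome: Genome,
    components: dict[str, CheComponent],
    max_gap: int = 2,
    kinase_gene_ids: Optional[set[str]] = None,
) -> tuple[list[list[GeneRecord]], dict[str, CheComponent]]:
    """Chain chemosensory genes into clusters and finalize CheY calls.

    Genes carrying a component are chained while at most ``max_gap``
    non-chemosensory genes intervene; clusters are the full contiguous
    gene range from first to last chained gene, so interleaved
    hypothetical genes stay visible to the signature alignment.
    Histidine-kinase genes (``kinase_gene_ids``) also extend chains — some
    class signatures place an HK gene (token K) inside the cluster — but
    cannot form clusters by themselves: a chain is a cluster only if it
    contains at least one core component.  Singleton MCP genes are orphan
    receptors, not clusters.  CheY candidates (single-REC proteins) and
    lone STAS genes outside any surviving cluster are dropped from the
    component map (they belong to the TCS / STYK censuses instead).

    Returns (clusters, filtered component map).
    """
    kinase_gene_ids = kinase_gene_ids or set()
    chains: list[list[GeneRecord]] = []  # full gene ranges, first..last member
    for genes in genome.replicons.values():
        first_ord = last_ord = None
        for g in genes:
            is_member = (g.protein_id is not None and g.protein_id in components) \
                or g.gene_id in kinase_gene_ids
            if not is_member:
                continue
            if last_ord is not None and g.ordinal - last_ord - 1 > max_gap:
                chains.append(genes[first_ord:last_ord + 1])
                first_ord = None
            if first_ord is None:
                first_ord = g.ordinal
            last_ord = g.ordinal
        if first_ord is not None:
            chains.append(genes[first_ord:last_ord + 1])

    clusters: list[list[GeneRecord]] = []
    in_cluster: set[str] = set()
    for chain in chains:
        comps = {
            components[g.protein_id].component
            for g in chain
            if g.protein_id in components
        }
        if comps & CORE_COMPONENTS:
            clusters.append(chain)
            in_cluster.update(g.protein_id for g in chain if g.protein_id)

    filtered = {}
    for pid, comp in components.items():
        if comp.component in ("CheY", "STAS") and pid not in in_cluster:
            continue  # context-restricted components
        filtered[pid] = comp
    return clusters, filtered


def count_chemoreceptors(components: dict[str, CheComponent]) -> int:
    """Genome-wide chemoreceptor (MCP) count, inside and outside clusters."""
    return sum(1 for c in components.values() if c.component == "MCP")


# ---------------------------------------------------------------------------
# signature alignment
# ---------------------------------------------------------------------------

def tokenize_cluster(
    cluster: list[GeneRecord],
    components: dict[str, CheComponent],
    hk_genes: set[str],
) -> list[str]:
    """One token per gene: component letter, K for an HK gene, else '.'."""
    tokens = []
    for g in cluster:
        comp = components.get(g.protein_id) if g.protein_id else None
        if comp is not None:
            tokens.append(COMPONENT_TOKEN[comp.component])
        elif g.gene_id in hk_genes:
            tokens.append("K")
        else:
            tokens.append(".")
    return tokens


def align_signature(
    sig_tokens: tuple[str, ...], cluster_tokens: tuple[str, ...], max_insertions: int
) -> tuple[int, list[tuple[int, int]]]:
    """Best order-preserving match of a signature against a cluster.

    A legal alignment maps a subset of signature positions, in order, onto
    increasing cluster positions with equal tokens; unmatched cluster genes
    *between* the first and last matched position are insertions and may
    number at most ``max_insertions``.  Unmatched signature tokens are
    missing components (free, but they cost completeness).

    Returns (number of matched tokens, the matched (sig_idx, cluster_idx)
    pairs of one best alignment).
    """
    n, m = len(cluster_tokens), len(sig_tokens)
    best = (0, [])

    @lru_cache(maxsize=None)
    def extend(ci: int, si: int, ins: int) -> tuple[int, tuple]:
        """Best continuation after a started alignment (span open)."""
        choices = [(0, ())]  # stop here
        if si < m and ci < n:
            if sig_tokens[si] == cluster_tokens[ci]:
                sc, pairs = extend(ci + 1, si + 1, ins)
                choices.append((1 + sc, ((si, ci),) + pairs))
            # skip a signature token (missing component)
            sc, pairs = extend(ci, si + 1, ins)
            choices.append((sc, pairs))
            # skip a cluster gene (insertion) — only counts if we match later
            if ins < max_insertions:
                sc, pairs = extend(ci + 1, si, ins + 1)
                if sc > 0:  # an insertion at the end of the span is not inside it
                    choices.append((sc, pairs))
        elif si < m:
            sc, pairs = extend(ci, si + 1, ins)
            choices.append((sc, pairs))
        return max(choices, key=lambda c: c[0])

    for ci in range(n):
        for si in range(m):
            if sig_tokens[si] == cluster_tokens[ci]:
                sc, pairs = extend(ci + 1, si + 1, 0)
                cand = (1 + sc, [(si, ci)] + list(pairs))
                if cand[0] > best[0]:
                    best = cand
    extend.cache_clear()
    return best


def _aux_rule_satisfied(
    rule: str,
    matched_components: dict[str, str],  # component -> protein_id (from this cluster)
    all_components: dict[str, CheComponent],  # genome-wide, filtered
) -> bool:
    """Evaluate one auxiliary rule.

    CheA rules refer to the cluster's own matched CheA; CheB rules search
    genome-wide (the auxiliary CheB may live outside the cluster).
    """
    comps = list(all_components.values())
    if rule == "CheA_has_REC":
        pid = matched_components.get("CheA")
        return pid is not None and all_components[pid].has_rec
    if rule == "CheA_lacks_REC":
        pid = matched_components.get("CheA")
        return pid is not None and not all_components[pid].has_rec
    if rule == "CheB_lacks_REC":
        return any(c.component == "CheB" and not c.has_rec for c in comps)
    if rule == "CheB_has_REC":
        return any(c.component == "CheB" and c.has_rec for c in comps)
    log.warning("unknown auxiliary rule %r treated as unsatisfied", rule)
    return False


def score_signature(
    sig: FClassSignature,
    cluster_tokens: list[str],
    cluster: list[GeneRecord],
    components: dict[str, CheComponent],
) -> tuple[float, float, list[tuple[str, str]]]:
    """Score one signature against one tokenized cluster.

    Both orientations of the cluster are tried.  Returns
    ``(score, completeness, matched_alignment)`` where

    * ``completeness`` = (required components matched in the cluster +
      auxiliary rules satisfied) / (n required + n auxiliary);
    * ``score`` = mean(alignment fraction, completeness) — gene order and
      composition weigh equally, so classes sharing a component set are
      still separated by their gene order.
    """
    sig_t = tuple(sig.gene_order)
    fwd = tuple(cluster_tokens)
    rev = tuple(reversed(cluster_tokens))

    n_f, pairs_f = align_signature(sig_t, fwd, sig.max_insertions)
    n_r, pairs_r = align_signature(sig_t, rev, sig.max_insertions)
    if n_r > n_f:
        n_match = n_r
        pairs = [(si, len(cluster_tokens) - 1 - ci) for si, ci in pairs_r]
    else:
        n_match = n_f
        pairs = pairs_f

    align_frac = n_match / len(sig_t)
    matched_alignment = [(sig.gene_order[si], cluster[ci].gene_id) for si, ci in pairs]

    matched_components: dict[str, str] = {}
    for si, ci in pairs:
        tok = sig.gene_order[si]
        if tok != "." and cluster[ci].protein_id:
            matched_components.setdefault(TOKEN_COMPONENT[tok], cluster[ci].protein_id)

    n_req = len(sig.required_components)
    n_aux = len(sig.auxiliary_rules)
    req_present = sum(1 for c in sig.required_components if c in matched_components)
    aux_ok = sum(
        1 for rule in sig.auxiliary_rules
        if _aux_rule_satisfied(rule, matched_components, components)
    )
    denom = n_req + n_aux
    completeness = (req_present + aux_ok) / denom if denom else 0.0
    score = (align_frac + completeness) / 2.0
    return score, completeness, matched_alignment


def assign_f_class(
    cluster: list[GeneRecord],
    cluster_tokens: list[str],
    components: dict[str, CheComponent],
    signatures: list[FClassSignature],
    partial_floor: float = 0.4,
    half_band: tuple[float, float] = (0.4, 0.8),
) -> ChemoClusterAssignment:
    """Assign the best-matching chemosensory class to one cluster.

    The highest-scoring signature wins; ties break by configured priority
    (F3 first).  A best score below ``partial_floor`` leaves the cluster
    unassigned.  Status: ``full`` at completeness 1, ``half`` inside the
    configured band, ``partial`` otherwise.  Clusters carrying component
    tokens foreign to the winning signature are annotated
    ``mixed_component`` (e.g. F3 cheZY genes inside another class).
    """
    gene_ids = [g.gene_id for g in cluster]
    if not cluster or not signatures:
        return ChemoClusterAssignment(gene_ids, None, 0.0, "none")

    scored = []
    for sig in sorted(signatures, key=lambda s: s.priority):
        score, completeness, alignment = score_signature(sig, cluster_tokens, cluster, components)
        scored.append((score, sig, completeness, alignment))
    best_score, best_sig, completeness, alignment = max(scored, key=lambda t: t[0])

    if best_score < partial_floor:
        return ChemoClusterAssignment(gene_ids, None, completeness, "none")

    if completeness >= 1.0 - 1e-9:
        status = "full"
    elif half_band[0] <= completeness < half_band[1]:
        status = "half"
    else:
        status = "partial"

    notes = []
    sig_alphabet = set(best_sig.gene_order)
    foreign = {t for t in cluster_tokens if t not in sig_alphabet and t != "."}
    if foreign:
        notes.append("mixed_component:" + ",".join(sorted(foreign)))

    return ChemoClusterAssignment(
        gene_ids, best_sig.class_name, completeness, status,
        matched_alignment=alignment, notes=notes,
    )
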