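"""Synthetic genome generator with ground truth.

Builds genomes (ordered gene tables), domain tables and protein sequences
that exercise every classification rule in the package, together with a
:class:`GroundTruth` recording what each implanted protein, cluster and
census column must come out as.  Everything is deterministic given the
seed.

Design notes
------------
* Domain hits are emitted directly into the domain table — closing the
  loop does not require an HMM search, which keeps tests hermetic.
* Implants are placed in blocks separated by ``margin`` background genes
  (default 9), which exceeds every neighborhood window in the pipeline, so
  directives cannot interact unless a directive deliberately co-locates
  genes (e.g. ``solo_hk`` places its RR at an exact distance).
* Protein sequences are generated only for GGDEF-containing proteins (the
  only consumers of sequence are the A-site/I-site calls).  DGC sequences
  use an amino-acid alphabet without G/D/E/F/R outside the implanted
  motifs, so the implanted A-site (and, when requested, the RxxD I-site)
  is provably the only anchor the caller can find.
* Background genes are hypothetical (no domains) or carry one inert decoy
  domain; decoys never map to any vocabulary role.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .chemo import COMPONENT_TOKEN, FClassSignature, load_signatures
from .io import write_domain_table, write_gene_table
from .model import DomainHit, GeneRecord, Genome

# canonical emitted domain name per vocabulary role
DOMAIN_NAME = {
    "HisKA": "HisKA", "HATPase": "HATPase_c", "HATPase_alt": "HATPase_c_2",
    "REC": "Response_reg", "Hpt": "Hpt",
    "GGDEF": "GGDEF", "EAL": "EAL", "HD_GYP": "HD-GYP",
    "HTH": "Trans_reg_C", "sigma70_r2": "Sigma70_r2", "sigma70_r4_2": "Sigma70_r4_2",
    "AC": "Adenylate_cycl", "CHASE2": "CHASE2", "cAMP_PDE": "PDEase_I",
    "FecR": "FecR", "TonB_receptor": "TonB_dep_Rec", "TPR": "TPR_1",
    "Pkinase": "Pkinase", "PP2C": "PP2Cc", "STAS": "STAS", "CRP": "cNMP_binding",
    "CheW": "CheW", "MCPsignal": "MCPsignal", "CheB_methylest": "CheB_methylest",
    "CheR": "CheR", "CheC": "CheC", "CheX": "CheX", "CheD": "CheD", "CheZ": "CheZ",
}

DOMAIN_LEN = {
    "HisKA": 65, "HATPase_c": 110, "HATPase_c_2": 110, "Response_reg": 115,
    "Hpt": 90, "GGDEF": 160, "EAL": 240, "HD-GYP": 170, "Trans_reg_C": 75,
    "Sigma70_r2": 70, "Sigma70_r4_2": 55, "Adenylate_cycl": 190, "CHASE2": 150,
    "PDEase_I": 220, "FecR": 100, "TonB_dep_Rec": 250, "TPR_1": 34,
    "Pkinase": 250, "PP2Cc": 230, "STAS": 110, "cNMP_binding": 95,
    "CheW": 140, "MCPsignal": 190, "CheB_methylest": 180, "CheR": 175,
    "CheC": 100, "CheX": 95, "CheD": 130, "CheZ": 95, "PAS": 105,
}
_DEFAULT_LEN = 120

DECOY_DOMAINS = ["PAS", "GAF", "ABC_tran", "MFS_1", "Radical_SAM",
                 "Acetyltransf_1", "Glycos_transf_1", "DUF4118"]

ACTIVE_MOTIFS = ("GGDEF", "GGEEF", "SGDEF", "AGDEF")
DEFAULT_DEGENERATE = "GGDQF"

# DGC protein alphabet: no G/D/E/F (A-site letters) and no R (I-site letter)
_SAFE_AA = "ACHIKLMNPQSTVWY"
_FULL_AA = "ACDEFGHIKLMNPQRSTVWY"

QS_DOMAINS = {
    "AHL": ("Autoind_synth", "Autoind_bind"),
    "AI-2": ("LuxS", "LuxP"),
    "CAI-1": ("CqsA", "CqsS_6TM"),
    "DSF": ("RpfF", "RpfC_sensor"),
    "PQS": ("PqsA", "PqsR_LBD"),
    "AIP": ("AgrB", "AgrC_sensor"),
}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic genome.

    ``implants`` is a list of directives, each a dict with a ``kind`` key;
    see the ``_implant_*`` builders for the recognized kinds and their
    parameters.
    """

    seed: int = 0
    genome_id: str = "syn"
    ecotype: str = "unknown"
    n_replicons: int = 1
    genes_per_replicon: int = 300
    implants: list = field(default_factory=list)
    decoy_domain_rate: float = 0.3
    noncoding_rate: float = 0.05
    margin: int = 9  # background genes separating implant blocks


@dataclass
class GroundTruth:
    """Expected classifications, cluster calls and census counts."""

    proteins: dict = field(default_factory=dict)  # pid -> {label_key: value}
    clusters: list = field(default_factory=list)  # [{"class_name", "status"}]
    counts: dict = field(default_factory=dict)    # expected census columns
    qs: dict = field(default_factory=dict)        # pathway -> bool (present)


@dataclass
class SyntheticGenome:
    spec: SyntheticSpec
    genome: Genome
    hits: list[DomainHit]
    sequences: dict[str, str]
    truth: GroundTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_table(self.genome, outdir / "genes.gff3")
        write_domain_table(self.hits, outdir / "domains.tsv")
        with open(outdir / "proteins.faa", "w") as fh:
            for pid in sorted(self.sequences):
                fh.write(f">{pid}\n{self.sequences[pid]}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {"proteins": self.truth.proteins, "clusters": self.truth.clusters,
                 "counts": self.truth.counts, "qs": self.truth.qs},
                fh, indent=1, default=str,
            )
            fh.write("\n")
        with open(outdir / "metadata.tsv", "w") as fh:
            fh.write("genome_id\tecotype\n")
            fh.write(f"{self.genome.genome_id}\t{self.spec.ecotype}\n")


# ---------------------------------------------------------------------------
# gene-level building blocks
# ---------------------------------------------------------------------------

@dataclass
class _GeneSpec:
    domains: list[str] = field(default_factory=list)  # domain names, in order
    truth: dict = field(default_factory=dict)
    seq_plan: Optional[dict] = None  # {"a_site": 5-mer, "i_site": present|absent}
    coding: bool = True


_COUNT_KEYS = [
    "n_HK", "n_HHK", "n_HRR", "n_solo", "n_RR",
    "rr_dna_binding", "rr_cdgmp_enzyme", "rr_other_unknown",
    "total_dgc", "dgc_with_partner", "pde_with_partner", "bifunctional",
    "single_domain", "active_dgc", "n_cdgmp_enzymes", "n_chemoreceptors",
    "n_ecf", "n_ecf242_clusters", "n_ac", "n_camp_clusters", "n_crp_like",
    "n_estyk", "n_stas_styk", "n_pp2c", "n_bifunc_pp2c_pkinase", "n_stas",
    "n_qs_present", "n_combined_pathways", "n_atypical_clusters",
]


class _Builder:
    """Translates implant directives into gene blocks plus ground truth."""

    def __init__(self, spec: SyntheticSpec, signatures: list[FClassSignature]):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.signatures = {s.class_name: s for s in signatures}
        self.truth = GroundTruth(counts={k: 0 for k in _COUNT_KEYS})
        self.truth.counts["classes"] = {}
        self.truth.qs = {}

    # ------------------------------------------------------------- genes
    def _bg(self) -> _GeneSpec:
        return _GeneSpec(domains=[], truth={})

    def _hk(self, solo: bool, partners: Optional[list[str]] = None) -> _GeneSpec:
        c = self.truth.counts
        c["n_HK"] += 1
        if solo:
            c["n_solo"] += 1
        return _GeneSpec(
            domains=(partners or []) + ["HisKA", "HATPase_c"],
            truth={"tcs": "HK", "solo": solo},
        )

    def _rr(self, output: str = "other_unknown") -> _GeneSpec:
        c = self.truth.counts
        c["n_RR"] += 1
        if output == "dna_binding":
            c["rr_dna_binding"] += 1
            domains = ["Response_reg", "Trans_reg_C"]
        else:
            c["rr_other_unknown"] += 1
            domains = ["Response_reg"]
        return _GeneSpec(domains=domains, truth={"tcs": "RR", "rr_output": output})

    def _hhk(self, solo: bool) -> _GeneSpec:
        c = self.truth.counts
        c["n_HHK"] += 1
        if solo:
            c["n_solo"] += 1
        return _GeneSpec(
            domains=["PAS", "HisKA", "HATPase_c", "Response_reg"],
            truth={"tcs": "HHK", "solo": solo},
        )

    def _hrr(self) -> _GeneSpec:
        # HRR outputs are classified but not pooled into the RR proportions
        self.truth.counts["n_HRR"] += 1
        return _GeneSpec(
            domains=["Response_reg", "HisKA", "HATPase_c"],
            truth={"tcs": "HRR", "rr_output": "other_unknown"},
        )

    def _dgc_gene(
        self,
        a_site: str = "GGDEF",
        i_site: str = "absent",
        partner: Optional[list[str]] = None,
        rec: bool = False,
        near_hk: Optional[bool] = None,
    ) -> _GeneSpec:
        """One GGDEF protein with a controlled A-site / I-site state."""
        c = self.truth.counts
        partner = list(partner or [])
        domains = (["Response_reg"] if rec else []) + partner + ["GGDEF"]
        active = a_site in ACTIVE_MOTIFS
        motif = a_site if active else (
            a_site if len(a_site) == 5 else DEFAULT_DEGENERATE
        )
        truth = {
            "cdgmp": "dgc",
            "a_site": "active" if active else "degenerate",
            "i_site": i_site,
        }
        c["total_dgc"] += 1
        c["n_cdgmp_enzymes"] += 1
        if active:
            c["active_dgc"] += 1
        if partner or rec:
            c["dgc_with_partner"] += 1
        else:
            c["single_domain"] += 1
        if rec:
            c["n_RR"] += 1
            c["rr_cdgmp_enzyme"] += 1
            truth["tcs"] = "RR"
            truth["rr_output"] = "cdgmp_enzyme"
            truth["near_hk"] = bool(near_hk)
        return _GeneSpec(domains=domains, truth=truth,
                         seq_plan={"a_site": motif, "i_site": i_site})

    def _pde_gene(self, domain: str = "EAL", partner: Optional[list[str]] = None) -> _GeneSpec:
        c = self.truth.counts
        partner = list(partner or [])
        c["n_cdgmp_enzymes"] += 1
        if partner:
            c["pde_with_partner"] += 1
        else:
            c["single_domain"] += 1
        return _GeneSpec(
            domains=partner + [DOMAIN_NAME[domain]],
            truth={"cdgmp": "pde", "a_site": "unknown", "i_site": "unknown"},
        )

    def _aux_gene(self, system: str, domains: list[str], **extra_truth) -> _GeneSpec:
        counter = {
            "ECF": "n_ecf", "AC": "n_ac", "CRP_like": "n_crp_like",
            "eSTYK": "n_estyk", "stas_STYK": "n_stas_styk", "PP2C": "n_pp2c",
            "bifunctional_PP2C_Pkinase": "n_bifunc_pp2c_pkinase", "STAS": "n_stas",
        }
        self.truth.counts[counter[system]] += 1
        return _GeneSpec(domains=domains, truth={"aux": system, **extra_truth})

    # ---------------------------------------------------------- directives
    def build(self, implant: dict) -> list[_GeneSpec]:
        kind = implant["kind"]
        fn = getattr(self, f"_implant_{kind}", None)
        if fn is None:
            raise ValueError(f"unknown implant kind {kind!r}")
        return fn(implant)

    def _implant_tcs_pair(self, imp) -> list[_GeneSpec]:
        return [self._hk(solo=False), self._rr(imp.get("rr_output", "dna_binding"))]

    def _implant_hk_lone(self, imp) -> list[_GeneSpec]:
        # an HK with no RR anywhere in its block (solo under default margins)
        return [self._hk(solo=True)]

    def _implant_hhk_lone(self, imp) -> list[_GeneSpec]:
        return [self._hhk(solo=True)]

    def _implant_hhk(self, imp) -> list[_GeneSpec]:
        return [self._hhk(solo=False), self._rr("other_unknown")]

    def _implant_hrr(self, imp) -> list[_GeneSpec]:
        return [self._hrr()]

    def _implant_solo_hk(self, imp) -> list[_GeneSpec]:
        d = int(imp.get("distance", 5))
        hk = self._hk(solo=d > 4)
        spacers = [self._bg() for _ in range(d)]
        return [hk] + spacers + [self._rr("other_unknown")]

    def _implant_rr(self, imp) -> list[_GeneSpec]:
        output = imp.get("output", "other_unknown")
        if output == "cdgmp_enzyme":
            return [self._dgc_gene(a_site=imp.get("a_site", "GGDEF"),
                                   i_site=imp.get("i_site", "absent"),
                                   rec=True, near_hk=False)]
        return [self._rr(output)]

    def _implant_dgc(self, imp) -> list[_GeneSpec]:
        rec = bool(imp.get("rec", False))
        near = bool(imp.get("near_hk", False))
        dgc = self._dgc_gene(
            a_site=imp.get("a_site", "GGDEF"),
            i_site=imp.get("i_site", "absent"),
            partner=imp.get("partner", ["PAS"]),
            rec=rec,
            near_hk=near if rec else None,
        )
        if rec and near:
            return [self._hk(solo=False), self._rr("other_unknown"), dgc]
        return [dgc]

    def _implant_pde(self, imp) -> list[_GeneSpec]:
        return [self._pde_gene(imp.get("domain", "EAL"), imp.get("partner", ["GAF"]))]

    def _implant_bifunctional(self, imp) -> list[_GeneSpec]:
        c = self.truth.counts
        a_site = imp.get("a_site", "GGDEF")
        active = a_site in ACTIVE_MOTIFS
        c["total_dgc"] += 1
        c["bifunctional"] += 1
        c["n_cdgmp_enzymes"] += 1
        if active:
            c["active_dgc"] += 1
        return [_GeneSpec(
            domains=["PAS", "GGDEF", "EAL"],
            truth={"cdgmp": "bifunctional",
                   "a_site": "active" if active else "degenerate",
                   "i_site": imp.get("i_site", "absent")},
            seq_plan={"a_site": a_site if len(a_site) == 5 else DEFAULT_DEGENERATE,
                      "i_site": imp.get("i_site", "absent")},
        )]

    def _implant_single_dgc(self, imp) -> list[_GeneSpec]:
        return [self._dgc_gene(a_site=imp.get("a_site", "GGDEF"),
                               i_site=imp.get("i_site", "absent"), partner=[])]

    # -- chemosensory ------------------------------------------------------
    _TOKEN_DOMAINS = {
        "A": ["Hpt", "HATPase_c"],
        "B": ["CheB_methylest", "Response_reg"],
        "C": ["CheC"], "D": ["CheD"], "K": ["HisKA", "HATPase_c"],
        "M": ["MCPsignal"], "R": ["CheR"], "S": ["STAS"],
        "V": ["CheW", "Response_reg"], "W": ["CheW"], "X": ["CheX"],
        "Y": ["Response_reg"], "Z": ["CheZ"],
    }
    _TOKEN_COMPONENT = {v: k for k, v in COMPONENT_TOKEN.items()}

    def _implant_che_cluster(self, imp) -> list[_GeneSpec]:
        """A chemosensory cluster following a named signature.

        ``status`` full implants the whole gene order (plus auxiliary
        requirements); ``status`` half keeps the longest prefix whose
        completeness falls inside the half band — only supported for
        signatures without auxiliary rules, whose completeness does not
        depend on the rest of the genome.
        """
        name = imp.get("class_name", "F3")
        status = imp.get("status", "full")
        sig = self.signatures.get(name)
        if sig is None:
            raise ValueError(f"unknown chemosensory class {name!r}")
        order = list(sig.gene_order)
        if status == "half":
            if sig.auxiliary_rules:
                raise ValueError(
                    f"half clusters of {name} are ambiguous (auxiliary rules "
                    "are genome-wide); implant a class without auxiliary rules"
                )
            # longest prefix whose completeness stays below the half-band top
            n_req = len(sig.required_components)
            keep = max(2, int(np.ceil(0.8 * n_req)) - 1)
            order = order[:keep]
        elif status != "full":
            raise ValueError(f"unsupported cluster status {status!r}")

        aux_has_rec_chea = "CheA_has_REC" in sig.auxiliary_rules
        genes: list[_GeneSpec] = []
        for tok in order:
            if tok == ".":
                genes.append(self._bg())
                continue
            if tok == "K":
                # an HK gene inside the cluster; no RR nearby, hence solo
                genes.append(self._hk(solo=True))
                continue
            domains = list(self._TOKEN_DOMAINS[tok])
            comp = self._TOKEN_COMPONENT[tok]
            if tok == "A" and aux_has_rec_chea:
                domains = ["Response_reg"] + domains
            if tok == "M":
                self.truth.counts["n_chemoreceptors"] += 1
            genes.append(_GeneSpec(domains=domains, truth={"chemo": comp}))

        if "CheB_lacks_REC" in sig.auxiliary_rules:
            # auxiliary CheB without REC, outside the cluster (> max_gap away)
            genes += [self._bg() for _ in range(4)]
            genes.append(_GeneSpec(domains=["CheB_methylest"], truth={"chemo": "CheB"}))

        self.truth.clusters.append({"class_name": name, "status": status})
        classes = self.truth.counts["classes"]
        rank = {"full": 3, "half": 2, "partial": 1, "none": 0}
        if rank[status] > rank.get(classes.get(name, "none"), 0):
            classes[name] = status
        return genes

    def _implant_orphan_mcp(self, imp) -> list[_GeneSpec]:
        n = int(imp.get("count", 1))
        genes: list[_GeneSpec] = []
        for i in range(n):
            if i:
                genes += [self._bg() for _ in range(3)]
            self.truth.counts["n_chemoreceptors"] += 1
            genes.append(_GeneSpec(domains=["MCPsignal"], truth={"chemo": "MCP"}))
        return genes

    # -- auxiliary systems -------------------------------------------------
    def _implant_ecf(self, imp) -> list[_GeneSpec]:
        return [self._aux_gene("ECF", ["Sigma70_r2", "Sigma70_r4_2"])]

    def _implant_ecf242(self, imp) -> list[_GeneSpec]:
        copies = int(imp.get("copies", 1))
        with_tonb = bool(imp.get("with_tonb", True))
        genes: list[_GeneSpec] = []
        for _ in range(copies):
            genes.append(self._aux_gene("ECF", ["Sigma70_r2", "Sigma70_r4_2"]))
            genes.append(_GeneSpec(domains=["FecR"], truth={}))
            if with_tonb:
                genes.append(_GeneSpec(domains=["TonB_dep_Rec"], truth={}))
            self.truth.counts["n_ecf242_clusters"] += 1
        return genes

    def _implant_camp_cluster(self, imp) -> list[_GeneSpec]:
        ac = self._aux_gene("AC", ["CHASE2", "Adenylate_cycl"])
        if not imp.get("full", True):
            return [ac]
        self.truth.counts["n_camp_clusters"] += 1
        return [
            ac,
            _GeneSpec(domains=["PDEase_I"], truth={}),
            _GeneSpec(domains=["FecR"], truth={}),
            _GeneSpec(domains=["TPR_1"], truth={}),
        ]

    def _implant_crp(self, imp) -> list[_GeneSpec]:
        return [self._aux_gene("CRP_like", ["cNMP_binding"])]

    def _implant_estyk(self, imp) -> list[_GeneSpec]:
        genes = [self._aux_gene("eSTYK", ["Pkinase"])]
        if imp.get("with_pp2c", True):
            genes.append(self._aux_gene("PP2C", ["PP2Cc"]))
        return genes

    def _implant_bifunc_styk(self, imp) -> list[_GeneSpec]:
        rec = bool(imp.get("rec", False))
        domains = (["Response_reg"] if rec else []) + ["PP2Cc", "Pkinase"]
        g = self._aux_gene("bifunctional_PP2C_Pkinase", domains)
        if rec:
            self.truth.counts["n_RR"] += 1
            self.truth.counts["rr_other_unknown"] += 1
            g.truth.update({"tcs": "RR", "rr_output": "other_unknown"})
        return [g]

    def _implant_stas_styk_system(self, imp) -> list[_GeneSpec]:
        return [
            self._aux_gene("stas_STYK", ["HATPase_c_2"]),
            self._aux_gene("PP2C", ["PP2Cc"]),
            self._aux_gene("STAS", ["STAS"]),
        ]

    def _implant_combined(self, imp) -> list[_GeneSpec]:
        rule = imp.get("rule", "pp2c_styk_stas_cdgmp")
        self.truth.counts["n_combined_pathways"] += 1
        if rule == "pp2c_styk_stas_cdgmp":
            return [
                self._aux_gene("PP2C", ["PP2Cc"]),
                self._aux_gene("stas_STYK", ["HATPase_c_2"]),
                self._aux_gene("STAS", ["STAS"]),
                self._dgc_gene(a_site="GGDEF", partner=["PAS"]),
            ]
        if rule == "rec_pp2c_styk_mcp":
            bif = self._aux_gene("bifunctional_PP2C_Pkinase",
                                 ["Response_reg", "PP2Cc", "Pkinase"])
            self.truth.counts["n_RR"] += 1
            self.truth.counts["rr_other_unknown"] += 1
            bif.truth.update({"tcs": "RR", "rr_output": "other_unknown"})
            self.truth.counts["n_chemoreceptors"] += 1
            return [
                bif,
                self._aux_gene("STAS", ["STAS"]),
                _GeneSpec(domains=["MCPsignal"], truth={"chemo": "MCP"}),
            ]
        if rule == "ecf_partial_plus_cyclase":
            return [
                self._aux_gene("ECF", ["Sigma70_r2", "Sigma70_r4_2"]),
                self._aux_gene("AC", ["CHASE2", "Adenylate_cycl"]),
            ]
        raise ValueError(f"unknown combined-pathway rule {rule!r}")

    def _implant_qs(self, imp) -> list[_GeneSpec]:
        pathway = imp.get("pathway", "AHL")
        parts = imp.get("parts", "both")
        syn_dom, rec_dom = QS_DOMAINS[pathway]
        genes = [_GeneSpec(domains=[syn_dom], truth={})]
        if parts == "both":
            genes.append(_GeneSpec(domains=[rec_dom], truth={}))
            self.truth.qs[pathway] = True
            self.truth.counts["n_qs_present"] += 1
        else:
            self.truth.qs[pathway] = False
        return genes

    def _implant_atypical_cluster(self, imp) -> list[_GeneSpec]:
        n_signaling = int(imp.get("n_signaling", 8))
        n_atypical = int(imp.get("n_atypical", 2))
        if n_signaling < 2 * n_atypical:
            raise ValueError("n_signaling too small for the requested atypical count")
        genes: list[_GeneSpec] = []
        for i in range(n_atypical):
            genes.append(self._hhk(solo=False) if i % 2 == 0 else self._hrr())
            genes.append(self._rr("other_unknown"))
        while len(genes) + 2 <= n_signaling:
            genes.append(self._hk(solo=False))
            genes.append(self._rr("other_unknown"))
        while len(genes) < n_signaling:
            genes.append(self._rr("other_unknown"))
        if n_atypical >= 2:
            self.truth.counts["n_atypical_clusters"] += 1
        return genes


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(
    spec: SyntheticSpec, signatures: Optional[list[FClassSignature]] = None
) -> SyntheticGenome:
    """Realize a synthetic genome from its spec (deterministic per seed).

    Raises before emitting anything if the directives cannot fit on the
    requested replicons.
    """
    signatures = signatures if signatures is not None else load_signatures()
    builder = _Builder(spec, signatures)
    blocks = [builder.build(imp) for imp in spec.implants]

    margin = spec.margin
    capacity = spec.n_replicons * spec.genes_per_replicon
    needed = sum(len(b) + margin for b in blocks) + margin
    if needed > capacity:
        raise ValueError(
            f"spec unrealizable: implants need {needed} gene slots, "
            f"genome has {capacity}"
        )

    # allocate blocks to replicon slots, margin background genes between
    rng = builder.rng
    slots: dict[str, list[Optional[_GeneSpec]]] = {}
    rep_ids = [f"{spec.genome_id}_rep{i + 1}" for i in range(spec.n_replicons)]
    for rid in rep_ids:
        slots[rid] = [None] * spec.genes_per_replicon
    rep_i, pos = 0, margin
    for block in blocks:
        while pos + len(block) + margin > spec.genes_per_replicon:
            rep_i += 1
            pos = margin
            if rep_i >= spec.n_replicons:
                raise ValueError("spec unrealizable: ran out of replicon space")
        for j, g in enumerate(block):
            slots[rep_ids[rep_i]][pos + j] = g
        pos += len(block) + margin

    # fill background and materialize genes / hits / sequences
    replicons: dict[str, list[GeneRecord]] = {}
    hits: list[DomainHit] = []
    sequences: dict[str, str] = {}
    for rid in rep_ids:
        genes: list[GeneRecord] = []
        coord = 1
        for i, gspec in enumerate(slots[rid]):
            if gspec is None:
                gspec = _background_gene(spec, rng)
            coord += int(rng.integers(20, 200))
            gene_id = f"{rid}_g{i:05d}"
            if gspec.coding:
                pid = gene_id + "p"
                prot_len, gene_hits, seq = _materialize_protein(pid, gspec, rng)
                hits.extend(gene_hits)
                if seq is not None:
                    sequences[pid] = seq
                nt = 3 * (prot_len + 1)
            else:
                pid = None
                nt = int(rng.integers(200, 600))
            start = coord
            end = coord + nt - 1
            coord = end + 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(gene_id, rid, i, start, end, strand, pid))
            if pid is not None and gspec.truth:
                builder.truth.proteins[pid] = dict(gspec.truth)
        replicons[rid] = genes

    # genome-level derived truths
    counts = builder.truth.counts
    counts["crp_without_cyclase"] = counts["n_crp_like"] > 0 and counts["n_ac"] == 0
    genome = Genome(
        spec.genome_id, replicons,
        {"ecotype": spec.ecotype, "species": f"Synthetica {spec.genome_id}"},
    )
    return SyntheticGenome(spec, genome, hits, sequences, builder.truth)


def _background_gene(spec: SyntheticSpec, rng) -> _GeneSpec:
    if rng.random() < spec.noncoding_rate:
        return _GeneSpec(coding=False)
    if rng.random() < spec.decoy_domain_rate:
        dom = DECOY_DOMAINS[int(rng.integers(len(DECOY_DOMAINS)))]
        return _GeneSpec(domains=[dom], truth={})
    return _GeneSpec(domains=[], truth={})


def _materialize_protein(pid: str, gspec: _GeneSpec, rng):
    """Emit domain hits (and sequence when needed) for one protein."""
    pos = 15
    hits = []
    ggdef_span = None
    for name in gspec.domains:
        length = DOMAIN_LEN.get(name, _DEFAULT_LEN)
        start, end = pos, pos + length - 1
        if name == "GGDEF" and ggdef_span is None:
            ggdef_span = (start, end)
        hits.append(
            DomainHit(
                protein_id=pid, accession="", name=name,
                env_start=start, env_end=end,
                e_value=float(10.0 ** -rng.uniform(8, 40)),
                bit_score=float(rng.uniform(60, 300)),
            )
        )
        pos = end + 1 + int(rng.integers(10, 20))
    prot_len = max(pos + 15, 120)

    seq = None
    if gspec.seq_plan is not None:
        if ggdef_span is None:
            raise ValueError(f"{pid}: sequence plan without a GGDEF domain")
        seq = _dgc_sequence(prot_len, ggdef_span, gspec.seq_plan, rng)
    return prot_len, hits, seq


def _dgc_sequence(prot_len: int, ggdef_span: tuple[int, int], plan: dict, rng) -> str:
    """Sequence over the safe alphabet with the planned A-site (and I-site)
    implanted at a recorded offset inside the GGDEF domain."""
    aa = list("".join(rng.choice(list(_SAFE_AA), size=prot_len)))
    g_start, g_end = ggdef_span
    a_pos = g_start + 70  # 1-based start of the 5-mer, inside the domain
    assert a_pos + 4 <= g_end
    motif = plan["a_site"]
    aa[a_pos - 1:a_pos + 4] = list(motif)
    if plan.get("i_site") == "present":
        r = a_pos - 5  # R..D ends 2 before the A-site start
        aa[r - 1] = "R"
        aa[r + 2] = "D"
    return "".join(aa)


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------

def perturb(
    hits: list[DomainHit],
    drop_domain_rate: float = 0.0,
    extra_decoy_rate: float = 0.0,
    seed: int = 0,
) -> list[DomainHit]:
    """Stochastically corrupt a domain table (for robustness measurement).

    Each hit is dropped independently with ``drop_domain_rate``; each
    protein gains one inert decoy hit with ``extra_decoy_rate``.  Rates of
    zero are an identity.
    """
    if not 0 <= drop_domain_rate <= 1 or not 0 <= extra_decoy_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    kept = [h for h in hits if rng.random() >= drop_domain_rate]
    if extra_decoy_rate > 0:
        by_protein: dict[str, int] = {}
        for h in hits:
            by_protein[h.protein_id] = max(by_protein.get(h.protein_id, 0), h.env_end)
        for pid in sorted(by_protein):
            if rng.random() < extra_decoy_rate:
                start = by_protein[pid] + 10
                dom = DECOY_DOMAINS[int(rng.integers(len(DECOY_DOMAINS)))]
                kept.append(
                    DomainHit(pid, "", dom, start, start + 49,
                              e_value=1e-10, bit_score=80.0)
                )
    return kept


# ---------------------------------------------------------------------------
# self-audit
# ---------------------------------------------------------------------------

def audit(result: SyntheticGenome) -> list[str]:
    """Check the emitted genome against its own implant promises.

    Verifies motif implants directly on the sequences and solo distances
    directly on the gene table; returns a list of violations (empty when
    the generator kept its contract).
    """
    problems = []
    genome, truth = result.genome, result.truth
    ggdef_by_pid: dict[str, DomainHit] = {}
    for h in result.hits:
        if h.name == "GGDEF" and h.protein_id not in ggdef_by_pid:
            ggdef_by_pid[h.protein_id] = h
    for pid, labels in truth.proteins.items():
        if labels.get("a_site") in ("active", "degenerate"):
            seq = result.sequences.get(pid)
            hit = ggdef_by_pid.get(pid)
            if seq is None or hit is None:
                problems.append(f"{pid}: promised A-site but no sequence/GGDEF hit")
                continue
            sub = seq[hit.env_start - 1:hit.env_end]
            has_active = any(m in sub for m in ACTIVE_MOTIFS)
            if (labels["a_site"] == "active") != has_active:
                problems.append(f"{pid}: A-site state does not match sequence")
        if "solo" in labels:
            gene = genome.gene_for_protein(pid)
            rr_genes = [
                genome.gene_for_protein(p)
                for p, lab in truth.proteins.items()
                if lab.get("tcs") == "RR"
            ]
            near = any(genome.distance(gene.gene_id, r.gene_id) <= 4 for r in rr_genes)
            if labels["solo"] != (not near):
                problems.append(f"{pid}: solo flag inconsistent with gene distances")
    return problems
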