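"""Evaluation helpers: ground-truth recovery scoring, study cohorts,
archetype fixtures and the noise-degradation experiment.

These functions connect the synthetic-data generator to the pipeline so
that recovery, symmetry, invariant and robustness measurements can be run
identically from the test suite and from the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import GenomeClassification, classify_genome
from .io import resolve_all
from .synth import SyntheticGenome, SyntheticSpec, generate, perturb
from .vocab import DomainVocabulary, load_qs_vocabulary


# ---------------------------------------------------------------------------
# label extraction and scoring
# ---------------------------------------------------------------------------

def predicted_labels(res: GenomeClassification) -> dict[str, dict]:
    """Flatten a pipeline result into per-protein label dicts, the same
    shape the generator's ground truth uses."""
    labels: dict[str, dict] = {}

    def put(pid, key, value):
        labels.setdefault(pid, {})[key] = value

    for pid, role in res.tcs_roles.items():
        put(pid, "tcs", role.role)
    for pid, cat in res.rr_outputs.items():
        put(pid, "rr_output", cat.category)
    for gene_id, is_solo in res.solo.items():
        pid = res.genome.gene(gene_id).protein_id
        put(pid, "solo", bool(is_solo))
    for p in res.cdgmp_proteins:
        kind = "bifunctional" if p.is_bifunctional else ("dgc" if p.has_ggdef else "pde")
        put(p.protein_id, "cdgmp", kind)
        put(p.protein_id, "a_site", p.a_site.state)
        put(p.protein_id, "i_site", p.i_site)
        if p.has_rec:
            put(p.protein_id, "near_hk", bool(p.near_hk))
    for pid, comp in res.che_components.items():
        put(pid, "chemo", comp.component)
    for pid, aux in res.aux_classifications.items():
        put(pid, "aux", aux.system)
    return labels


@dataclass
class LabelScore:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0


def score_labels(
    truth: dict[str, dict], predicted: dict[str, dict]
) -> dict[tuple[str, object], LabelScore]:
    """Per-(label key, label value) precision/recall.

    A missing key on either side counts as "no label of that kind", so a
    spurious classification is a false positive even for proteins the
    truth never mentions.
    """
    scores: dict[tuple[str, object], LabelScore] = {}
    pids = set(truth) | set(predicted)
    for pid in pids:
        t = truth.get(pid, {})
        p = predicted.get(pid, {})
        for key in set(t) | set(p):
            tv, pv = t.get(key), p.get(key)
            if tv == pv:
                if tv is not None:
                    scores.setdefault((key, tv), LabelScore()).tp += 1
                continue
            if tv is not None:
                scores.setdefault((key, tv), LabelScore()).fn += 1
            if pv is not None:
                scores.setdefault((key, pv), LabelScore()).fp += 1
    return scores


def overall_min_f(scores: dict) -> float:
    """The worst precision/recall over every label value (1.0 = perfect)."""
    worst = 1.0
    for s in scores.values():
        worst = min(worst, s.precision, s.recall)
    return worst


# ---------------------------------------------------------------------------
# running the pipeline on synthetic output
# ---------------------------------------------------------------------------

def classify_synthetic(
    syn: SyntheticGenome,
    vocab: DomainVocabulary | None = None,
    qs_vocab: dict | None = None,
    hits=None,
    config=None,
) -> GenomeClassification:
    vocab = vocab or DomainVocabulary.default()
    qs_vocab = qs_vocab if qs_vocab is not None else load_qs_vocabulary()
    archs = resolve_all(hits if hits is not None else syn.hits, syn.sequences)
    return classify_genome(syn.genome, archs, vocab=vocab, qs_vocab=qs_vocab,
                           config=config)


# ---------------------------------------------------------------------------
# study cohorts
# ---------------------------------------------------------------------------

def random_spec(genome_id: str, seed: int, n_genes: int = 1500,
                ecotype: str = "unknown") -> SyntheticSpec:
    """One randomized genome recipe exercising every classification rule."""
    rng = np.random.default_rng(seed)
    implants: list[dict] = []

    for _ in range(int(rng.integers(3, 9))):
        implants.append({"kind": "tcs_pair",
                         "rr_output": rng.choice(["dna_binding", "other_unknown"])})
    for _ in range(int(rng.integers(0, 3))):
        implants.append({"kind": "hhk"})
    for _ in range(int(rng.integers(0, 3))):
        implants.append({"kind": "hrr"})
    for d in rng.choice([2, 3, 4, 5, 6, 8], size=2, replace=True):
        implants.append({"kind": "solo_hk", "distance": int(d)})
    for _ in range(int(rng.integers(1, 4))):
        implants.append({"kind": "rr",
                         "output": rng.choice(["dna_binding", "other_unknown",
                                               "cdgmp_enzyme"])})
    for _ in range(int(rng.integers(2, 7))):
        implants.append({
            "kind": "dgc",
            "a_site": rng.choice(["GGDEF", "GGEEF", "SGDEF", "AGDEF", "degenerate"]),
            "i_site": rng.choice(["present", "absent"]),
            "partner": [["PAS"], ["GAF"], []][int(rng.integers(3))],
            "rec": bool(rng.random() < 0.3),
            "near_hk": bool(rng.random() < 0.5),
        })
    for _ in range(int(rng.integers(1, 4))):
        implants.append({"kind": "pde", "domain": rng.choice(["EAL", "HD_GYP"]),
                         "partner": [["PAS"], []][int(rng.integers(2))]})
    for _ in range(int(rng.integers(0, 3))):
        implants.append({"kind": "bifunctional",
                         "a_site": rng.choice(["GGDEF", "degenerate"])})
    for _ in range(int(rng.integers(0, 3))):
        implants.append({"kind": "single_dgc",
                         "a_site": rng.choice(["GGDEF", "degenerate"])})

    implants.append({"kind": "che_cluster", "class_name": "F3", "status": "full"})
    if rng.random() < 0.7:
        cname = rng.choice(["F7", "F8", "F9", "F14"])
        status = "half" if (cname != "F14" and rng.random() < 0.4) else "full"
        implants.append({"kind": "che_cluster", "class_name": str(cname),
                         "status": status})
    implants.append({"kind": "orphan_mcp", "count": int(rng.integers(0, 6))})

    if rng.random() < 0.5:
        implants.append({"kind": "ecf"})
    if rng.random() < 0.5:
        implants.append({"kind": "ecf242", "copies": int(rng.integers(1, 3)),
                         "with_tonb": bool(rng.random() < 0.7)})
    if rng.random() < 0.6:
        implants.append({"kind": "camp_cluster", "full": bool(rng.random() < 0.7)})
    if rng.random() < 0.5:
        implants.append({"kind": "crp"})
    if rng.random() < 0.5:
        implants.append({"kind": "estyk", "with_pp2c": bool(rng.random() < 0.7)})
    if rng.random() < 0.4:
        implants.append({"kind": "bifunc_styk", "rec": bool(rng.random() < 0.5)})
    if rng.random() < 0.5:
        implants.append({"kind": "stas_styk_system"})
    for rule in ("pp2c_styk_stas_cdgmp", "rec_pp2c_styk_mcp", "ecf_partial_plus_cyclase"):
        if rng.random() < 0.35:
            implants.append({"kind": "combined", "rule": rule})
    if rng.random() < 0.3:
        implants.append({"kind": "qs", "pathway": "AHL", "parts": "both"})
    elif rng.random() < 0.3:
        implants.append({"kind": "qs", "pathway": "AHL", "parts": "synthase_only"})
    if rng.random() < 0.5:
        implants.append({"kind": "atypical_cluster",
                         "n_signaling": int(rng.integers(6, 13)),
                         "n_atypical": int(rng.integers(2, 4))})

    return SyntheticSpec(
        seed=int(rng.integers(2 ** 31)),
        genome_id=genome_id,
        ecotype=ecotype,
        genes_per_replicon=n_genes,
        implants=implants,
    )


def cohort_specs(n_genomes: int, seed: int, n_genes: int = 1500) -> list[SyntheticSpec]:
    rng = np.random.default_rng(seed)
    ecotypes = ["vent_specialist", "generalist", "host_associated"]
    return [
        random_spec(f"cohort{i:03d}", int(rng.integers(2 ** 31)), n_genes=n_genes,
                    ecotype=ecotypes[i % 3])
        for i in range(n_genomes)
    ]


# ---------------------------------------------------------------------------
# ecotype archetypes
# ---------------------------------------------------------------------------

def archetype_spec(name: str, seed: int = 7) -> SyntheticSpec:
    """Three integration fixtures echoing the ecotype narratives:

    * vent specialist — F3 plus a c-di-GMP enzyme repertoire larger than
      its HK count;
    * free-living generalist — several chemosensory classes, atypical-HK
      clusters, and every sporadic system represented;
    * host-associated — a streamlined genome: one F3 class, few TCS pairs,
      degenerate DGCs only (no c-di-GMP production).
    """
    if name == "vent_specialist":
        implants = [
            {"kind": "che_cluster", "class_name": "F3", "status": "full"},
            *[{"kind": "tcs_pair"} for _ in range(6)],
            {"kind": "hhk"},
            *[{"kind": "dgc", "a_site": m, "i_site": s, "partner": ["PAS"]}
              for m, s in [("GGDEF", "present"), ("GGEEF", "absent"),
                           ("SGDEF", "present"), ("AGDEF", "absent"),
                           ("GGDEF", "present"), ("GGDEF", "absent"),
                           ("GGEEF", "present"), ("SGDEF", "absent")]],
            *[{"kind": "dgc", "a_site": "GGDEF", "rec": True, "near_hk": True}
              for _ in range(2)],
            *[{"kind": "dgc", "a_site": "degenerate"} for _ in range(3)],
            {"kind": "pde", "domain": "EAL"}, {"kind": "pde", "domain": "EAL"},
            {"kind": "pde", "domain": "HD_GYP"}, {"kind": "pde", "domain": "HD_GYP"},
            {"kind": "bifunctional"}, {"kind": "bifunctional"},
            {"kind": "single_dgc"}, {"kind": "single_dgc"},
            {"kind": "orphan_mcp", "count": 6},
        ]
        return SyntheticSpec(seed=seed, genome_id="vent", ecotype="vent_specialist",
                             genes_per_replicon=1200, implants=implants)
    if name == "generalist":
        implants = [
            {"kind": "che_cluster", "class_name": "F3", "status": "full"},
            {"kind": "che_cluster", "class_name": "F7", "status": "full"},
            {"kind": "che_cluster", "class_name": "F9", "status": "half"},
            *[{"kind": "tcs_pair"} for _ in range(12)],
            {"kind": "hhk"}, {"kind": "hhk"}, {"kind": "hrr"}, {"kind": "hrr"},
            {"kind": "solo_hk", "distance": 6},
            {"kind": "atypical_cluster", "n_signaling": 10, "n_atypical": 2},
            {"kind": "atypical_cluster", "n_signaling": 8, "n_atypical": 3},
            *[{"kind": "dgc", "a_site": "GGDEF", "partner": ["PAS"]} for _ in range(6)],
            *[{"kind": "dgc", "a_site": "degenerate"} for _ in range(2)],
            {"kind": "dgc", "a_site": "GGEEF", "rec": True, "near_hk": True},
            {"kind": "pde", "domain": "EAL"}, {"kind": "pde", "domain": "HD_GYP"},
            {"kind": "bifunctional"},
            {"kind": "ecf242", "copies": 2, "with_tonb": True},
            {"kind": "camp_cluster", "full": True},
            {"kind": "crp"},
            {"kind": "estyk", "with_pp2c": True},
            {"kind": "bifunc_styk", "rec": True},
            {"kind": "stas_styk_system"},
            {"kind": "combined", "rule": "pp2c_styk_stas_cdgmp"},
            {"kind": "qs", "pathway": "AHL", "parts": "synthase_only"},
            {"kind": "orphan_mcp", "count": 8},
        ]
        return SyntheticSpec(seed=seed, genome_id="generalist", ecotype="generalist",
                             genes_per_replicon=1800, implants=implants)
    if name == "host_associated":
        implants = [
            {"kind": "che_cluster", "class_name": "F3", "status": "full"},
            *[{"kind": "tcs_pair"} for _ in range(4)],
            *[{"kind": "dgc", "a_site": "degenerate", "i_site": "absent"}
              for _ in range(2)],
            {"kind": "crp"},
            {"kind": "orphan_mcp", "count": 3},
        ]
        return SyntheticSpec(seed=seed, genome_id="host", ecotype="host_associated",
                             genes_per_replicon=900, implants=implants)
    raise ValueError(f"unknown archetype {name!r}")


ARCHETYPES = ("vent_specialist", "generalist", "host_associated")


def archetype_pattern_ok(name: str, census_row: dict) -> bool:
    """The qualitative ecotype pattern each archetype must reproduce."""
    if name == "vent_specialist":
        return census_row["n_cdgmp_enzymes"] > census_row["n_total_HK"]
    if name == "generalist":
        n_classes = sum(
            1 for k, v in census_row.items()
            if k.startswith("class_") and v != "none"
        )
        return census_row["n_HHK"] + census_row["n_HRR"] > 0 and n_classes >= 2
    if name == "host_associated":
        full_f3 = census_row.get("class_F3") == "full"
        others = [v for k, v in census_row.items()
                  if k.startswith("class_") and k != "class_F3"]
        return (census_row["active_dgc"] == 0 and full_f3
                and all(v == "none" for v in others))
    raise ValueError(name)


# ---------------------------------------------------------------------------
# noise degradation
# ---------------------------------------------------------------------------

# role -> (implant kind, truth (key, value), number of domain hits that must
# all survive for the label to be recovered)
NOISE_ROLES = {
    "HK": ("hk_lone", ("tcs", "HK"), 2),
    "HHK": ("hhk_lone", ("tcs", "HHK"), 3),
    "HRR": ("hrr", ("tcs", "HRR"), 3),
    "RR": ("rr", ("tcs", "RR"), 1),
    "ECF": ("ecf", ("aux", "ECF"), 2),
    "eSTYK": ("estyk_lone", ("aux", "eSTYK"), 1),
    "MCP": ("mcp_lone", ("chemo", "MCP"), 1),
    "DGC": ("single_dgc", ("cdgmp", "dgc"), 1),
}

_NOISE_IMPLANTS = {
    "hk_lone": {"kind": "hk_lone"},
    "hhk_lone": {"kind": "hhk_lone"},
    "hrr": {"kind": "hrr"},
    "rr": {"kind": "rr", "output": "other_unknown"},
    "ecf": {"kind": "ecf"},
    "estyk_lone": {"kind": "estyk", "with_pp2c": False},
    "mcp_lone": {"kind": "orphan_mcp", "count": 1},
    "single_dgc": {"kind": "single_dgc", "a_site": "GGDEF"},
}


def noise_experiment(
    n_per_role: int, drop_rate: float, seed: int
) -> dict[str, dict[str, float]]:
    """Measure classification recall per role under random domain dropout
    and compare with the analytic binomial survival probability.

    A label needing k domain hits survives dropout with probability
    (1 - p)^k; measured recall on the perturbed genome is compared with
    that closed form.  Returns per-role measured/analytic recall and n.
    """
    implants = []
    for role, (ikey, _, _) in NOISE_ROLES.items():
        implants += [dict(_NOISE_IMPLANTS[ikey]) for _ in range(n_per_role)]
    spec = SyntheticSpec(
        seed=seed, genome_id="noise", margin=1, decoy_domain_rate=0.0,
        genes_per_replicon=2 * len(implants) + 20, implants=implants,
    )
    syn = generate(spec)
    noisy = perturb(syn.hits, drop_domain_rate=drop_rate, seed=seed + 1)
    res = classify_synthetic(syn, hits=noisy)
    predicted = predicted_labels(res)

    out = {}
    for role, (_, (key, value), k_required) in NOISE_ROLES.items():
        truth_pids = [pid for pid, lab in syn.truth.proteins.items()
                      if lab.get(key) == value]
        recovered = sum(
            1 for pid in truth_pids if predicted.get(pid, {}).get(key) == value
        )
        out[role] = {
            "measured_recall": recovered / len(truth_pids),
            "analytic_recall": (1.0 - drop_rate) ** k_required,
            "n": len(truth_pids),
        }
    return out
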