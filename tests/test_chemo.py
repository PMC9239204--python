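"""Chemosensory components, cluster detection and F-class assignment."""

import numpy as np
import pytest

from sigcensus.chemo import (
    align_signature,
    assign_f_class,
    count_chemoreceptors,
    find_che_clusters,
    identify_che_components,
    load_signatures,
    score_signature,
    tokenize_cluster,
)
from sigcensus.evaluation import classify_synthetic
from sigcensus.synth import SyntheticSpec, generate

from conftest import linear_genome, make_arch
from _alignment_oracle import oracle_best_match


@pytest.mark.parametrize(
    "names, component",
    [
        (["CheW", "Response_reg"], "CheV"),
        (["CheW"], "CheW"),
        (["MCPsignal"], "MCP"),
        (["Hpt", "HATPase_c"], "CheA"),
        (["Response_reg", "Hpt", "HATPase_c"], "CheA"),
        (["CheB_methylest", "Response_reg"], "CheB"),
        (["CheB_methylest"], "CheB"),
        (["CheR"], "CheR"),
        (["CheD"], "CheD"),
        (["CheZ"], "CheZ"),
        (["STAS"], "STAS"),
        (["Response_reg"], "CheY"),  # candidate; cluster context decides
    ],
)
def test_component_identification(vocab, names, component):
    c = identify_che_components(make_arch("p", names), vocab)
    assert c is not None and c.component == component


def test_non_che_protein_is_none(vocab):
    assert identify_che_components(make_arch("p", ["HisKA", "HATPase_c"]), vocab) is None


def _components_at(genome, vocab, layout):
    comps = {}
    for i, names in layout.items():
        pid = genome.replicons["rep1"][i].protein_id
        c = identify_che_components(make_arch(pid, names), vocab)
        if c is not None:
            comps[pid] = c
    return comps


def test_cluster_chaining_and_gap(vocab):
    g = linear_genome(30)
    layout = {5: ["CheW", "Response_reg"], 6: ["Response_reg", "Hpt", "HATPase_c"],
              7: ["CheW"],  # cheVAW operon
              15: ["CheR"], 21: ["CheB_methylest"]}  # 5 genes apart: 2 clusters
    comps = _components_at(g, vocab, layout)
    clusters, comps2 = find_che_clusters(g, comps, max_gap=2)
    spans = [(c[0].ordinal, c[-1].ordinal) for c in clusters]
    assert spans == [(5, 7), (15, 15), (21, 21)]


def test_singleton_mcp_not_a_cluster_but_counted(vocab):
    g = linear_genome(10)
    comps = _components_at(g, vocab, {4: ["MCPsignal"]})
    clusters, comps2 = find_che_clusters(g, comps)
    assert clusters == []
    assert count_chemoreceptors(comps2) == 1


def test_orphan_single_rec_is_not_chey(vocab):
    """A lone REC protein far from any cluster is dropped from the
    chemosensory component map (it stays an ordinary RR)."""
    g = linear_genome(20)
    comps = _components_at(g, vocab, {2: ["Response_reg"], 10: ["CheW"],
                                      11: ["Hpt", "HATPase_c"]})
    _, comps2 = find_che_clusters(g, comps)
    assert "p002" not in comps2
    assert "p010" in comps2


def test_no_che_genes_no_clusters(vocab):
    g = linear_genome(5)
    clusters, _ = find_che_clusters(g, {})
    assert clusters == []


# ---------------------------------------------------------------------------

def _assign(genome, vocab, signatures, layout, hk_ordinals=()):
    comps = _components_at(genome, vocab, layout)
    clusters, comps = find_che_clusters(
        genome, comps,
        kinase_gene_ids={f"g{o:03d}" for o in hk_ordinals})
    hk_genes = {f"g{o:03d}" for o in hk_ordinals}
    out = []
    for cl in clusters:
        tokens = tokenize_cluster(cl, comps, hk_genes)
        out.append(assign_f_class(cl, tokens, comps, signatures))
    return out


def test_f3_full_assignment(vocab, signatures):
    """cheVAW with REC-bearing CheA and an auxiliary REC-less CheB
    elsewhere in the genome: the class text-book definition."""
    g = linear_genome(30)
    layout = {5: ["CheW", "Response_reg"],
              6: ["Response_reg", "Hpt", "HATPase_c"],
              7: ["CheW"],
              20: ["CheB_methylest"]}  # auxiliary CheB, outside the cluster
    assignments = _assign(g, vocab, signatures, layout)
    f3 = assignments[0]
    assert (f3.class_name, f3.status) == ("F3", "full")
    assert f3.completeness == pytest.approx(1.0)


def test_f3_without_rec_chea_is_not_full(vocab, signatures):
    g = linear_genome(30)
    layout = {5: ["CheW", "Response_reg"], 6: ["Hpt", "HATPase_c"], 7: ["CheW"],
              20: ["CheB_methylest"]}
    a = _assign(g, vocab, signatures, layout)[0]
    assert a.class_name == "F3"
    assert a.status != "full"
    assert a.completeness < 1.0


def test_half_f9_cluster(vocab, signatures):
    """Receptor + CheW + CheB + CheR without kinase or CheY: matched to
    F9 at roughly half completeness."""
    g = linear_genome(20)
    layout = {5: ["MCPsignal"], 6: ["CheW"], 7: ["CheB_methylest", "Response_reg"],
              8: ["CheR"]}
    a = _assign(g, vocab, signatures, layout)[0]
    assert (a.class_name, a.status) == ("F9", "half")
    assert a.completeness == pytest.approx(4 / 6)


def test_empty_cluster_unassigned(vocab, signatures):
    a = assign_f_class([], [], {}, signatures)
    assert (a.class_name, a.status) == (None, "none")


def test_orientation_invariance(vocab, signatures):
    """Reversing the replicon leaves the class call unchanged."""
    g = linear_genome(30)
    layout = {5: ["CheW", "Response_reg"],
              6: ["Response_reg", "Hpt", "HATPase_c"],
              7: ["CheW"], 20: ["CheB_methylest"]}
    fwd = _assign(g, vocab, signatures, layout)[0]
    g_rev = g.reversed()
    layout_rev = {g.n_genes - 1 - i: names for i, names in layout.items()}
    comps = {}
    for i, names in layout_rev.items():
        pid = g_rev.replicons["rep1"][i].protein_id
        c = identify_che_components(make_arch(pid, names), vocab)
        comps[pid] = c
    clusters, comps = find_che_clusters(g_rev, comps)
    vaw = max(clusters, key=len)  # the other cluster is the auxiliary CheB
    rev = assign_f_class(vaw, tokenize_cluster(vaw, comps, set()),
                         comps, signatures)
    assert (fwd.class_name, fwd.status, fwd.completeness) \
        == (rev.class_name, rev.status, rev.completeness)


def test_completeness_monotone_under_deletion(vocab, signatures):
    """Removing a required-component gene never raises completeness."""
    g = linear_genome(30)
    full_layout = {5: ["MCPsignal"], 6: ["CheW"],
                   7: ["CheB_methylest", "Response_reg"], 8: ["CheR"],
                   9: ["Response_reg", "Hpt", "HATPase_c"], 10: ["Response_reg"]}
    full = _assign(g, vocab, signatures, full_layout)[0]
    for drop in list(full_layout):
        layout = {k: v for k, v in full_layout.items() if k != drop}
        reduced = _assign(g, vocab, signatures, layout)
        if reduced:
            assert reduced[0].completeness <= full.completeness + 1e-9


def test_generator_class_labels_recovered(vocab, signatures):
    specs = [("F3", "full"), ("F7", "full"), ("F8", "full"),
             ("F9", "half"), ("F14", "full")]
    implants = [{"kind": "che_cluster", "class_name": c, "status": s}
                for c, s in specs]
    syn = generate(SyntheticSpec(seed=4, genome_id="che",
                                 genes_per_replicon=200, implants=implants))
    res = classify_synthetic(syn)
    got = sorted((a.class_name, a.status) for a in res.che_assignments
                 if a.class_name is not None)
    assert got == sorted(specs)


# ---------------------------------------------------------------------------

def test_alignment_matches_bruteforce_oracle(signatures):
    """The DP signature alignment equals exhaustive enumeration of all
    alignments (both orientations, all insertion placements) on random
    clusters of up to 12 genes."""
    rng = np.random.default_rng(42)
    alphabet = list("ABDKMRSVWYCXZ.")
    for _ in range(300):
        n = int(rng.integers(1, 13))
        cluster = [alphabet[int(j)] for j in rng.integers(0, len(alphabet), size=n)]
        sig = signatures[int(rng.integers(len(signatures)))]
        dp = max(
            align_signature(tuple(sig.gene_order), tuple(cluster), sig.max_insertions)[0],
            align_signature(tuple(sig.gene_order), tuple(reversed(cluster)),
                            sig.max_insertions)[0],
        )
        assert dp == oracle_best_match(sig.gene_order, cluster, sig.max_insertions)
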