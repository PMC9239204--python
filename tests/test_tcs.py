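"""Two-component system classification, linkage, solo flags, clusters."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sigcensus.tcs import (
    classify_rr_output,
    classify_tcs_protein,
    detect_atypical_clusters,
    flag_solo,
    link_hk_rr,
)
from sigcensus.evaluation import classify_synthetic
from sigcensus.synth import SyntheticSpec, generate

from conftest import linear_genome, make_arch


@pytest.mark.parametrize(
    "names, role, rec_pos",
    [
        (["HisKA", "HATPase_c"], "HK", "absent"),
        (["PAS", "HisKA", "HATPase_c"], "HK", "absent"),
        (["Response_reg", "HisKA", "HATPase_c"], "HRR", "N_terminal"),
        (["HisKA", "HATPase_c", "Response_reg"], "HHK", "C_terminal"),
        (["Response_reg"], "RR", "absent"),
        (["Response_reg", "Trans_reg_C"], "RR", "absent"),
        (["HATPase_c"], "none", "absent"),  # stas_STYK candidate, not an HK
        (["HisKA"], "none", "absent"),
        (["PAS"], "none", "absent"),
        # ambiguous REC placements default to HHK (documented convention)
        (["Response_reg", "HisKA", "HATPase_c", "Response_reg"], "HHK", "C_terminal"),
    ],
)
def test_tcs_role_assignment(vocab, names, role, rec_pos):
    r = classify_tcs_protein(make_arch("p", names), vocab)
    assert (r.role, r.rec_position) == (role, rec_pos)


def test_interior_rec_labeled_hhk(vocab):
    """A REC hit between HisKA and HATPase (midpoint inside the kinase
    core) is labeled HHK with a warning rather than dropped."""
    from conftest import make_hit
    from sigcensus.model import ProteinArchitecture

    hits = [
        make_hit("p", "HisKA", 10, 80),
        make_hit("p", "Response_reg", 100, 200),
        make_hit("p", "HATPase_c", 220, 330),
    ]
    r = classify_tcs_protein(ProteinArchitecture("p", hits), vocab)
    assert r.role == "HHK"


def _roles_at(genome, vocab, layout):
    """layout: {ordinal: domain name list}; returns the roles dict."""
    roles = {}
    for i, names in layout.items():
        pid = genome.replicons["rep1"][i].protein_id
        roles[pid] = classify_tcs_protein(make_arch(pid, names), vocab)
    return roles


HK, RR = ["HisKA", "HATPase_c"], ["Response_reg"]


def test_link_types(vocab):
    g = linear_genome(30)
    # adjacent pair at 10/11; isolated 1:1 pair at 18 & 22 (3 intervening);
    # HK at 2 flanked by RRs at 0 and 4 -> multi links
    roles = _roles_at(g, vocab, {10: HK, 11: RR, 18: HK, 22: RR,
                                 2: HK, 0: RR, 4: RR})
    links = {(l.hk_gene_id, l.rr_gene_id): l for l in link_hk_rr(g, roles)}
    assert links[("g010", "g011")].link_type == "adjacent_pair"
    assert links[("g010", "g011")].distance == 0
    assert links[("g018", "g022")].link_type == "one_to_one_within_window"
    assert links[("g002", "g000")].link_type == "multi_within_window"
    assert links[("g002", "g004")].link_type == "multi_within_window"
    assert len(links) == 4


@pytest.mark.parametrize("distance, solo", [(4, False), (5, True)])
def test_solo_boundary(vocab, distance, solo):
    """'More than four genes away' flips exactly between distances 4 and 5."""
    g = linear_genome(20)
    roles = _roles_at(g, vocab, {0: HK, distance + 1: RR})
    assert flag_solo(g, roles)["g000"] is solo


def test_hk_with_no_rr_anywhere_is_solo(vocab):
    g = linear_genome(10)
    roles = _roles_at(g, vocab, {5: HK})
    assert flag_solo(g, roles)["g005"] is True


@given(rr_ordinals=st.sets(st.integers(0, 29), max_size=6),
       hk_ordinal=st.integers(0, 29), window=st.integers(0, 8))
def test_solo_monotone_in_window(vocab, rr_ordinals, hk_ordinal, window):
    """Enlarging the window never turns a non-solo gene solo."""
    g = linear_genome(30)
    layout = {hk_ordinal: HK}
    layout.update({o: RR for o in rr_ordinals if o != hk_ordinal})
    roles = _roles_at(g, vocab, layout)
    solo_small = flag_solo(g, roles, window=window)
    solo_big = flag_solo(g, roles, window=window + 1)
    gid = f"g{hk_ordinal:03d}"
    if not solo_small[gid]:
        assert not solo_big[gid]


def test_links_invariant_under_replicon_reversal(vocab):
    rng = np.random.default_rng(5)
    g = linear_genome(40)
    layout = {}
    for o in rng.choice(40, size=10, replace=False):
        layout[int(o)] = HK if rng.random() < 0.5 else RR
    roles = _roles_at(g, vocab, layout)
    fwd = {(l.hk_gene_id, l.rr_gene_id, l.link_type, l.distance)
           for l in link_hk_rr(g, roles)}
    rev = {(l.hk_gene_id, l.rr_gene_id, l.link_type, l.distance)
           for l in link_hk_rr(g.reversed(), roles)}
    assert fwd == rev


@pytest.mark.parametrize(
    "names, category",
    [
        (["Response_reg", "Trans_reg_C"], "dna_binding"),
        (["Response_reg", "GerE"], "dna_binding"),
        (["Response_reg", "GGDEF"], "cdgmp_enzyme"),
        (["Response_reg", "EAL"], "cdgmp_enzyme"),
        (["Response_reg"], "other_unknown"),
        # chimera: enzyme output takes precedence over the HTH
        (["Response_reg", "GGDEF", "Trans_reg_C"], "cdgmp_enzyme"),
    ],
)
def test_rr_output_categories(vocab, names, category):
    assert classify_rr_output(make_arch("p", names), vocab).category == category


# ---------------------------------------------------------------------------

def test_atypical_cluster_detection(vocab):
    g = linear_genome(40)
    layout = {10: ["HisKA", "HATPase_c", "Response_reg"],  # HHK
              11: RR, 13: ["Response_reg", "HisKA", "HATPase_c"],  # HRR
              14: RR, 16: HK}
    roles = _roles_at(g, vocab, layout)
    signaling = {f"g{o:03d}" for o in layout}
    clusters = detect_atypical_clusters(g, roles, signaling, max_gap=2, min_atypical=2)
    assert len(clusters) == 1
    assert clusters[0].n_signaling_genes == 5
    assert clusters[0].n_atypical_hks == 2


def test_no_atypicals_no_clusters(vocab):
    g = linear_genome(20)
    roles = _roles_at(g, vocab, {3: HK, 4: RR, 6: HK, 7: RR})
    clusters = detect_atypical_clusters(g, roles, {"g003", "g004", "g006", "g007"})
    assert clusters == []


def test_generator_implanted_clusters_recovered_exactly():
    """k implanted atypical-HK clusters -> exactly k detected."""
    spec = SyntheticSpec(
        seed=3, genome_id="atyp", genes_per_replicon=400,
        implants=[{"kind": "atypical_cluster", "n_signaling": 8, "n_atypical": 2}
                  for _ in range(3)],
    )
    syn = generate(spec)
    res = classify_synthetic(syn)
    assert len(res.atypical_clusters) == 3
    assert all(c.n_signaling_genes == 8 for c in res.atypical_clusters)
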