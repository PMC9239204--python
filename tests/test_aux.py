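"""ECF, cAMP, STYK/PP2C/STAS, QS screen and combined pathways."""

import pytest
from hypothesis import given, strategies as st

from sigcensus.aux_systems import (
    classify_aux,
    classify_ecf,
    classify_styk,
    detect_camp_cluster,
    detect_combined_pathways,
    detect_ecf242,
    qs_screen,
)
from sigcensus.evaluation import classify_synthetic
from sigcensus.synth import SyntheticSpec, generate

from conftest import linear_genome, make_arch


def test_ecf_requires_both_and_only(vocab):
    assert classify_ecf(make_arch("p", ["Sigma70_r2", "Sigma70_r4_2"]), vocab)
    assert not classify_ecf(make_arch("p", ["Sigma70_r2", "Sigma70_r4_2", "PAS"]), vocab)
    assert not classify_ecf(make_arch("p", ["Sigma70_r4_2"]), vocab)
    assert not classify_ecf(make_arch("p", ["Sigma70_r2", "Sigma70_r2"]), vocab)


@given(extra=st.sampled_from(
    ["PAS", "GAF", "Response_reg", "HisKA", "GGDEF", "TPR_1", "FecR", "CheW"]))
def test_ecf_flips_negative_with_any_extra_domain(vocab, extra):
    """Exact-set semantics: adding any third domain disqualifies an ECF."""
    assert classify_ecf(make_arch("p", ["Sigma70_r2", "Sigma70_r4_2"]), vocab)
    assert not classify_ecf(make_arch("p", ["Sigma70_r2", "Sigma70_r4_2", extra]), vocab)


@pytest.mark.parametrize(
    "names, system",
    [
        (["Pkinase"], "eSTYK"),
        (["PP2Cc", "Pkinase"], "bifunctional_PP2C_Pkinase"),
        (["Response_reg", "PP2Cc", "Pkinase"], "bifunctional_PP2C_Pkinase"),
        (["HATPase_c_2"], "stas_STYK"),      # HATPase family, no HisKA
        (["HATPase_c"], "stas_STYK"),
        (["PP2Cc"], "PP2C"),
        (["SpoIIE"], "PP2C"),
        (["STAS"], "STAS"),
    ],
)
def test_styk_family_rules(vocab, names, system):
    c = classify_styk(make_arch("p", names), vocab)
    assert c is not None and c.system == system


def test_styk_guards_exclude_hk_and_chea(vocab):
    assert classify_styk(make_arch("p", ["HisKA", "HATPase_c"]), vocab) is None
    assert classify_styk(make_arch("p", ["Hpt", "HATPase_c"]), vocab) is None


def test_classify_aux_order(vocab):
    assert classify_aux(make_arch("p", ["Sigma70_r2", "Sigma70_r4_2"]), vocab).system == "ECF"
    ac = classify_aux(make_arch("p", ["CHASE2", "Adenylate_cycl"]), vocab)
    assert ac.system == "AC" and ac.has_chase2
    assert classify_aux(make_arch("p", ["cNMP_binding"]), vocab).system == "CRP_like"
    assert classify_aux(make_arch("p", ["PAS"]), vocab) is None


# ---------------------------------------------------------------------------

def test_ecf242_detection(vocab):
    g = linear_genome(20)
    out = detect_ecf242(g, ecf_pids={"p005"}, fecr_pids={"p006"},
                        tonb_pids={"p008"}, window=4)
    assert len(out) == 1
    assert out[0].members == ["g005", "g006", "g008"]
    # no FecR within the window -> no candidate
    assert detect_ecf242(g, {"p005"}, {"p015"}, set(), window=4) == []


def test_tandem_ecf242_copies_detected_via_generator():
    syn = generate(SyntheticSpec(
        seed=2, genome_id="e", genes_per_replicon=60,
        implants=[{"kind": "ecf242", "copies": 2, "with_tonb": True}]))
    res = classify_synthetic(syn)
    assert len(res.ecf242) == 2


def test_camp_cluster_rules(vocab):
    g = linear_genome(30)
    full = detect_camp_cluster(g, ac_pids={"p010"}, camp_pde_pids={"p011"},
                               fecr_pids={"p012"}, tpr_pids={"p013"}, window=6)
    assert len(full) == 1
    assert sorted(full[0].support_types) == ["FecR", "TPR", "cAMP_PDE"]
    # cyclase alone: system present (caller reports), but no cluster
    assert detect_camp_cluster(g, {"p010"}, set(), set(), set()) == []


def test_crp_without_cyclase_flagged():
    syn = generate(SyntheticSpec(seed=6, genome_id="c", genes_per_replicon=40,
                                 implants=[{"kind": "crp"}]))
    res = classify_synthetic(syn)
    assert res.crp_without_cyclase != []
    syn2 = generate(SyntheticSpec(
        seed=6, genome_id="c2", genes_per_replicon=60,
        implants=[{"kind": "crp"}, {"kind": "camp_cluster", "full": False}]))
    res2 = classify_synthetic(syn2)
    assert res2.crp_without_cyclase == []


def test_qs_screen_requires_both_probes(vocab, qs_vocab):
    none = qs_screen({}, qs_vocab)
    assert all(not r.present for r in none)

    syn_only = {"p1": make_arch("p1", ["Autoind_synth"])}
    reports = {r.pathway: r for r in qs_screen(syn_only, qs_vocab)}
    assert not reports["AHL"].present and reports["AHL"].partial

    both = {"p1": make_arch("p1", ["Autoind_synth"]),
            "p2": make_arch("p2", ["Autoind_bind"])}
    reports = {r.pathway: r for r in qs_screen(both, qs_vocab)}
    assert reports["AHL"].present


def test_combined_pathway_contiguous_vs_scattered(vocab):
    g = linear_genome(30)
    role_pids = {
        "pp2c": {"p010"}, "stas_styk": {"p011"}, "stas": {"p012"},
        "cdgmp": {"p013"},
        "rec_bifunctional": set(), "mcp": set(), "ecf": set(),
        "cyclase_enzyme": set(),
    }
    out = detect_combined_pathways(g, role_pids, window=6)
    assert len(out) == 1 and out[0].rule_name == "pp2c_styk_stas_cdgmp"

    # same roles scattered far apart: nothing fires
    far = dict(role_pids)
    far.update({"pp2c": {"p000"}, "stas_styk": {"p010"}, "stas": {"p020"},
                "cdgmp": {"p029"}})
    assert detect_combined_pathways(g, far, window=6) == []


def test_generator_combined_rules_recovered():
    implants = [{"kind": "combined", "rule": r} for r in
                ("pp2c_styk_stas_cdgmp", "rec_pp2c_styk_mcp",
                 "ecf_partial_plus_cyclase")]
    syn = generate(SyntheticSpec(seed=8, genome_id="cb", genes_per_replicon=80,
                                 implants=implants))
    res = classify_synthetic(syn)
    assert sorted(c.rule_name for c in res.combined) == sorted(
        r["rule"] for r in implants)
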