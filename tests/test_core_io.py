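"""Gene/domain table IO and architecture resolution."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sigcensus.io import (
    read_domain_table,
    read_gene_table,
    resolve_architecture,
    write_domain_table,
    write_gene_table,
)
from sigcensus.model import DomainHit

from conftest import make_hit


GFF = """##gff-version 3
chr1\tsrc\tCDS\t2000\t2900\t.\t+\t.\tID=b;protein_id=bp
chr1\tsrc\tCDS\t100\t900\t.\t+\t.\tID=a;protein_id=ap
chr1\tsrc\tpseudogene\t3100\t3400\t.\t-\t.\tID=c
chr1\tsrc\tCDS\t5000\t5900\t.\t-\t.\tID=d;protein_id=dp
"""


def test_gff3_sorted_ordinals(tmp_path):
    """Genes get ordinals in coordinate order, not file order; non-coding
    features occupy an ordinal but carry no protein."""
    p = tmp_path / "genes.gff3"
    p.write_text(GFF)
    g = read_gene_table(p)
    genes = g.replicons["chr1"]
    assert [x.gene_id for x in genes] == ["a", "b", "c", "d"]
    assert [x.ordinal for x in genes] == [0, 1, 2, 3]
    assert genes[2].protein_id is None
    assert genes[3].strand == "-"


def test_empty_gene_table(tmp_path):
    p = tmp_path / "genes.tsv"
    p.write_text("")
    g = read_gene_table(p)
    assert g.n_genes == 0


def test_duplicate_gene_id_is_hard_error(tmp_path):
    p = tmp_path / "genes.tsv"
    p.write_text(
        "gene_id\treplicon\tstart\tend\tstrand\tprotein_id\n"
        "a\tchr1\t1\t10\t+\tap\na\tchr1\t20\t30\t+\tbp\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        read_gene_table(p)


def test_tsv_out_of_order_sorted_by_start(tmp_path):
    """Ordinal assignment equals an independent sort of the start column."""
    rng = np.random.default_rng(0)
    starts = rng.choice(np.arange(1, 100000, 100), size=40, replace=False)
    lines = ["gene_id\treplicon\tstart\tend\tstrand\tprotein_id"]
    for i, s in enumerate(starts):
        lines.append(f"g{i}\tchr1\t{s}\t{s + 50}\t+\tp{i}")
    p = tmp_path / "genes.tsv"
    p.write_text("\n".join(lines) + "\n")
    g = read_gene_table(p)
    expected = [f"g{i}" for i in np.argsort(starts, kind="stable")]
    assert [x.gene_id for x in g.replicons["chr1"]] == expected


@pytest.mark.parametrize("fmt", ["tsv", "gff3"])
def test_gene_table_round_trip(tmp_path, fmt):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF)
    g1 = read_gene_table(p)
    out = tmp_path / f"again.{'tsv' if fmt == 'tsv' else 'gff3'}"
    write_gene_table(g1, out, fmt=fmt)
    g2 = read_gene_table(out)
    assert {r: [tuple(vars(x).values()) for x in gs] for r, gs in g1.replicons.items()} \
        == {r: [tuple(vars(x).values()) for x in gs] for r, gs in g2.replicons.items()}


# ---------------------------------------------------------------------------

DOMTBL = """# comment line
#                       --- full sequence --- -------------- this domain --------------
HisKA  PF00512.28  64  prot1  -  480  1e-20  80.0  0.1  1  2  1e-18  1e-16  75.0  0.1  1  60  200  260  198  262  0.9  histidine kinase
HATPase_c  PF02518.28  110  prot1  -  480  1e-30  90.0  0.1  1  1  1e-28  1e-26  88.0  0.1  1  108  300  410  298  412  0.9  -
GGDEF  PF00990.25  160  prot2  -  350  2e-3  12.0  0.1  1  1  2e-3  1e-2  10.0  0.1  1  150  100  260  98  262  0.8  weak hit
malformed row
"""


def test_domtblout_parse_and_threshold(tmp_path):
    """Comments and malformed rows are skipped; hits above the e-value
    threshold are dropped (the 1e-16 hit survives 1e-5, the 1e-2 does not)."""
    p = tmp_path / "hits.domtblout"
    p.write_text(DOMTBL)
    hits = read_domain_table(p, evalue_threshold=1e-5)
    assert [h.name for h in hits] == ["HisKA", "HATPase_c"]
    h = hits[0]
    assert (h.protein_id, h.env_start, h.env_end) == ("prot1", 198, 262)
    assert h.e_value == pytest.approx(1e-16)
    # threshold=None keeps the weak GGDEF hit too
    assert len(read_domain_table(p, evalue_threshold=None)) == 3


def test_domain_tsv_round_trip(tmp_path):
    hits = [make_hit("p1", "GGDEF", 10, 170, evalue=1e-6),
            make_hit("p1", "EAL", 200, 440, evalue=1e-30)]
    p = tmp_path / "d.tsv"
    write_domain_table(hits, p)
    back = read_domain_table(p, evalue_threshold=1e-5)
    assert [(h.protein_id, h.name, h.env_start, h.env_end) for h in back] \
        == [(h.protein_id, h.name, h.env_start, h.env_end) for h in hits]


@given(
    evs=st.lists(st.floats(min_value=1e-40, max_value=1.0), min_size=1, max_size=30),
    thr=st.floats(min_value=1e-30, max_value=1e-2),
)
def test_evalue_filter_is_subset_of_unfiltered(tmp_path_factory, evs, thr):
    """Any finite threshold yields a subset of the unfiltered rows,
    exactly those at or below the threshold."""
    tmp = tmp_path_factory.mktemp("ev")
    hits = [make_hit(f"p{i}", "PAS", 1, 100, evalue=e) for i, e in enumerate(evs)]
    p = tmp / "d.tsv"
    write_domain_table(hits, p)
    all_hits = {h.protein_id for h in read_domain_table(p, evalue_threshold=None)}
    kept = {h.protein_id for h in read_domain_table(p, evalue_threshold=thr)}
    assert kept <= all_hits
    assert kept == {f"p{i}" for i, e in enumerate(evs) if e <= thr}


# ---------------------------------------------------------------------------

def test_resolve_dominance():
    """Of two identical-interval hits the higher-scoring one survives."""
    hits = [make_hit("p", "A", 10, 100, score=80), make_hit("p", "B", 10, 100, score=40)]
    arch = resolve_architecture(hits)
    assert [h.name for h in arch.domains] == ["A"]


def test_resolve_keeps_disjoint_in_order():
    hits = [
        make_hit("p", "HATPase_c", 230, 340, score=90),
        make_hit("p", "REC", 1, 120, score=50),
        make_hit("p", "HisKA", 150, 210, score=70),
    ]
    arch = resolve_architecture(hits)
    assert [h.name for h in arch.domains] == ["REC", "HisKA", "HATPase_c"]


def test_resolve_drops_hit_beyond_sequence():
    hits = [make_hit("p", "GGDEF", 10, 170)]
    arch = resolve_architecture(hits, sequence="A" * 100)
    assert arch.domains == []


@st.composite
def _random_hits(draw):
    n = draw(st.integers(1, 12))
    hits = []
    for i in range(n):
        start = draw(st.integers(1, 300))
        length = draw(st.integers(5, 120))
        score = draw(st.floats(min_value=1, max_value=500))
        hits.append(make_hit("p", f"D{i}", start, start + length - 1, score=score))
    return hits


@given(hits=_random_hits(), frac=st.sampled_from([0.0, 0.2, 0.5]))
def test_resolution_no_overlap_and_maximal(hits, frac):
    """Resolved architectures never violate the overlap policy, and no
    rejected hit could be added back (greedy result is maximal)."""
    arch = resolve_architecture(hits, max_overlap_frac=frac)
    kept = arch.domains
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            assert a.overlap(b) <= frac * min(a.length, b.length) + 1e-9
    rejected = [h for h in hits if h not in kept]
    for r in rejected:
        assert any(
            r.overlap(a) > frac * min(r.length, a.length) for a in kept
        ), "rejected hit is compatible with all accepted hits"
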