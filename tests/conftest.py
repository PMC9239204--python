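import pytest
from hypothesis import HealthCheck, settings

from sigcensus.model import DomainHit, GeneRecord, Genome, ProteinArchitecture
from sigcensus.vocab import DomainVocabulary, load_qs_vocabulary
from sigcensus.chemo import load_signatures

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def vocab():
    return DomainVocabulary.default()


@pytest.fixture(scope="session")
def signatures():
    return load_signatures()


@pytest.fixture(scope="session")
def qs_vocab():
    return load_qs_vocabulary()


def make_hit(pid, name, start, end, score=100.0, evalue=1e-20):
    return DomainHit(protein_id=pid, accession="", name=name,
                     env_start=start, env_end=end, e_value=evalue, bit_score=score)


def make_arch(pid, names, sequence=None, dom_len=100, gap=20):
    """Architecture with the named domains laid out left to right."""
    hits, pos = [], 10
    for name in names:
        hits.append(make_hit(pid, name, pos, pos + dom_len - 1))
        pos += dom_len + gap
    return ProteinArchitecture(protein_id=pid, domains=hits, sequence=sequence,
                               length_aa=len(sequence) if sequence else pos + 50)


def linear_genome(n_genes, genome_id="g", replicon="rep1", metadata=None):
    """n coding genes in a row; gene i is g###, protein p###."""
    genes = [
        GeneRecord(f"g{i:03d}", replicon, i, 1 + 1000 * i, 900 + 1000 * i, "+", f"p{i:03d}")
        for i in range(n_genes)
    ]
    return Genome(genome_id, {replicon: genes}, metadata or {})
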