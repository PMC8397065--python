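import pytest

from mitochar.genome_io import AnnotatedMitogenome, GeneFeature
from mitochar.synthetic_data import GeneratorConfig, generate, study_like_fixture_set


@pytest.fixture(scope="session")
def default_genome():
    """One genome from the default generator plan, with its ground truth."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_set():
    """The five study-like genomes (accession-order), with ground truths."""
    return study_like_fixture_set(seed=1)


def make_toy_genome(seq: str, feats: list[tuple], genome_id: str = "toy") -> AnnotatedMitogenome:
    """feats: (name, role, start, end, strand) in 0-based half-open coordinates."""
    features = [GeneFeature(canonical_name=n, role=r, start=s, end=e, strand=st) for n, r, s, e, st in feats]
    return AnnotatedMitogenome(id=genome_id, sequence=seq, features=features)
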