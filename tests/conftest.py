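import pytest

from rcseq import (
    SimConfig,
    decode_reads,
    fidelity_profile,
    fixed_termination,
    simulate_dataset,
)
from rcseq.templates import builtin_templates


@pytest.fixture(scope="session")
def collection():
    return builtin_templates()


@pytest.fixture(scope="session")
def circular_A(collection):
    return collection.templates["A_circular"]


@pytest.fixture(scope="session")
def linear_A(collection):
    return collection.templates["A_linear"]


@pytest.fixture(scope="session")
def barcode_map(collection):
    return collection.barcode_map()


@pytest.fixture(scope="session")
def circular_specs(collection, barcode_map):
    return {label: collection.templates[label + "_circular"] for label in barcode_map.values()}


@pytest.fixture(scope="session")
def onepot_sim(circular_A):
    """A standard simulated one-pot-style dataset on circular template A:
    2,000 reads, 18 incorporations each, plateau/invasion/recovery fidelity
    profile, every read adapter-terminated."""
    config = SimConfig(
        seed=101,
        n_reads=2000,
        template=circular_A,
        p_correct=fidelity_profile(18),
        termination=fixed_termination(18),
    )
    reads, truth = simulate_dataset(config)
    return config, reads, truth


@pytest.fixture(scope="session")
def onepot_decoded(onepot_sim, circular_A):
    _, reads, _ = onepot_sim
    return decode_reads(reads, circular_A.primer_seq)


#: Error distribution that cannot recreate the primer inside a read: the
#: primer GAAGAACTG can only be spelled in-frame as GAA,GAA,CTG (no other
#: alphabet triplets spell it across frame boundaries), so excluding CTG
#: (and GAA, so errors stay errors) keeps the primer unique per read.
PRIMER_SAFE_ERRORS = {
    t: 1.0 / 12
    for t in ["ATA", "CCA", "CCC", "AAA", "CAC", "GGG", "TTA", "TCC", "GGC", "ATC", "GAT", "CGC"]
}


@pytest.fixture(scope="session")
def primer_safe_errors():
    return PRIMER_SAFE_ERRORS


@pytest.fixture(scope="session")
def shortpot_sim(circular_A):
    """Simulated reads terminating at 8 incorporations — short of the
    primer-site slots (10-12) — with a primer-safe error model, so the
    primer occurs exactly once per read and anchored decoding coincides
    with raw substring scanning.  Used for oracle-equivalence checks
    against grep-style counting."""
    config = SimConfig(
        seed=202,
        n_reads=1200,
        template=circular_A,
        p_correct={a: 0.9 for a in range(1, 9)},
        termination=fixed_termination(8),
        error_model=PRIMER_SAFE_ERRORS,
    )
    reads, truth = simulate_dataset(config)
    return config, reads, truth
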