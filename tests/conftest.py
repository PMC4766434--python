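import pytest

from epistate import (
    DomainAnnotation,
    build_inactive_model,
    conservation_profile,
    exposure_profile,
    load_alignment,
    make_toy_alignment,
    make_toy_crystal,
    parse_structure,
)
from epistate.synthetic import ToyAlignmentSpec, ToyCrystalSpec


@pytest.fixture(scope="session")
def toy_crystal():
    """Default toy crystal: (pdb_text, ground_truth)."""
    return make_toy_crystal(ToyCrystalSpec())


@pytest.fixture(scope="session")
def toy_model(toy_crystal):
    return parse_structure(toy_crystal[0])


@pytest.fixture(scope="session")
def toy_domains():
    spec = ToyCrystalSpec()
    return (
        DomainAnnotation("regulatory", "A", 1, spec.n_res_a),
        DomainAnnotation("partner", "B", 1, spec.n_res_b),
    )


@pytest.fixture(scope="session")
def toy_assembly(toy_model, toy_domains):
    reg, par = toy_domains
    return build_inactive_model(toy_model, reg, par)


@pytest.fixture(scope="session")
def toy_exposure(toy_assembly, toy_domains):
    return exposure_profile(toy_assembly, toy_domains[0])


@pytest.fixture(scope="session")
def toy_alignment():
    """Default toy alignment: (fasta_text, ground_truth)."""
    return make_toy_alignment(ToyAlignmentSpec())


@pytest.fixture(scope="session")
def toy_alignment_set(toy_alignment):
    fasta, truth = toy_alignment
    return load_alignment(fasta, truth["families"], truth["reference_id"], truth["offset"])


@pytest.fixture(scope="session")
def toy_conservation(toy_alignment_set):
    return conservation_profile(toy_alignment_set)
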