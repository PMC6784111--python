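import numpy as np
import pytest

from abframe.germline import find_closest_germline, group_mismatches, load_toy_germlines
from abframe.kabat import CONSENSUS_TEMPLATES, assign_kabat_numbering
from abframe.simulate import GeneratorConfig, generate_variant_panel, parental_vl_sequence


@pytest.fixture(scope="session")
def kappa_consensus() -> str:
    return CONSENSUS_TEMPLATES["L"]


@pytest.fixture(scope="session")
def heavy_consensus() -> str:
    return CONSENSUS_TEMPLATES["H"]


@pytest.fixture(scope="session")
def parental_vl():
    ns = assign_kabat_numbering(parental_vl_sequence(), "L")
    ns.source_id = "parental-VL"
    return ns


@pytest.fixture(scope="session")
def germline_set():
    return load_toy_germlines("L")


@pytest.fixture(scope="session")
def germline_match(parental_vl, germline_set):
    return find_closest_germline(parental_vl, germline_set)


@pytest.fixture(scope="session")
def mutation_regions(parental_vl, germline_set, germline_match):
    germ = next(g for g in germline_set if g.source_id == germline_match.germline_id)
    return group_mismatches(germline_match.mismatches, query=parental_vl, germline=germ)


@pytest.fixture(scope="session")
def panel_bundle():
    return generate_variant_panel(GeneratorConfig(seed=0))
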