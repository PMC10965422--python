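import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cdrdesign import (
    ModelConfig,
    Model,
    ToySpec,
    encode_sample,
    select_context,
)
from cdrdesign.synthetic import make_toy_complex


def _ca_line(serial, res_name, chain, res_num, x, y, z, icode=" "):
    return (
        f"ATOM  {serial:5d}  CA  {res_name} {chain}{res_num:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
    )


@pytest.fixture
def minimal_pdb_text():
    """Three-residue single-chain CA trace."""
    lines = [
        _ca_line(1, "ALA", "H", 1, 0.0, 0.0, 0.0),
        _ca_line(2, "GLY", "H", 2, 3.8, 0.0, 0.0),
        _ca_line(3, "SER", "H", 3, 7.6, 0.0, 0.0),
        "TER",
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def insertion_pdb_text():
    """Chain with an insertion-coded residue 100A between 100 and 101."""
    lines = [
        _ca_line(1, "ALA", "H", 99, 0.0, 0.0, 0.0),
        _ca_line(2, "GLY", "H", 100, 3.8, 0.0, 0.0),
        _ca_line(3, "TYR", "H", 100, 7.6, 0.0, 0.0, icode="A"),
        _ca_line(4, "TRP", "H", 101, 11.4, 0.0, 0.0),
        "TER",
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_chain_pdb_text():
    """Antibody chain H plus antigen chain A."""
    lines = [
        _ca_line(1, "ALA", "H", 1, 0.0, 0.0, 0.0),
        _ca_line(2, "GLY", "H", 2, 3.8, 0.0, 0.0),
        "TER",
        _ca_line(3, "LEU", "A", 1, 0.0, 8.0, 0.0),
        _ca_line(4, "LYS", "A", 2, 3.8, 8.0, 0.0),
        "TER",
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec(n_complexes=8, seed=5)


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    """(ComplexRecord, CdrSpec, class_id) for one deterministic toy complex."""
    return make_toy_complex(toy_spec, 0)


@pytest.fixture(scope="session")
def toy_sample(toy_complex):
    record, cdr, _ = toy_complex
    context = select_context(record, "H")
    return encode_sample(context, cdr, k_neighbors=24)


@pytest.fixture(scope="session")
def small_model():
    return Model(
        ModelConfig(n_layers=5, hidden_dim=24, aa_embed_dim=12, k_neighbors=24),
        seed=1,
    )
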