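import numpy as np
import pytest

from gating_metrics.structure import Atom, Structure
from gating_metrics.synthetic import build_tetramer, demo_config


def make_atom(
    name,
    coords,
    res_seq=1,
    chain_id="A",
    res_name="GLY",
    element=None,
    serial=1,
):
    if element is None:
        element = name.lstrip("0123456789")[0]
    return Atom(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        coords=tuple(float(x) for x in coords),
        is_hydrogen=(element == "H"),
    )


def make_structure(atom_specs, label="test"):
    """Build a Structure from (name, coords[, kwargs]) tuples."""
    atoms = []
    for k, spec in enumerate(atom_specs):
        name, coords = spec[0], spec[1]
        kwargs = spec[2] if len(spec) > 2 else {}
        kwargs.setdefault("serial", k + 1)
        atoms.append(make_atom(name, coords, **kwargs))
    return Structure(atoms, label=label)


@pytest.fixture(scope="session")
def wt_tetramer():
    """The shipped wild-type demo tetramer (Ile at 223)."""
    return build_tetramer(demo_config(mutant=False))


@pytest.fixture(scope="session")
def mutant_tetramer():
    """The Leu-223 demo tetramer."""
    return build_tetramer(demo_config(mutant=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
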