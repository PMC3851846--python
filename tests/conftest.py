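import pytest

from ancadj.examples import load_worked_example
from ancadj.io import read_species_tree


@pytest.fixture
def worked_example():
    """Fresh copy of the packaged two-family example (the pipeline
    subdivides trees in place, so each test loads its own)."""
    return load_worked_example()


@pytest.fixture
def four_species_tree():
    """The worked example's dated species tree: ((A,B)e,(C,D)f)r with
    ranks r=0, e=1, f=2."""
    return read_species_tree("((A,B)e,(C,D)f)r;", "r\t0\ne\t1\nf\t2\n")
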