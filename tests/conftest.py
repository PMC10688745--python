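import numpy as np
import pytest

from photothermal import load_reference_surfaces


@pytest.fixture(scope="session")
def reference_rows():
    return load_reference_surfaces()


def ref_row(rows, species, trait, has=None):
    """Pick a reference row by species/trait, optionally requiring a term."""
    candidates = [r for r in rows if r.species == species and r.trait == trait
                  and (has is None or has in r.coefficients.term_mask)]
    assert candidates, f"no reference row {species}/{trait} (has={has})"
    return max(candidates,
               key=lambda r: (len(r.coefficients.term_mask), r.r_squared))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
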