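import numpy as np
import pytest

from reefshield import reef3d, synthgen


@pytest.fixture(scope="session")
def shape_bank():
    return synthgen.generate_shape_bank(n_per_taxon=2, seed=1)


@pytest.fixture(scope="session")
def stamp_bank(shape_bank):
    return reef3d.build_stamp_bank(shape_bank)


@pytest.fixture(scope="session")
def survey():
    return synthgen.generate_survey_table(seed=3)


@pytest.fixture(scope="session")
def desk_bathymetry():
    return synthgen.generate_bathymetry(
        synthgen.BathymetryConfig(
            flat_length=40.0, sand_length=30.0, offshore_pad=100.0
        )
    )


@pytest.fixture(scope="session")
def small_strip():
    return reef3d.SubstrateStrip(length=10.0, width=0.5, cell=0.01)
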