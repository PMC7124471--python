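import numpy as np
import pytest
from hypothesis import settings

from glycosearch.simulate import SimConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cfg():
    """A small but complete simulation: fast enough for unit tests while
    exercising co-elution, mispicks and negatives."""
    return SimConfig(seed=7, n_glycopeptides=40, n_negative=40, n_glycans=50)


def make_gpsm(**kw):
    """Minimal duck-typed GPSM for the FDR/report stages."""
    from types import SimpleNamespace

    defaults = dict(
        raw="r",
        scan=1,
        candidate_index=0,
        precursor_mz=1000.0,
        charge=2,
        neutral_mass=2000.0,
        score=50.0,
        motif_class="NXT",
        decoy=False,
        entrapment=False,
        backbone_key=("PEPTIDE", ()),
    )
    defaults.update(kw)
    glycan = SimpleNamespace(
        mass=kw.get("glycan_mass", 1500.0),
        entrapment=defaults["entrapment"],
        compositions=(),
    )
    return SimpleNamespace(glycan=glycan, **defaults)
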