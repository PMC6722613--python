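import numpy as np
import pytest

from splicecnn.data import encode_events
from splicecnn.events import SplicingEvent, classify_events
from splicecnn.synth import SynthConfig, generate_dataset


def make_event(event_id="ev1", cls="CON", **kw):
    """A well-formed event of the requested class, overridable per-field."""
    base = dict(
        event_id=event_id,
        chrom="chr1",
        strand="+",
        exon_start=1000,
        exon_end=1120,
        upstream_intron_len=500,
        downstream_intron_len=600,
        incl_level=1.0,
        usage3_level=1.0,
        usage5_level=1.0,
        est_incl=50,
        est_excl=0,
        est_alt3=0,
        est_alt5=0,
    )
    if cls == "ES":
        base.update(incl_level=0.5, est_incl=25, est_excl=25)
    elif cls == "ALT3":
        base.update(usage3_level=0.6, est_alt3=8)
    elif cls == "ALT5":
        base.update(usage5_level=0.6, est_alt5=8)
    base.update(kw)
    e = SplicingEvent(**base)
    return classify_events([e])[0]


@pytest.fixture(scope="session")
def small_synth():
    """Small planted-motif dataset shared across read-only tests."""
    return generate_dataset(SynthConfig(scale=0.01, seed=42))


@pytest.fixture(scope="session")
def small_encoded(small_synth):
    dataset, stats = encode_events(small_synth.events, small_synth.genome)
    return dataset, stats


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
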