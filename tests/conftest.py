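import numpy as np
import pytest

from taushield.xlms import CrossLinkRecord


@pytest.fixture
def make_record():
    """Factory for cross-link records with all-passing QC defaults."""

    def _make(**overrides):
        fields = dict(
            replicate_id="rep1",
            condition="WT",
            temperature_c=37.0,
            res_a=280,
            res_b=321,
            score=30.0,
            mass_error_ppm=1.0,
            tic_pct=15.0,
            pep_len_a=8,
            pep_len_b=9,
            frag_ions_a=5,
            frag_ions_b=5,
            contig_frags_a=4,
            contig_frags_b=4,
            nseen=3,
        )
        fields.update(overrides)
        return CrossLinkRecord(**fields)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
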