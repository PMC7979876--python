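import numpy as np
import pytest

from somaseq.io_model import SmallVariantCall


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_call(**overrides) -> SmallVariantCall:
    """A call that passes every pipeline filter unless overridden.

    Strand splits are kept consistent with the ao/ro totals supplied.
    """
    fields = dict(
        chrom="17", pos=1000, ref="A", alt="T", qual=50.0, numalt=1,
        ao=40, ro=40, qa=1200.0, qr=1200.0, mqm=60.0, sap=5.0, ab=0.5,
    )
    fields.update(overrides)
    fields.setdefault("saf", fields["ao"] // 2)
    fields.setdefault("sar", fields["ao"] - fields["saf"])
    fields.setdefault("srf", fields["ro"] // 2)
    fields.setdefault("srr", fields["ro"] - fields["srf"])
    return SmallVariantCall(**fields)
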