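import numpy as np
import pytest

from paleoroh import ReferencePanel, SNPSite


def make_sites(pos_cm, chrom="1", transversion=True):
    """Panel sites at the given cM positions; all transversions by default."""
    ref, alt = ("A", "C") if transversion else ("C", "T")
    return [
        SNPSite(chrom, int(round(p * 1e6)) + 1, float(p), ref, alt, f"s{i}")
        for i, p in enumerate(pos_cm)
    ]


def tiny_panel(haps, pos_cm, freqs=None):
    haps = np.asarray(haps, dtype=np.int8)
    if freqs is None:
        freqs = haps.mean(axis=0)
    return ReferencePanel(haps, np.asarray(freqs, float), make_sites(pos_cm))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
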