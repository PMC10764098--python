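import numpy as np
import pytest

from numtkit.core import Hsp, Numt


def make_hsp(
    mt_start=0,
    mt_end=100,
    scaffold="scaf1",
    n_start=1000,
    n_end=1100,
    orientation="+",
    identity=95.0,
    aln_length=None,
    e_value=1e-40,
    bit_score=180.0,
):
    return Hsp(
        mt_start=mt_start,
        mt_end=mt_end,
        scaffold=scaffold,
        n_start=n_start,
        n_end=n_end,
        orientation=orientation,
        identity=identity,
        aln_length=aln_length if aln_length is not None else mt_end - mt_start,
        e_value=e_value,
        bit_score=bit_score,
    )


def make_numt(
    numt_id="Hsap_numt_1",
    scaffold="scaf1",
    n_start=1000,
    n_end=1100,
    orientation="+",
    mt_intervals=((0, 100),),
    identity=95.0,
    species="Hsap",
):
    return Numt(
        id=numt_id,
        scaffold=scaffold,
        n_start=n_start,
        n_end=n_end,
        orientation=orientation,
        mt_intervals=tuple(tuple(iv) for iv in mt_intervals),
        identity=identity,
        species=species,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def random_hsps(rng, n, mt_length=16_600, scaffold="scaf1"):
    """Random HSP instances dense enough for merges to occur."""
    hsps = []
    cursor = 0
    for _ in range(n):
        cursor += int(rng.integers(0, 30))
        length = int(rng.integers(30, 400))
        mt_start = int(rng.integers(0, mt_length - 1))
        mt_len = min(length, mt_length - mt_start)
        hsps.append(
            make_hsp(
                mt_start=mt_start,
                mt_end=mt_start + mt_len,
                scaffold=scaffold,
                n_start=cursor,
                n_end=cursor + length,
                orientation="+" if rng.random() < 0.5 else "-",
                identity=float(rng.uniform(70, 100)),
            )
        )
        cursor += length
    return hsps
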