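import numpy as np
import pytest

from dnvsex.qc import MISSING, VariantRecord


def make_record(
    chrom="1",
    pos=100,
    ref="A",
    alts=("T",),
    qual=50.0,
    gt=None,
    ad=None,
    dp=None,
    gq=None,
    pl=None,
    n_samples=None,
):
    """Build a VariantRecord from compact per-sample specs.

    ``gt`` is a list of dosages (-1 missing) or (a, b) allele pairs; missing
    arrays are filled with sensible defaults so tests only state what they
    assert on.
    """
    if gt is None:
        gt = [1] * (n_samples or 2)
    n = len(gt)
    gt_arr = np.zeros((n, 2), dtype=np.int8)
    for i, g in enumerate(gt):
        if np.isscalar(g):
            if g == MISSING:
                gt_arr[i] = MISSING
            else:
                gt_arr[i] = (1 if g >= 1 else 0, 1 if g == 2 else 0)
        else:
            gt_arr[i] = g
    n_all = 1 + len(alts)
    if ad is None:
        ad = np.zeros((n, n_all))
        for i, g in enumerate(gt_arr):
            dos = (g == 1).sum() if (g != MISSING).all() else 0
            ad[i, 0] = 30 - 15 * dos
            if n_all > 1:
                ad[i, 1] = 15 * dos
    ad = np.asarray(ad, dtype=float)
    dp = np.asarray(dp if dp is not None else ad.sum(axis=1), dtype=float)
    gq = np.asarray(gq if gq is not None else [60.0] * n, dtype=float)
    n_geno = n_all * (n_all + 1) // 2
    if pl is None:
        pl = np.zeros((n, n_geno))
        for i, g in enumerate(gt_arr):
            dos = int((g == 1).sum()) if (g != MISSING).all() else 0
            if n_all == 2:
                pl[i] = [0 if d == dos else 100 for d in range(3)]
    pl = np.asarray(pl, dtype=float)
    return VariantRecord(chrom, pos, ref, tuple(alts), qual,
                         gt_arr, ad, dp, gq, pl)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
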