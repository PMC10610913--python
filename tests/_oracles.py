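"""Shared independent oracles and row factories for the test suite."""

import numpy as np


def brute_force_otsu_classification(values):
    """Oracle: exhaustive search over all cut points between sorted values,
    maximizing between-class variance on the raw (unbinned) sample.  Returns
    the boolean low-class membership of the sorted sample."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    best, best_cut = -np.inf, None
    for i in range(1, n):
        if x[i - 1] == x[i]:
            continue
        lo, hi = x[:i], x[i:]
        w0, w1 = len(lo) / n, len(hi) / n
        sb = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sb > best:
            best, best_cut = sb, (x[i - 1] + x[i]) / 2
    return x <= best_cut


def xlms_row(**kw):
    """A cross-link identification row passing every quality filter."""
    row = {
        "replicate": 1, "pep_a": "ACDEFGHK", "pep_b": "LMNPQRST",
        "res_a": 5, "res_b": 20, "score": 35.0, "mass_error": 0.0,
        "tic_pct": 15.0, "frags_a": 5, "frags_b": 5, "contig_a": 3, "contig_b": 3,
    }
    row.update(kw)
    return row
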