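"""Independent straight-line oracles shared by the test modules."""

import math

import numpy as np


def tmm_oracle_pair(obs, ref, logratio_trim=0.3, sum_trim=0.05):
    """Trimmed weighted mean of M-values for one library pair, written
    directly from the published formula (sort-based trimming, inverse
    asymptotic-variance weights)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep0 = (obs > 0) & (ref > 0)
    o, r = obs[keep0], ref[keep0]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(m)
    lo_m, hi_m = math.floor(n * logratio_trim) + 1, n - math.floor(n * logratio_trim)
    lo_a, hi_a = math.floor(n * sum_trim) + 1, n - math.floor(n * sum_trim)
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    return 2.0 ** f
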