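"""Independent high-precision evaluation of the four disproportionality
statistics, coded directly from their printed closed forms with mpmath.

Kept deliberately separate from the package implementation (no imports
from pvsignal) so it can serve as the oracle in equivalence tests.
"""

from __future__ import annotations

import mpmath as mp

mp.mp.dps = 50

Z = mp.mpf("1.96")


def ror_oracle(a, b, c, d):
    a, b, c, d = map(mp.mpf, (a, b, c, d))
    est = a * d / (b * c)
    se = mp.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, mp.e ** (mp.log(est) - Z * se), mp.e ** (mp.log(est) + Z * se)


def prr_oracle(a, b, c, d):
    a, b, c, d = map(mp.mpf, (a, b, c, d))
    return (a / (a + b)) / (c / (c + d))


def chi2_oracle(a, b, c, d):
    """Pearson chi-square via the textbook sum over (observed-expected)^2/E."""
    a, b, c, d = map(mp.mpf, (a, b, c, d))
    n = a + b + c + d
    total = mp.mpf(0)
    obs = [[a, b], [c, d]]
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            total += (obs[i][j] - e) ** 2 / e
    return total


def bcpnn_oracle(a, b, c, d, a1=1, b1=1, al=2, be=2, g11=1):
    a, b, c, d = map(mp.mpf, (a, b, c, d))
    a1, b1, al, be, g11 = map(mp.mpf, (a1, b1, al, be, g11))
    n = a + b + c + d
    gamma = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    e_ic = mp.log(
        (a + g11) * (n + al) * (n + be) / ((n + gamma) * (a + b + a1) * (a + c + b1)),
        2,
    )
    v_ic = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
        + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be))
    ) / mp.log(2) ** 2
    return e_ic, v_ic, e_ic - 2 * mp.sqrt(v_ic)


def mgps_oracle(a, b, c, d):
    a, b, c, d = map(mp.mpf, (a, b, c, d))
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    se = mp.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ebgm, mp.e ** (mp.log(ebgm) - Z * se)


def rel_err(x, y) -> float:
    y = mp.mpf(y)
    if y == 0:
        return float(abs(x - y))
    return float(abs((mp.mpf(x) - y) / y))


def max_rel_err_all_stats(impl_score, a, b, c, d) -> float:
    """Largest relative error across all eight statistics for one table,
    comparing a pvsignal SignalScore-like object with the oracle."""
    r, lo, hi = ror_oracle(a, b, c, d)
    e_ic, v_ic, ic025 = bcpnn_oracle(a, b, c, d)
    ebgm, ebgm05 = mgps_oracle(a, b, c, d)
    pairs = [
        (impl_score.ror, r),
        (impl_score.ror_lo, lo),
        (impl_score.ror_hi, hi),
        (impl_score.prr, prr_oracle(a, b, c, d)),
        (impl_score.chi2, chi2_oracle(a, b, c, d)),
        (impl_score.e_ic, e_ic),
        (impl_score.v_ic, v_ic),
        (impl_score.ic025, ic025),
        (impl_score.ebgm, ebgm),
        (impl_score.ebgm05, ebgm05),
    ]
    return max(rel_err(x, y) for x, y in pairs)
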