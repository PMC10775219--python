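"""Independent reference implementations used only to check the package.

These deliberately use the textbook closed forms (raw factorial sums,
M/M/1 algebra) rather than the package's numerically-stable recurrences,
so agreement is meaningful.
"""

import math


def erlang_c_direct(lam: float, mu: float, s: int) -> float:
    """Erlang-C by direct summation of the defining formula."""
    a = lam / mu
    rho = a / s
    if lam == 0:
        return 0.0
    assert rho < 1
    p0_inv = sum(a**k / math.factorial(k) for k in range(s))
    p0_inv += a**s / (math.factorial(s) * (1 - rho))
    return (a**s / (math.factorial(s) * (1 - rho))) / p0_inv


def mm1_wq(lam: float, mu: float) -> float:
    """M/M/1 expected queue wait: rho / (mu - lam)."""
    rho = lam / mu
    assert rho < 1
    return rho / (mu - lam)


def mms_wq_direct(lam: float, mu: float, s: int) -> float:
    """M/M/s expected queue wait from the direct Erlang-C sum."""
    return erlang_c_direct(lam, mu, s) / (s * mu - lam)
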