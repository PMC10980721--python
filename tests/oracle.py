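"""Independent brute-force oracle for the disproportionality statistics.

Deliberately naive: every quantity is a literal transcription of the
published 2x2-table formulas using only the ``math`` module, computed
step by step with no shared code with the package.  Used to cross-check
the implementation to 1e-10 relative error.
"""

import math

NAN = float("nan")


def ror_oracle(a, b, c, d):
    if a <= 0 or b <= 0 or c <= 0 or d <= 0:
        return NAN, NAN, NAN
    ror = (a / c) / (b / d)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lo = math.e ** (math.log(ror) - 1.96 * se)
    hi = math.e ** (math.log(ror) + 1.96 * se)
    return ror, lo, hi


def prr_oracle(a, b, c, d):
    if a <= 0 or c <= 0 or (a + b) <= 0 or (c + d) <= 0:
        return NAN, NAN, NAN
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    lo = math.e ** (math.log(prr) - 1.96 * se)
    hi = math.e ** (math.log(prr) + 1.96 * se)
    return prr, lo, hi


def chi2_yates_oracle(a, b, c, d):
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        return NAN
    diff = abs(a * d - b * c) - n / 2.0
    if diff < 0:
        diff = 0.0
    return n * diff * diff / denom


def chi2_uncorrected_oracle(a, b, c, d):
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        return NAN
    diff = a * d - b * c
    return n * diff * diff / denom


def bcpnn_oracle(a, b, c, d, gamma11=1.0, alpha1=1.0, beta1=1.0, alpha=2.0, beta=2.0):
    """Returns (ic, e_ic, v_ic, ic025, gamma)."""
    n = a + b + c + d
    if (a + b) <= 0 or (a + c) <= 0:
        return NAN, NAN, NAN, NAN, NAN
    ic = math.log2(a * n / ((a + b) * (a + c))) if a > 0 else NAN
    gamma = gamma11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
    e_ic = math.log2(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (a + b + alpha1) * (a + c + beta1))
    )
    term1 = ((n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma)))
    term2 = ((n - (a + b) + alpha - alpha1) / ((a + b + alpha1) * (1 + n + alpha)))
    term3 = ((n - (a + c) + beta - beta1) / ((a + c + beta1) * (1 + n + beta)))
    v_ic = (1.0 / (math.log(2) ** 2)) * (term1 + term2 + term3)
    ic025 = e_ic - 2.0 * math.sqrt(v_ic)
    return ic, e_ic, v_ic, ic025, gamma


def ebgm_oracle(a, b, c, d):
    n = a + b + c + d
    if a <= 0 or (a + b) <= 0 or (a + c) <= 0:
        return NAN, NAN, NAN
    ebgm = a * n / ((a + c) * (a + b))
    if b <= 0 or c <= 0 or d <= 0:
        return ebgm, NAN, NAN
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lo = math.e ** (math.log(ebgm) - 1.96 * se)
    hi = math.e ** (math.log(ebgm) + 1.96 * se)
    return ebgm, lo, hi


def contingency_oracle(report_events, cohort_ids):
    """Brute-force 2x2 cells by double loop over distinct (report, event) pairs.

    ``report_events``: mapping report id -> iterable of event labels
    (possibly repeated).  Returns {event: (a, b, c, d)} with unit-based
    margins.
    """
    pairs = set()
    for pid, events in report_events.items():
        for e in events:
            pairs.add((pid, e))
    all_events = sorted({e for _, e in pairs})
    total_cohort = sum(1 for pid, _ in pairs if pid in cohort_ids)
    total_other = len(pairs) - total_cohort
    out = {}
    for event in all_events:
        a = sum(1 for pid, e in pairs if e == event and pid in cohort_ids)
        c = sum(1 for pid, e in pairs if e == event and pid not in cohort_ids)
        out[event] = (a, total_cohort - a, c, total_other - c)
    return out
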