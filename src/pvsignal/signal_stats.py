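"""Disproportionality statistics for drug-event 2x2 tables.

Given the table

                 event   other events
    target drug    a          b
    other drugs    c          d          N = a+b+c+d

four frequentist and Bayesian measures of reporting disproportionality
are computed:

* **ROR** — reporting odds ratio ``ad/bc`` with the Wald interval
  ``exp(ln ROR +/- 1.96 * sqrt(1/a+1/b+1/c+1/d))``.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with
  ``SE(ln PRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))``, accompanied by
  a Pearson chi-squared statistic (Yates-corrected by default).
* **BCPNN IC** — information component ``log2[a N / ((a+b)(a+c))]``,
  with the shrinkage expectation E(IC) and variance V(IC) of the
  Bayesian confidence propagation neural network under Dirichlet priors
  (gamma11, alpha1, beta1, alpha, beta); the lower credibility bound is
  the 2-standard-deviation form ``IC025 = E(IC) - 2 sqrt(V(IC))``.
* **EBGM** — the closed-form empirical-Bayes geometric-mean relative
  reporting ratio ``a N / ((a+c)(a+b))`` with a log-scale Wald interval.
  (A full gamma-mixture MGPS fit is deliberately out of scope; the
  closed form is what this pipeline reports.)

Signal thresholds: ROR and PRR require a >= 3 and a lower 95% bound
above 1; BCPNN requires IC025 > 0; EBGM requires EBGM05 > 2.  Cells
that make an estimate undefined mark it non-computable (NaN, never a
continuity correction) and its flag false.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from pvsignal.contingency import ContingencyTable

Z95 = 1.96
NAN = float("nan")


@dataclass(frozen=True)
class BcpnnPriors:
    """Dirichlet hyperparameters of the BCPNN shrinkage model.

    Defaults (gamma11 = alpha1 = beta1 = 1, alpha = beta = 2) are the
    standard symmetric choice; gamma is derived from them so that the
    prior expectation of IC is 0.
    """

    gamma11: float = 1.0
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gamma11", "alpha1", "beta1", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def gamma(self, a: int, b: int, c: int, d: int) -> float:
        n = a + b + c + d
        return self.gamma11 * (n + self.alpha) * (n + self.beta) / (
            (a + b + self.alpha1) * (a + c + self.beta1)
        )


def _wald_ci(estimate: float, se: float) -> tuple[float, float]:
    if not math.isfinite(estimate) or estimate <= 0 or not math.isfinite(se):
        return (NAN, NAN)
    log_e = math.log(estimate)
    return (math.exp(log_e - Z95 * se), math.exp(log_e + Z95 * se))


def ror_stats(t: ContingencyTable) -> tuple[float, tuple[float, float]]:
    """Reporting odds ratio with its 95% Wald CI; NaN on any zero cell."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) <= 0:
        return (NAN, (NAN, NAN))
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, _wald_ci(ror, se))


def prr_stats(
    t: ContingencyTable, chi2_variant: Literal["yates", "uncorrected"] = "yates"
) -> tuple[float, tuple[float, float], float]:
    """Proportional reporting ratio, 95% CI and Pearson chi-squared.

    The Yates-corrected statistic ``N(|ad-bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))``
    is floored at 0 when ``|ad-bc| < N/2``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    chi2 = NAN
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom > 0:
        diff = abs(a * d - b * c)
        if chi2_variant == "yates":
            adj = max(diff - n / 2, 0.0)
            chi2 = n * adj * adj / denom
        elif chi2_variant == "uncorrected":
            chi2 = n * diff * diff / denom
        else:
            raise ValueError(f"unknown chi2 variant {chi2_variant!r}")
    if a <= 0 or c <= 0 or (a + b) <= 0 or (c + d) <= 0:
        return (NAN, (NAN, NAN), chi2)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return (prr, _wald_ci(prr, se), chi2)


def bcpnn_stats(
    t: ContingencyTable, priors: BcpnnPriors | None = None
) -> tuple[float, float, float, float]:
    """BCPNN information component: (IC, E(IC), V(IC), IC025).

    The observed IC is NaN when a = 0 (log of zero), but the shrunk
    moments E(IC)/V(IC) and the bound IC025 remain finite because the
    priors regularize the counts.
    """
    priors = priors or BcpnnPriors()
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    if (a + b) <= 0 or (a + c) <= 0:
        return (NAN, NAN, NAN, NAN)

    ic = math.log2(a * n / ((a + b) * (a + c))) if a > 0 and n > 0 else NAN

    g11, a1, b1, al, be = priors.gamma11, priors.alpha1, priors.beta1, priors.alpha, priors.beta
    gamma = priors.gamma(a, b, c, d)
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + gamma) * (a + b + a1) * (a + c + b1))
    )
    v_ic = (1 / math.log(2) ** 2) * (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
        + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be))
    )
    ic025 = e_ic - 2 * math.sqrt(v_ic) if v_ic >= 0 else NAN
    return (ic, e_ic, v_ic, ic025)


def ebgm_stats(t: ContingencyTable) -> tuple[float, tuple[float, float]]:
    """Closed-form EBGM ``aN/((a+c)(a+b))`` with a log-scale Wald CI.

    The point estimate only needs non-zero margins; the CI additionally
    needs all four cells positive (its SE term is the same as the ROR's).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    if (a + b) <= 0 or (a + c) <= 0 or a <= 0:
        return (NAN, (NAN, NAN))
    ebgm = a * n / ((a + c) * (a + b))
    if min(b, c, d) <= 0:
        return (ebgm, (NAN, NAN))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ebgm, _wald_ci(ebgm, se))


@dataclass
class SignalStats:
    """All four statistics plus threshold flags for one drug-event pair."""

    event_label: str
    level: str
    a: int
    b: int
    c: int
    d: int
    ror: float = NAN
    ror_lo: float = NAN
    ror_hi: float = NAN
    prr: float = NAN
    prr_lo: float = NAN
    prr_hi: float = NAN
    chi2: float = NAN
    ic: float = NAN
    e_ic: float = NAN
    v_ic: float = NAN
    ic025: float = NAN
    ebgm: float = NAN
    ebgm05: float = NAN
    ebgm95: float = NAN
    ror_flag: bool = False
    prr_flag: bool = False
    bcpnn_flag: bool = False
    ebgm_flag: bool = False
    combined_flag: bool = False

    @property
    def case_reports(self) -> int:
        return self.a


Policy = Literal["all", "any", "per-method"]


def evaluate_signal(s: SignalStats, policy: Policy = "all") -> SignalStats:
    """Apply the per-method thresholds and the combined signal policy.

    ROR/PRR: a >= 3 and CI lower bound > 1.  BCPNN: IC025 > 0.
    EBGM: EBGM05 > 2.  Non-computable (NaN) values never flag.
    ``policy`` controls the combined flag: ``all`` four methods must
    agree (default), ``any`` one suffices, ``per-method`` leaves the
    combined flag false so callers read the individual flags.
    """
    ror_flag = s.a >= 3 and not math.isnan(s.ror_lo) and s.ror_lo > 1
    prr_flag = s.a >= 3 and not math.isnan(s.prr_lo) and s.prr_lo > 1
    bcpnn_flag = not math.isnan(s.ic025) and s.ic025 > 0
    ebgm_flag = not math.isnan(s.ebgm05) and s.ebgm05 > 2
    if policy == "all":
        combined = ror_flag and prr_flag and bcpnn_flag and ebgm_flag
    elif policy == "any":
        combined = ror_flag or prr_flag or bcpnn_flag or ebgm_flag
    elif policy == "per-method":
        combined = False
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return replace(
        s,
        ror_flag=ror_flag,
        prr_flag=prr_flag,
        bcpnn_flag=bcpnn_flag,
        ebgm_flag=ebgm_flag,
        combined_flag=combined,
    )


def compute_signal_stats(
    t: ContingencyTable,
    priors: BcpnnPriors | None = None,
    chi2_variant: Literal["yates", "uncorrected"] = "yates",
    policy: Policy = "all",
) -> SignalStats:
    """Compute all four statistics and threshold flags for one table."""
    ror, (ror_lo, ror_hi) = ror_stats(t)
    prr, (prr_lo, prr_hi), chi2 = prr_stats(t, chi2_variant)
    ic, e_ic, v_ic, ic025 = bcpnn_stats(t, priors)
    ebgm, (ebgm05, ebgm95) = ebgm_stats(t)
    s = SignalStats(
        event_label=t.event_label,
        level=t.level,
        a=t.a,
        b=t.b,
        c=t.c,
        d=t.d,
        ror=ror,
        ror_lo=ror_lo,
        ror_hi=ror_hi,
        prr=prr,
        prr_lo=prr_lo,
        prr_hi=prr_hi,
        chi2=chi2,
        ic=ic,
        e_ic=e_ic,
        v_ic=v_ic,
        ic025=ic025,
        ebgm=ebgm,
        ebgm05=ebgm05,
        ebgm95=ebgm95,
    )
    return evaluate_signal(s, policy)


def rank_results(
    results: list[SignalStats],
    by: Literal["case_reports", "ebgm"] = "case_reports",
    top_n: int | None = None,
) -> list[SignalStats]:
    """Stable descending sort; ties broken by (a desc, label asc)."""
    if by == "case_reports":
        key = lambda s: (-s.a, s.event_label)
    elif by == "ebgm":
        # NaN EBGM sorts last
        key = lambda s: (math.isnan(s.ebgm), -(s.ebgm if not math.isnan(s.ebgm) else 0.0), -s.a, s.event_label)
    else:
        raise ValueError(f"unknown ranking key {by!r}")
    ordered = sorted(results, key=key)
    if top_n is not None:
        if top_n <= 0:
            return []
        ordered = ordered[:top_n]
    return ordered


__all__ = [
    "BcpnnPriors",
    "SignalStats",
    "bcpnn_stats",
    "compute_signal_stats",
    "ebgm_stats",
    "evaluate_signal",
    "prr_stats",
    "rank_results",
    "ror_stats",
]
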