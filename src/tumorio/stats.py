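"""Trial statistics: confusion tables, accuracy, odds ratios, and exact
binomial (Clopper-Pearson) confidence intervals.

The contingency table is oriented predicted x clinical::

                    clinical pCR    clinical residual
    predicted pCR        TP               FP
    predicted residual   FN               TN

The odds ratio is OR = (TP*TN)/(FP*FN) with the usual log-normal 95% CI
exp(ln OR +/- z * sqrt(1/TP + 1/FP + 1/FN + 1/TN)).  Clopper-Pearson
intervals come from the Beta-quantile characterization of the exact
binomial test and are conservative (coverage >= nominal for every p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as spstats

__all__ = [
    "PCR",
    "RESIDUAL",
    "ContingencyTable",
    "ProportionCI",
    "OddsRatioResult",
    "confusion",
    "accuracy",
    "odds_ratio",
    "clopper_pearson_ci",
    "response_rate",
]

PCR = "pCR"
RESIDUAL = "residual"


def _canon(call: str) -> str:
    c = str(call).strip().lower()
    if c in {"pcr", "1", "true", "yes"}:
        return PCR
    if c in {"residual", "residual disease", "rd", "0", "false", "no"}:
        return RESIDUAL
    raise ValueError(f"unrecognized outcome call {call!r}")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of predicted vs clinical pCR calls."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion k/n with an exact confidence interval."""

    k: int
    n: int
    level: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n or self.n <= 0:
            raise ValueError(f"invalid counts k={self.k}, n={self.n}")
        if not (0.0 <= self.lo <= self.k / self.n <= self.hi <= 1.0):
            raise ValueError("CI must bracket the point estimate within [0, 1]")

    @property
    def estimate(self) -> float:
        return self.k / self.n

    def as_percent(self, decimals: int = 1) -> str:
        """Render like ``67.1% (59.2-74.3)`` (Table-style, one decimal)."""
        f = f"{{:.{decimals}f}}"
        return (
            f"{f.format(100 * self.estimate)}% "
            f"({f.format(100 * self.lo)}–{f.format(100 * self.hi)})"
        )


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    lo: float
    hi: float
    level: float = 0.95


def confusion(
    predictions: Sequence[str], truths: Sequence[str]
) -> ContingencyTable:
    """Tally predicted vs clinical calls into a 2x2 table."""
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    pred = [_canon(p) for p in predictions]
    true = [_canon(t) for t in truths]
    tp = sum(p == PCR and t == PCR for p, t in zip(pred, true))
    fp = sum(p == PCR and t == RESIDUAL for p, t in zip(pred, true))
    fn = sum(p == RESIDUAL and t == PCR for p, t in zip(pred, true))
    tn = sum(p == RESIDUAL and t == RESIDUAL for p, t in zip(pred, true))
    return ContingencyTable(TP=tp, FP=fp, FN=fn, TN=tn)


def accuracy(ct: ContingencyTable) -> float:
    """Percent of concordant calls, 100 * (TP + TN) / total."""
    return 100.0 * (ct.TP + ct.TN) / ct.total


def odds_ratio(
    ct: ContingencyTable, level: float = 0.95, haldane: bool = False
) -> OddsRatioResult:
    """Odds ratio (TP*TN)/(FP*FN) with a log-normal confidence interval.

    A zero cell leaves the OR undefined and raises; pass ``haldane=True``
    to apply the Haldane-Anscombe +0.5 correction to every cell instead.
    """
    cells = np.array([ct.TP, ct.FP, ct.FN, ct.TN], dtype=float)
    if (cells == 0).any():
        if not haldane:
            raise ZeroDivisionError(
                "odds ratio undefined with a zero cell; "
                "pass haldane=True for the +0.5 correction"
            )
        cells = cells + 0.5
    tp, fp, fn, tn = cells
    orr = (tp * tn) / (fp * fn)
    z = spstats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt((1 / cells).sum())
    return OddsRatioResult(
        oddsratio=float(orr),
        lo=float(np.exp(np.log(orr) - half)),
        hi=float(np.exp(np.log(orr) + half)),
        level=level,
    )


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact binomial confidence interval for k successes in n trials.

    lo = Beta(alpha/2; k, n-k+1) quantile (0 when k = 0) and
    hi = Beta(1-alpha/2; k+1, n-k) quantile (1 when k = n).
    """
    if n <= 0 or not 0 <= k <= n or k != int(k) or n != int(n):
        raise ValueError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(spstats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(spstats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(k=int(k), n=int(n), level=level, lo=lo, hi=hi)


def response_rate(calls: Sequence[str], level: float = 0.95) -> ProportionCI:
    """pCR rate among a vector of calls, with its Clopper-Pearson CI."""
    if len(calls) == 0:
        raise ValueError("empty call vector")
    k = sum(_canon(c) == PCR for c in calls)
    return clopper_pearson_ci(k, len(calls), level=level)
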