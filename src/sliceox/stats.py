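"""Paired nonparametric inference and summary statistics.

Repeated-measures comparisons (the same slice recorded under control and
treatment) are tested with the Wilcoxon signed-rank test; because the design
compares each treatment level against control only, raw p-values are
Bonferroni-adjusted for the number of such comparisons.  Group values are
summarized as median (25th, 75th percentile) since the underlying quantities
are not normally distributed.

The exact null distribution of the signed-rank statistic is computed by a
characteristic-polynomial convolution over all 2^n sign assignments (zeros
dropped per Wilcoxon's convention, ties given average ranks via doubled-rank
integers); above n = 25 a normal approximation with tie correction is used
and labeled as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm, rankdata

from .diffusion import ValidationError

__all__ = [
    "PairedComparison",
    "DegenerateDataError",
    "wilcoxon_signed_rank",
    "bonferroni_adjust",
    "summarize_median_iqr",
]

#: largest n for which the exact enumeration null is used by default
EXACT_N_MAX = 25


class DegenerateDataError(ValidationError):
    """All paired differences are zero — no signed-rank test is possible."""


@dataclass
class PairedComparison:
    """Result of one paired signed-rank comparison."""

    labels: tuple[str, str]
    differences: np.ndarray
    statistic: float  # W = min(W+, W-)
    w_plus: float
    w_minus: float
    n_nonzero: int
    p_raw: float
    p_adjusted: float
    method: str  # "exact" | "normal-approximation"
    m_comparisons: int = 1

    def adjusted(self, m: int) -> "PairedComparison":
        """Return a copy with a Bonferroni adjustment for ``m`` comparisons."""
        return PairedComparison(
            labels=self.labels,
            differences=self.differences,
            statistic=self.statistic,
            w_plus=self.w_plus,
            w_minus=self.w_minus,
            n_nonzero=self.n_nonzero,
            p_raw=self.p_raw,
            p_adjusted=bonferroni_adjust(self.p_raw, m),
            method=self.method,
            m_comparisons=m,
        )

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "n_nonzero": self.n_nonzero,
            "W": self.statistic,
            "w_plus": self.w_plus,
            "w_minus": self.w_minus,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "method": self.method,
            "m_comparisons": self.m_comparisons,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict())
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _exact_two_sided_p(doubled_ranks: np.ndarray, w_plus2: int, w_minus2: int) -> float:
    """P(min(W+, W-) <= min(w+, w-)) over all 2^n equiprobable sign patterns.

    Works on doubled (integer) ranks so that average ranks from ties stay
    exact.  The distribution of 2W+ is built by convolving the polynomial
    prod_i (1 + x^{2 r_i}).
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    m = min(w_plus2, w_minus2)
    n_assignments = counts.sum()  # 2^n
    if 2 * m >= total:
        return 1.0
    lower = counts[: m + 1].sum()  # P(2W+ <= 2m)
    upper = counts[total - m :].sum()  # P(2W+ >= total - 2m) = P(2W- <= 2m)
    return float((lower + upper) / n_assignments)


def wilcoxon_signed_rank(
    differences,
    labels: tuple[str, str] = ("a", "b"),
    method: str = "auto",
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's convention) and tied magnitudes
    receive average ranks.  With ``method="auto"`` the exact null (complete
    enumeration of sign assignments) is used for n <= 25 nonzero differences
    and a tie-corrected normal approximation above; ``"exact"`` or
    ``"approx"`` force either mode.  The two-sided p-value is the null
    probability that min(W+, W-) is at most its observed value.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValidationError("no differences supplied")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)

    if method not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_N_MAX)

    if use_exact:
        doubled = np.rint(2.0 * ranks).astype(int)
        p = _exact_two_sided_p(doubled, int(round(2 * w_plus)), int(round(2 * w_minus)))
        used = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        if var <= 0:
            raise DegenerateDataError("zero variance after tie correction")
        # continuity-corrected two-sided normal approximation on W+
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        used = "normal-approximation"

    return PairedComparison(
        labels=labels,
        differences=d,
        statistic=statistic,
        w_plus=w_plus,
        w_minus=w_minus,
        n_nonzero=n,
        p_raw=p,
        p_adjusted=p,
        method=used,
        m_comparisons=1,
    )


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """Bonferroni adjustment: ``min(1, m * p)``."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValidationError(f"p-value must lie in [0, 1], got {p_raw!r}")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return min(1.0, m * p_raw)


def summarize_median_iqr(values) -> dict:
    """Median and quartiles (linear interpolation between order statistics).

    Returns ``{"median", "q25", "q75", "n"}``.  The quantile definition is
    fixed to linear interpolation and recorded here so summaries are
    reproducible across software.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return {"median": float(med), "q25": float(q25), "q75": float(q75), "n": int(v.size)}
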