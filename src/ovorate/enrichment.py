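"""One-tailed chi-square enrichment of positive selection in a gene set.

A set of n genes with k positive-selection calls on a branch is compared
to the genome-wide proportion p0 for that branch by a Pearson goodness-
of-fit test on the 2-cell table (k, n - k) vs (n p0, n (1 - p0)).  The
one-tailed P halves the two-sided chi^2(1) upper tail when the deviation
is in the enrichment direction (k >= n p0) and is 1 minus the half-tail
otherwise.  The Yates continuity correction (subtract 0.5 from |O - E|
before squaring) is available because published one-tailed values from
small tables reproduce with it while large-table values reproduce
without; the default is uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

__all__ = ["EnrichmentResult", "chi_square_enrichment"]


@dataclass
class EnrichmentResult:
    observed_k: int
    n: int
    p0: float
    chi2: float
    p_one_tailed: float
    yates: bool
    enriched_direction: bool

    def summary(self) -> str:
        return (
            f"chi-square GOF: k={self.observed_k}/{self.n} vs p0={self.p0:g} "
            f"({'Yates' if self.yates else 'uncorrected'})\n"
            f"chi2 = {self.chi2:.4f}, one-tailed P = {self.p_one_tailed:.4g}"
        )


def chi_square_enrichment(
    observed_k: int, n: int, p0: float, yates: bool = False
) -> EnrichmentResult:
    """One-tailed chi-square goodness-of-fit of k/n against proportion p0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    if not (0 <= observed_k <= n):
        raise ValueError("observed_k must be between 0 and n")
    expected = (n * p0, n * (1.0 - p0))
    observed = (observed_k, n - observed_k)
    stat = 0.0
    for o, e in zip(observed, expected):
        dev = abs(o - e)
        if yates:
            dev = max(dev - 0.5, 0.0)
        stat += dev * dev / e
    half_tail = 0.5 * float(chi2.sf(stat, df=1))
    enriched = observed_k >= n * p0
    p = half_tail if enriched else 1.0 - half_tail
    return EnrichmentResult(observed_k, n, p0, float(stat), p, yates, enriched)
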