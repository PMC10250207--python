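"""Clonality QC from the shape of the detected-VAF spectrum.

In a clonal line every founder mutation sits on one haplotype, so true VAF
is ~50% on autosomes; in a line grown from two or more cells most mutations
are private to one founder and sit below 50%.  Precise VAFs cannot be read
off shallow (5x) data, but detection is biased towards high-frequency
mutations, so the *ratio* of detected calls measured above vs below 50% VAF
separates clonal from nonclonal lines: ratios above 3 indicate a clonal
line, below 2 a nonclonal line, and 2-3 are inconclusive.

This QC must run on raw calls, before the 30%-VAF postfilter: the filter
would delete exactly the low-VAF counts the ratio needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .io_model import MutationCall

CLONAL = "clonal"
NONCLONAL = "nonclonal"
INCONCLUSIVE = "inconclusive"
NO_DATA = "no_data"

#: Ratio above which a line is considered clonal.
CLONAL_THRESHOLD = 3.0
#: Ratio below which a line is considered nonclonal.
NONCLONAL_THRESHOLD = 2.0


@dataclass(frozen=True)
class ClonalityReport:
    sample: str
    n_high: int    # calls with measured VAF > 0.5
    n_low: int     # calls with measured VAF < 0.5
    n_tie: int     # VAF exactly 0.5 (excluded from the ratio)
    ratio: float | None  # +inf when n_low == 0 < n_high; None when both 0
    verdict: str


def classify_clonality(ratio: float | None) -> str:
    """Map a high/low-VAF ratio to a clonality verdict."""
    if ratio is None:
        return INCONCLUSIVE
    if ratio < 0:
        raise ValueError("ratio must be >= 0 or +inf")
    if ratio > CLONAL_THRESHOLD:
        return CLONAL
    if ratio < NONCLONAL_THRESHOLD:
        return NONCLONAL
    return INCONCLUSIVE


def vaf_ratio(calls: Iterable[MutationCall], sample: str | None = None) -> ClonalityReport:
    """Count high- vs low-VAF detected calls and classify clonality.

    Inequalities are strict: calls at exactly 50% measured VAF are ties
    and enter neither count.  Input must be raw (pre-postfilter) calls.
    """
    calls = list(calls)
    if sample is None:
        sample = calls[0].sample if calls else ""
    if not calls:
        return ClonalityReport(sample, 0, 0, 0, None, NO_DATA)
    n_high = sum(1 for c in calls if c.vaf > 0.5)
    n_low = sum(1 for c in calls if c.vaf < 0.5)
    n_tie = len(calls) - n_high - n_low
    if n_high == 0 and n_low == 0:
        return ClonalityReport(sample, 0, 0, n_tie, None, INCONCLUSIVE)
    ratio = math.inf if n_low == 0 else n_high / n_low
    return ClonalityReport(sample, n_high, n_low, n_tie, ratio, classify_clonality(ratio))


def write_reports(reports: Iterable[ClonalityReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tn_high\tn_low\tn_tie\tratio\tverdict\n")
        for r in reports:
            ratio = "NA" if r.ratio is None else ("inf" if math.isinf(r.ratio) else f"{r.ratio:.4f}")
            fh.write(f"{r.sample}\t{r.n_high}\t{r.n_low}\t{r.n_tie}\t{ratio}\t{r.verdict}\n")
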