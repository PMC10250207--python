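"""Count-level sequencing operations and the pairwise caller contract.

A :class:`SiteCounts` object holds per-site (depth, alt-read) counts for one
sample and is the unit of merging: summing the counts of redundant shallow
lines is what turns a cluster of 5x genomes into one >=15x genome for the
corresponding lineage.  ``call_pair`` is an explicit, reproducible stand-in
for a tumor/normal consensus caller: case support, clean control, adequate
control depth, accessible site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_model import INDEL, GenomeMask, GenomicSite, MutationCall

logger = logging.getLogger(__name__)

COUNTS_HEADER = "#sample\tchrom\tpos\tref\talt\tdepth\talt_count"


@dataclass
class SiteCounts:
    """Per-site (depth, alt_count) counts for one sample; summable."""

    sample: str
    counts: dict[GenomicSite, tuple[int, int]]
    mean_coverage: float
    role: str = "case"

    def __post_init__(self) -> None:
        for site, (depth, alt) in self.counts.items():
            if not (0 <= alt <= depth):
                raise ValueError(
                    f"{self.sample}: alt_count {alt} > depth {depth} at "
                    f"{site.chrom}:{site.pos}"
                )

    def depth(self, site: GenomicSite) -> int:
        return self.counts.get(site, (0, 0))[0]

    def alt(self, site: GenomicSite) -> int:
        return self.counts.get(site, (0, 0))[1]

    def sites(self) -> list[GenomicSite]:
        return sorted(self.counts)


@dataclass
class CallerParams:
    """Thresholds of the pairwise caller and post-call filters.

    ``min_alt_reads=3`` (case support), ``max_control_alt=0`` with
    ``min_control_depth=6`` (control must be clean *and* covered, so
    germline alleles cannot leak through control dropout at shallow
    coverage), ``min_vaf_postfilter=0.30`` (removes culture-acquired
    low-frequency mutations), ``max_indel_len=9`` (only indels <10 bp).
    """

    min_alt_reads: int = 3
    max_control_alt: int = 0
    min_control_depth: int = 6
    min_vaf_postfilter: float = 0.30
    max_indel_len: int = 9
    mask: GenomeMask | None = None

    def __post_init__(self) -> None:
        for name in ("min_alt_reads", "max_control_alt", "min_control_depth", "max_indel_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.min_vaf_postfilter <= 1:
            raise ValueError("min_vaf_postfilter must be in [0, 1]")


def downsample_counts(counts: SiteCounts, target_cov: float, seed: int) -> SiteCounts:
    """Thin counts to a lower target coverage (read-level emulation).

    Each read is kept independently with probability
    ``p = target_cov / mean_coverage``: depth is binomially thinned and the
    surviving alt reads are a hypergeometric draw from the kept reads.
    Deterministic under ``seed``.  Upsampling is refused.
    """
    if counts.mean_coverage <= 0:
        raise ValueError("cannot downsample counts with mean_coverage <= 0")
    if target_cov > counts.mean_coverage:
        raise ValueError(
            f"target coverage {target_cov} exceeds mean coverage "
            f"{counts.mean_coverage}; upsampling is not possible"
        )
    p = target_cov / counts.mean_coverage
    rng = np.random.default_rng(seed)
    sites = counts.sites()
    depth = np.array([counts.counts[s][0] for s in sites], dtype=np.int64)
    alt = np.array([counts.counts[s][1] for s in sites], dtype=np.int64)
    new_depth = rng.binomial(depth, p)
    new_alt = np.zeros_like(new_depth)
    nonzero = new_depth > 0
    new_alt[nonzero] = rng.hypergeometric(
        alt[nonzero], depth[nonzero] - alt[nonzero], new_depth[nonzero]
    )
    return SiteCounts(
        sample=counts.sample,
        counts={s: (int(d), int(a)) for s, d, a in zip(sites, new_depth, new_alt)},
        mean_coverage=target_cov,
        role=counts.role,
    )


def sum_counts(many: Sequence[SiteCounts]) -> SiteCounts:
    """Sitewise sum of several samples' counts ('sum all' merging)."""
    if not many:
        raise ValueError("sum_counts requires at least one input")
    ids = [c.sample for c in many]
    if len(ids) != len(set(ids)):
        logger.warning("sum_counts: duplicate sample ids in input: %s", ids)
    total: dict[GenomicSite, tuple[int, int]] = {}
    for sc in many:
        for site, (d, a) in sc.counts.items():
            d0, a0 = total.get(site, (0, 0))
            total[site] = (d0 + d, a0 + a)
    return SiteCounts(
        sample="+".join(ids),
        counts=total,
        mean_coverage=float(sum(c.mean_coverage for c in many)),
    )


def build_pseudobulk(lines: Sequence[SiteCounts], sample: str = "pseudobulk") -> SiteCounts:
    """Build a control from designated clones when no true bulk exists.

    Same arithmetic as :func:`sum_counts`; the result is tagged
    ``role='control'``.  Choosing clones outside the lineages under study is
    the caller's responsibility.
    """
    if not lines:
        raise ValueError("pseudo-bulk requires at least one clone")
    merged = sum_counts(lines)
    return replace(merged, sample=sample, role="control")


def call_pair(
    case: SiteCounts, control: SiteCounts, params: CallerParams
) -> list[MutationCall]:
    """Call somatic variants in ``case`` against ``control``.

    A site is emitted iff case alt >= ``min_alt_reads``, control alt <=
    ``max_control_alt``, control depth >= ``min_control_depth`` and the site
    lies in the accessibility mask (no mask = everything accessible).
    VAF is taken from the case counts.
    """
    calls: list[MutationCall] = []
    mask = params.mask
    for site in case.sites():
        d, a = case.counts[site]
        if a < params.min_alt_reads:
            continue
        cd, ca = control.counts.get(site, (0, 0))
        if cd < params.min_control_depth or ca > params.max_control_alt:
            continue
        if mask is not None and site not in mask:
            continue
        calls.append(MutationCall.from_counts(site, case.sample, a, d))
    return calls


def postfilter(calls: Iterable[MutationCall], params: CallerParams) -> list[MutationCall]:
    """Keep calls with VAF >= threshold and indels shorter than 10 bp."""
    kept = []
    for c in calls:
        if c.vaf < params.min_vaf_postfilter:
            continue
        if c.vclass == INDEL and c.indel_len > params.max_indel_len:
            continue
        kept.append(c)
    return kept


def write_counts(counts: SiteCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(COUNTS_HEADER + "\n")
        for site in counts.sites():
            d, a = counts.counts[site]
            fh.write(f"{counts.sample}\t{site.chrom}\t{site.pos}\t{site.ref}"
                     f"\t{site.alt}\t{d}\t{a}\n")


def read_counts(path: str | Path, mean_coverage: float = 0.0) -> list[SiteCounts]:
    """Read one or more samples' counts from the counts TSV dialect."""
    per_sample: dict[str, dict[GenomicSite, tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            sample, chrom, pos, ref, alt, depth, alt_count = fields[:7]
            site = GenomicSite(chrom, int(pos), ref.upper(), alt.upper()).validate()
            per_sample.setdefault(sample, {})[site] = (int(depth), int(alt_count))
    out = []
    for sample, counts in per_sample.items():
        mc = mean_coverage or (
            float(np.mean([d for d, _ in counts.values()])) if counts else 0.0
        )
        out.append(SiteCounts(sample=sample, counts=counts, mean_coverage=mc))
    return out
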