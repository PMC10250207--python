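"""Exhaustive pairwise comparison and mosaic/germline scoring of variants.

Every analysis unit (a merged cluster or a single high-coverage line) is
compared against every other unit, once as case and once as control:
N units yield N(N-1) ordered comparisons.  For a genuine mosaic mutation
there exist two complementary unit sets, the carriers A and the
non-carriers B, such that the mutation is called consistently whenever a
member of A is the case and a member of B is the control.  The pattern of
calls is condensed into two scores:

* mosaic score ``M`` - fraction of the |A|*|B| ordered (carrier, non-carrier)
  comparisons in which the variant was actually called; 1 means a clean
  bipartition.
* germline score ``G`` - fraction of the called comparisons whose control
  unit itself has read support for the allele; calls made against controls
  that carry the allele are the signature of a germline variant leaking
  through control dropout.

These definitions are this package's concrete, testable reconstruction of
pattern-based pairwise filtering; they are deliberately unweighted (no
coverage weighting of pairs).  Thresholds are configurable and calibrated
on the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .counts_calls import CallerParams, SiteCounts
from .io_model import INDEL, GenomicSite

MOSAIC = "mosaic"
HIGH_FREQ_MOSAIC = "high_freq_mosaic"
GERMLINE = "germline"
FALSE_POSITIVE = "false_positive"


@dataclass
class ScoreThresholds:
    """Classification thresholds: germline iff G > g_max, else mosaic iff
    M >= m_min; mosaic variants carried by >= hf_fraction of units are
    flagged high-frequency (early-development mutations resembling
    germline variants)."""

    m_min: float = 0.8
    g_max: float = 0.2
    hf_fraction: float = 0.75


@dataclass
class PairwiseCallTable:
    """Per-variant call pattern over all ordered (case, control) pairs."""

    unit_ids: list[str]
    called_pairs: dict[GenomicSite, frozenset[tuple[int, int]]]
    support: dict[GenomicSite, frozenset[int]]  # units with >= 1 alt read

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def variants(self) -> list[GenomicSite]:
        return sorted(self.called_pairs)


@dataclass
class VariantScore:
    site: GenomicSite
    carriers: frozenset[str]  # set A, by unit id
    n_units: int
    mosaic_score: float
    germline_score: float
    vclass: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.mosaic_score <= 1 or not 0 <= self.germline_score <= 1:
            raise ValueError("scores must lie in [0, 1]")


def build_pair_table(
    units: Sequence[SiteCounts],
    params: CallerParams,
    restrict_sites: Iterable[GenomicSite] | None = None,
    apply_postfilter: bool = True,
) -> PairwiseCallTable:
    """Run the pairwise caller for every ordered pair of units.

    With ``restrict_sites`` the comparison is confined to a candidate list
    (e.g. germline-like variants heterogeneous across units), reducing the
    N(N-1) comparisons to the sites that can matter.  When
    ``apply_postfilter`` is set, each pairwise call must additionally pass
    the VAF/indel-length post-filters (the default pipeline behaviour).
    """
    n = len(units)
    if n < 2:
        raise ValueError("pairwise comparison needs at least two units")
    ids = [u.sample for u in units]
    if len(set(ids)) != n:
        raise ValueError("unit ids must be unique")

    site_set: set[GenomicSite] = set()
    for u in units:
        site_set.update(u.counts)
    if restrict_sites is not None:
        site_set &= set(restrict_sites)
    sites = sorted(site_set)
    if not sites:
        return PairwiseCallTable(unit_ids=ids, called_pairs={}, support={})

    depth = np.zeros((n, len(sites)), dtype=np.int64)
    alt = np.zeros_like(depth)
    for ui, u in enumerate(units):
        for si, s in enumerate(sites):
            d, a = u.counts.get(s, (0, 0))
            depth[ui, si] = d
            alt[ui, si] = a

    accessible = np.ones(len(sites), dtype=bool)
    if params.mask is not None:
        accessible = np.array([s in params.mask for s in sites])
    indel_ok = np.array(
        [s.vclass != INDEL or s.indel_len <= params.max_indel_len for s in sites]
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    case_ok = (alt >= params.min_alt_reads) & accessible[None, :]
    if apply_postfilter:
        case_ok &= (vaf >= params.min_vaf_postfilter) & indel_ok[None, :]
    ctrl_ok = (depth >= params.min_control_depth) & (alt <= params.max_control_alt)

    called: dict[GenomicSite, set[tuple[int, int]]] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            hit = case_ok[i] & ctrl_ok[j]
            for si in np.nonzero(hit)[0]:
                called.setdefault(sites[si], set()).add((i, j))
    support = {
        s: frozenset(np.nonzero(alt[:, si] >= 1)[0].tolist())
        for si, s in enumerate(sites)
        if s in called
    }
    return PairwiseCallTable(
        unit_ids=ids,
        called_pairs={s: frozenset(p) for s, p in called.items()},
        support=support,
    )


def score_variant(table: PairwiseCallTable, site: GenomicSite) -> VariantScore:
    """Compute mosaic and germline scores from a variant's call pattern.

    A = units called as case in at least one pair; B = complement.
    ``M = #called (i in A, j in B) / (|A|*|B|)`` (0 if either side is
    empty, so a variant carried by every unit is decided purely by G);
    ``G = #called pairs whose control has read support / #called pairs``.
    """
    pairs = table.called_pairs.get(site)
    if pairs is None:
        raise KeyError(f"variant {site} not in table")
    n = table.n_units
    a_idx = frozenset(i for i, _ in pairs)
    b_idx = frozenset(range(n)) - a_idx
    if a_idx and b_idx:
        n_ab = sum(1 for i, j in pairs if i in a_idx and j in b_idx)
        mosaic = n_ab / (len(a_idx) * len(b_idx))
    else:
        mosaic = 0.0
    supported = table.support.get(site, frozenset())
    germ = (
        sum(1 for _, j in pairs if j in supported) / len(pairs) if pairs else 0.0
    )
    return VariantScore(
        site=site,
        carriers=frozenset(table.unit_ids[i] for i in a_idx),
        n_units=n,
        mosaic_score=mosaic,
        germline_score=germ,
        vclass=site.vclass,
    )


def score_all(table: PairwiseCallTable) -> list[VariantScore]:
    return [score_variant(table, s) for s in table.variants()]


def classify_variants(
    scores: Iterable[VariantScore], thresholds: ScoreThresholds | None = None
) -> list[VariantScore]:
    """Label each variant mosaic / high-frequency mosaic / germline / false
    positive from its (M, G) scores and carrier fraction."""
    th = thresholds or ScoreThresholds()
    out = []
    for sc in scores:
        if sc.germline_score > th.g_max:
            label = GERMLINE
        elif sc.mosaic_score >= th.m_min:
            if sc.n_units and len(sc.carriers) / sc.n_units >= th.hf_fraction:
                label = HIGH_FREQ_MOSAIC
            else:
                label = MOSAIC
        else:
            label = FALSE_POSITIVE
        sc.label = label
        out.append(sc)
    return out


def sharing_sets(
    classified: Iterable[VariantScore],
) -> dict[GenomicSite, frozenset[str]]:
    """Carrier sets of mosaic-class variants: the input to tree building."""
    return {
        sc.site: sc.carriers
        for sc in classified
        if sc.label in (MOSAIC, HIGH_FREQ_MOSAIC)
    }


def write_scores(scores: Iterable[VariantScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tA_size\tM\tG\tclass\tcarriers\n")
        for sc in sorted(scores, key=lambda s: s.site):
            s = sc.site
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{len(sc.carriers)}"
                f"\t{sc.mosaic_score:.4f}\t{sc.germline_score:.4f}\t{sc.label}"
                f"\t{','.join(sorted(sc.carriers))}\n"
            )


def write_score_scatter(scores: Iterable[VariantScore], path) -> None:
    """CSV of (M, G, class) rows for score-scatter figures."""
    with open(path, "w") as fh:
        fh.write("mosaic_score,germline_score,class\n")
        for sc in scores:
            fh.write(f"{sc.mosaic_score:.4f},{sc.germline_score:.4f},{sc.label}\n")
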