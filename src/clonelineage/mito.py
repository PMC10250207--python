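"""Mitochondrial track: heterogeneity filtering and VAF-correlation
clustering.

Mitochondria are present in hundreds of copies per cell and segregate
stochastically, so heteroplasmic variants drift in frequency between cell
progenies and can disappear altogether.  Presence/absence is therefore an
unreliable lineage character; instead lines are clustered on the VAF
vectors of mitochondrial variants.  Two steps:

1. per-site Pearson chi-square test of ref/alt read-count independence
   across samples (Benjamini-Hochberg corrected) retains variants whose
   frequency is genuinely heterogeneous across lines rather than a uniform
   low-frequency artifact;
2. samples are clustered with the distance 1 - rho (Pearson correlation of
   VAFs over retained sites), reusing the Ward machinery of the nuclear
   track.  The distance range [0, 2] is kept as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .clustering import ClusterAssignment, DistanceMatrix, cut_clusters, ward_cluster
from .io_model import GenomicSite

logger = logging.getLogger(__name__)


@dataclass
class MitoVafMatrix:
    """Samples x mito-sites VAF matrix with the underlying read counts.

    ``vaf[i, k]`` is alt/(ref+alt) for sample i at site k, NaN where the
    site has no coverage in that sample (missing, not zero).
    """

    samples: list[str]
    sites: list[GenomicSite]
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    vaf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        shape = (len(self.samples), len(self.sites))
        self.ref_counts = np.asarray(self.ref_counts, dtype=float)
        self.alt_counts = np.asarray(self.alt_counts, dtype=float)
        if self.ref_counts.shape != shape or self.alt_counts.shape != shape:
            raise ValueError(f"count matrices must have shape {shape}")
        total = self.ref_counts + self.alt_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            self.vaf = np.where(total > 0, self.alt_counts / np.maximum(total, 1), np.nan)

    def select_sites(self, keep: Sequence[int]) -> "MitoVafMatrix":
        keep = list(keep)
        return MitoVafMatrix(
            samples=self.samples,
            sites=[self.sites[k] for k in keep],
            ref_counts=self.ref_counts[:, keep],
            alt_counts=self.alt_counts[:, keep],
        )


@dataclass
class HeterogeneityResult:
    sites: list[GenomicSite]
    chi2: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    degenerate: np.ndarray  # True where the 2xS table collapsed
    retained: np.ndarray    # q < alpha

    def retained_indices(self) -> list[int]:
        return [int(i) for i in np.nonzero(self.retained)[0]]


def chi2_heterogeneity(matrix: MitoVafMatrix, alpha: float = 0.05) -> HeterogeneityResult:
    """Test each site for heterogeneous allele frequency across samples.

    Pearson chi-square of independence on the 2 x S ref/alt table (no
    continuity correction), restricted to samples with coverage at the
    site; degenerate tables (all-zero row/column, or fewer than two
    covered samples) get p = 1 with a flag.  P-values are BH-adjusted
    across sites; a site is retained iff q < ``alpha``.
    """
    n_sites = len(matrix.sites)
    chi2 = np.zeros(n_sites)
    pvals = np.ones(n_sites)
    degenerate = np.zeros(n_sites, dtype=bool)
    for k in range(n_sites):
        ref = matrix.ref_counts[:, k]
        alt = matrix.alt_counts[:, k]
        covered = (ref + alt) > 0
        if covered.sum() < 2:
            degenerate[k] = True
            continue
        table = np.vstack([ref[covered], alt[covered]])
        if (table.sum(axis=1) == 0).any():
            degenerate[k] = True
            continue
        res = stats.chi2_contingency(table, correction=False)
        chi2[k], pvals[k] = res.statistic, res.pvalue
    qvals = stats.false_discovery_control(pvals, method="bh")
    return HeterogeneityResult(
        sites=list(matrix.sites),
        chi2=chi2,
        p_values=pvals,
        q_values=qvals,
        degenerate=degenerate,
        retained=qvals < alpha,
    )


def pearson_distance(matrix: MitoVafMatrix) -> tuple[DistanceMatrix, np.ndarray]:
    """Pairwise 1 - rho distance over sites observed in both samples.

    Sites missing in either sample are pairwise-deleted; pairs with fewer
    than two shared sites, or with a zero-variance VAF vector (rho
    undefined), get distance 1 and are flagged.  Distances live in [0, 2]
    (1 - rho kept literally, no rescaling).
    """
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("need at least two samples")
    raw = np.zeros((n, n))
    flagged = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(matrix.vaf[i]) & ~np.isnan(matrix.vaf[j])
            if both.sum() < 2:
                raw[i, j] = raw[j, i] = 1.0
                flagged[i, j] = flagged[j, i] = True
                continue
            x, y = matrix.vaf[i, both], matrix.vaf[j, both]
            if np.std(x) == 0 or np.std(y) == 0:
                raw[i, j] = raw[j, i] = 1.0
                flagged[i, j] = flagged[j, i] = True
                continue
            rho = float(np.corrcoef(x, y)[0, 1])
            raw[i, j] = raw[j, i] = 1.0 - rho
    dist = DistanceMatrix(ids=list(matrix.samples), values=raw, max_value=2.0)
    if flagged.any():
        logger.info("pearson_distance: %d pairs flagged (rho undefined)",
                    int(flagged.sum()) // 2)
    return dist, flagged


def pearson_vaf_cluster(
    matrix: MitoVafMatrix,
    alpha: float = 0.05,
    policy: str = "fixed_k",
    k: int | None = None,
    prefilter: bool = True,
    **cut_kwargs,
) -> tuple[ClusterAssignment, HeterogeneityResult | None]:
    """Retain heterogeneous sites, then Ward-cluster lines on 1 - rho.

    Agglomeration and cutting reuse the nuclear clustering machinery;
    the default cut policy here is ``fixed_k`` because the
    similarity-based policy is defined on Jaccard similarity only.
    """
    het = None
    if prefilter:
        het = chi2_heterogeneity(matrix, alpha=alpha)
        keep = het.retained_indices()
        if len(keep) >= 2:
            matrix = matrix.select_sites(keep)
        else:
            logger.warning("heterogeneity filter retained <2 sites; using all sites")
    dist, _ = pearson_distance(matrix)
    dend = ward_cluster(dist)
    if policy == "fixed_k" and k is None:
        k = max(2, len(matrix.samples) // 4)
    assignment = cut_clusters(dend, policy, dist=dist, k=k, **cut_kwargs)
    return assignment, het


def mito_matrix_from_counts(
    counts: Mapping[str, Mapping[GenomicSite, tuple[int, int]]]
) -> MitoVafMatrix:
    """Assemble a VAF matrix from per-sample {site: (ref, alt)} counts."""
    samples = sorted(counts)
    sites = sorted({s for per in counts.values() for s in per})
    ref = np.zeros((len(samples), len(sites)))
    alt = np.zeros_like(ref)
    for i, sample in enumerate(samples):
        for k, site in enumerate(sites):
            r, a = counts[sample].get(site, (0, 0))
            ref[i, k] = r
            alt[i, k] = a
    return MitoVafMatrix(samples=samples, sites=sites, ref_counts=ref, alt_counts=alt)


def read_mito_counts(path) -> MitoVafMatrix:
    """Read the mito counts TSV: ``sample pos ref alt ref_count alt_count``."""
    counts: dict[str, dict[GenomicSite, tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            sample, pos, ref, alt, rc, ac = fields[:6]
            site = GenomicSite("chrM", int(pos), ref.upper(), alt.upper()).validate()
            counts.setdefault(sample, {})[site] = (int(rc), int(ac))
    return mito_matrix_from_counts(counts)


def write_mito_counts(matrix: MitoVafMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tpos\tref\talt\tref_count\talt_count\n")
        for i, sample in enumerate(matrix.samples):
            for k, site in enumerate(matrix.sites):
                fh.write(f"{sample}\t{site.pos}\t{site.ref}\t{site.alt}"
                         f"\t{int(matrix.ref_counts[i, k])}\t{int(matrix.alt_counts[i, k])}\n")
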