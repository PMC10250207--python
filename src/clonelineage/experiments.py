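"""Canned simulation experiments behind the package's headline numbers.

These functions wrap the library into the three benchmark protocols the
package is validated against: the minimum mutation burden at which
Jaccard/Ward clustering recovers redundant-line groups perfectly, the
clonality-ratio separation between clonal and two-founder lines at 5x
coverage, and nuclear-vs-mitochondrial clustering accuracy.  All are
deterministic under their seed arguments.
"""

from __future__ import annotations

import statistics
from typing import Sequence

import numpy as np

from .clonality import vaf_ratio
from .counts_calls import CallerParams, call_pair
from .clustering import (
    adjusted_rand_index,
    cut_clusters,
    jaccard_distance,
    ward_cluster,
)
from .io_model import GenomicSite, MutationCall
from .mito import mito_matrix_from_counts, pearson_vaf_cluster
from .plan import run_simulated_pipeline
from .simulate import (
    SimConfig,
    simulate_bulk,
    simulate_lineage,
    simulate_mito_counts,
    simulate_sequencing,
)

#: Group sizes of the redundant-line clustering benchmark: 12 local clonal
#: expansions of 2-6 lines each, 45 lines in total.
BURDEN_GROUP_SIZES: tuple[int, ...] = (2, 3, 4, 5, 6, 2, 3, 4, 5, 6, 2, 3)

#: Sentinel returned when no tested burden clusters perfectly.
BURDEN_NOT_REACHED = 999.0


def burden_threshold_experiment(
    seed: int = 0,
    founder_burdens: Sequence[int] = (50, 100, 200, 400),
    group_sizes: Sequence[int] = BURDEN_GROUP_SIZES,
    detection_prob: float = 0.5,
    private_rate: float = 0.05,
    n_replicates: int = 20,
) -> dict:
    """Smallest detected burden at which clustering is perfect.

    Each group's founder carries M unique mutations; every line detects
    each founder mutation independently with ``detection_prob`` (the 5x
    sensitivity) plus Poisson(``private_rate`` * M) private detected
    mutations.  Lines are clustered on 1 - Jaccard with Ward linkage and
    cut to the true number of groups; a burden passes when the adjusted
    Rand index against the truth is 1 in every replicate.  Returns the
    smallest passing *detected* burden (M * detection_prob).
    """
    n_groups = len(group_sizes)
    per_burden: dict[float, float] = {}
    for m in founder_burdens:
        min_ari = 1.0
        for rep in range(n_replicates):
            rng = np.random.default_rng([seed, m, rep])
            counter = 0
            callsets: dict[str, set[int]] = {}
            truth: dict[str, int] = {}
            for g, size in enumerate(group_sizes):
                founder = np.arange(counter, counter + m)
                counter += m
                for li in range(size):
                    lid = f"G{g}L{li}"
                    detected = founder[rng.random(m) < detection_prob]
                    n_priv = int(rng.poisson(private_rate * m))
                    private = np.arange(counter, counter + n_priv)
                    counter += n_priv
                    callsets[lid] = set(detected.tolist()) | set(private.tolist())
                    truth[lid] = g
            dist = jaccard_distance(callsets)
            assignment = cut_clusters(ward_cluster(dist), "fixed_k", k=n_groups)
            ari = adjusted_rand_index(truth, {s: assignment.labels[s] for s in truth})
            min_ari = min(min_ari, ari)
            if ari < 1.0:
                break
        per_burden[m * detection_prob] = min_ari
    passing = [b for b, ari in per_burden.items() if ari == 1.0]
    return {
        "min_detected_burden": min(passing) if passing else BURDEN_NOT_REACHED,
        "per_burden_min_ari": per_burden,
        "n_lines": sum(group_sizes),
    }


def clonality_ratio_experiment(
    nonclonal: bool,
    seed: int = 0,
    n_lines: int = 50,
    n_sites: int = 2000,
    coverage: float = 5.0,
    min_alt: int = 3,
    shared_fraction: float = 0.10,
) -> dict:
    """Median high/low-VAF ratio of simulated lines at shallow coverage.

    Clonal lines carry every mutation at true VAF 0.5.  Nonclonal lines
    are equal two-founder mixtures sharing ``shared_fraction`` of their
    mutations (true VAF 0.5 at shared sites, 0.25 at private ones).
    Depth ~ Poisson(coverage), alt ~ Binomial(depth, VAF), detection at
    >= ``min_alt`` alt reads; ratios computed by the clonality module.
    """
    rng = np.random.default_rng([seed, 11 if nonclonal else 10])
    site = GenomicSite("chr1", 1, "A", "T")
    ratios: list[float] = []
    for i in range(n_lines):
        if nonclonal:
            p = np.where(rng.random(n_sites) < shared_fraction, 0.5, 0.25)
        else:
            p = np.full(n_sites, 0.5)
        depth = rng.poisson(coverage, size=n_sites)
        alt = rng.binomial(depth, p)
        det = alt >= min_alt
        calls = [
            MutationCall.from_counts(site, f"L{i}", int(a), int(d))
            for a, d in zip(alt[det], depth[det])
        ]
        report = vaf_ratio(calls, sample=f"L{i}")
        if report.ratio is not None:
            ratios.append(report.ratio)
    return {
        "median_ratio": float(statistics.median(ratios)),
        "n_lines": len(ratios),
        "n_sites": n_sites,
    }


def end_to_end_recovery(
    seeds: Sequence[int] = tuple(range(20)), config_kwargs: dict | None = None
) -> dict:
    """Fraction of true multi-unit lineage edges recovered, per seed."""
    values = []
    for seed in seeds:
        config = SimConfig(seed=seed, **(config_kwargs or {}))
        result = run_simulated_pipeline(config)
        values.append(result.metrics["recovered_multi_unit"])
    return {
        "per_seed": values,
        "mean": float(np.mean(values)),
        "min": float(np.min(values)),
    }


def nuclear_vs_mito_ari(
    seeds: Sequence[int] = tuple(range(20)), config_kwargs: dict | None = None
) -> dict:
    """Clustering accuracy of shared nuclear mutations vs mito VAFs.

    Both tracks cluster the same clonal lines and are cut to the true
    number of founder groups; accuracy is ARI against the founder
    partition.  Mito VAF vectors drift along the lineage, so close
    relatives correlate, but small drift steps and few sites limit the
    resolution - the comparison quantifies that.
    """
    nuclear, mito_ = [], []
    for seed in seeds:
        config = SimConfig(seed=seed, n_nonclonal=0, **(config_kwargs or {}))
        truth = simulate_lineage(config)
        lines = sorted(truth.lines)
        truth_part = truth.true_groups()
        k = len(set(truth_part.values()))
        universe = truth.site_universe()
        bulk = simulate_bulk(truth, sites=universe)
        params = CallerParams()
        callsets = {}
        for lid in lines:
            counts, _ = simulate_sequencing(
                truth, lid, config.shallow_coverage, sites=universe)
            callsets[lid] = {c.site for c in call_pair(counts, bulk, params)}
        dist = jaccard_distance(callsets)
        assignment = cut_clusters(ward_cluster(dist), "fixed_k", k=k)
        nuclear.append(adjusted_rand_index(
            truth_part, {s: assignment.labels[s] for s in lines}))
        counts = {lid: simulate_mito_counts(truth, lid) for lid in lines}
        matrix = mito_matrix_from_counts(counts)
        m_assign, _ = pearson_vaf_cluster(matrix, k=k)
        mito_.append(adjusted_rand_index(
            truth_part, {s: m_assign.labels[s] for s in lines}))
    return {
        "nuclear_median": float(np.median(nuclear)),
        "mito_median": float(np.median(mito_)),
        "nuclear": nuclear,
        "mito": mito_,
    }
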