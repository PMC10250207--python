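"""Sequencing-strategy planner, cost calculator and pipeline driver.

The experimental strategy behind this package: sequence every clonal line
shallowly (5x), QC clonality, cluster redundant lines, then either merge
the shallow data of each redundant cluster ('sum all') or deep-sequence
one representative of small clusters ('pick one'); unique lines - those
sharing mutations with nobody - must each be sequenced to 15-30x.  Only
the unique lineages pay for high coverage, which is where the cost saving
comes from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import clonality as clonality_mod
from . import clustering as clustering_mod
from . import mito as mito_mod
from . import sharing_scores as scores_mod
from . import simulate as sim_mod
from . import tree as tree_mod
from .counts_calls import CallerParams, SiteCounts, call_pair, sum_counts
from .io_model import HIGH, SHALLOW, MutationCall, write_calls

logger = logging.getLogger(__name__)

MERGE_SHALLOW = "merge_shallow"
PICK_ONE_HIGH = "pick_one_high"
SEQUENCE_NEW_HIGH = "sequence_new_high"
SEQUENCE_HIGH = "sequence_high"
SKIP = "skip"

SUM_ALL = "sum_all"
PICK_ONE = "pick_one"


@dataclass
class PlanEntry:
    unit: str                 # cluster label or line id
    action: str
    lines: list[str]
    representative: str | None
    rationale: str


@dataclass
class SequencingPlan:
    strategy: str
    entries: list[PlanEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            for line in e.lines:
                if line in seen:
                    raise ValueError(f"line {line} appears in two plan entries")
                seen.add(line)
            if e.action == MERGE_SHALLOW and len(e.lines) < 2:
                raise ValueError(f"merge action for cluster {e.unit} with <2 lines")

    def actions(self) -> dict[str, str]:
        return {e.unit: e.action for e in self.entries}


@dataclass
class CostModel:
    """Sequencing prices: one 30x WGS vs one 5x WGS."""

    price_high: float = 600.0
    price_shallow: float = 150.0

    def __post_init__(self) -> None:
        if self.price_high < 0 or self.price_shallow < 0:
            raise ValueError("prices must be >= 0")


def propose_plan(
    assignment: clustering_mod.ClusterAssignment,
    coverage_classes: Mapping[str, str],
    strategy: str = SUM_ALL,
    seed: int = 0,
    allow_new_sequencing: bool = True,
) -> SequencingPlan:
    """Derive per-cluster actions from a cluster assignment.

    sum_all: every non-Unique cluster with >= 2 lines is merged; unique
    lines (and singleton clusters) use existing high coverage or are
    queued for high-coverage sequencing (15-30x).

    pick_one: clusters with > 3 lines are merged; clusters with 2-3 lines
    use an existing high-coverage member if there is one (picked
    seeded-random), otherwise a seeded-random member is queued for new
    high-coverage sequencing - or, with ``allow_new_sequencing=False``,
    the cluster is skipped as having no usable data.
    """
    if strategy not in (SUM_ALL, PICK_ONE):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    entries: list[PlanEntry] = []
    clusters = assignment.clusters()
    for label in sorted(clusters):
        members = clusters[label]
        if label == clustering_mod.UNIQUE_LABEL:
            for line in members:
                if coverage_classes.get(line) == HIGH:
                    entries.append(PlanEntry(line, PICK_ONE_HIGH, [line], line,
                                             "unique line with existing high coverage"))
                else:
                    entries.append(PlanEntry(line, SEQUENCE_HIGH, [line], line,
                                             "unique lineage: sequence to 15-30x"))
            continue
        if len(members) == 1:
            line = members[0]
            if coverage_classes.get(line) == HIGH:
                entries.append(PlanEntry(label, PICK_ONE_HIGH, members, line,
                                         "singleton cluster with high-coverage line"))
            else:
                entries.append(PlanEntry(label, SEQUENCE_HIGH, members, line,
                                         "singleton cluster: sequence to 15-30x"))
            continue
        if strategy == SUM_ALL or len(members) > 3:
            entries.append(PlanEntry(label, MERGE_SHALLOW, members, None,
                                     f"merge {len(members)} shallow lines"))
            continue
        # pick_one, small cluster of 2-3 lines
        high = [m for m in members if coverage_classes.get(m) == HIGH]
        if high:
            rep = str(rng.choice(high))
            entries.append(PlanEntry(label, PICK_ONE_HIGH, members, rep,
                                     "small cluster: picked existing high-coverage line"))
        elif allow_new_sequencing:
            rep = str(rng.choice(members))
            entries.append(PlanEntry(label, SEQUENCE_NEW_HIGH, members, rep,
                                     "small cluster without high-coverage line: "
                                     "sequence one member deeply"))
        else:
            entries.append(PlanEntry(label, SKIP, members, None,
                                     "small cluster without high-coverage line: "
                                     "skipped (no new sequencing allowed)"))
    return SequencingPlan(strategy=strategy, entries=entries)


def estimate_costs(
    n_lines: int, n_unique_high: int, cost_model: CostModel | None = None
) -> dict[str, float]:
    """Savings of shallow-first sequencing versus all-high sequencing.

    baseline = n_lines * price_high; proposed = n_lines * price_shallow +
    n_unique_high * price_high.  Both the exact saving and its
    nearest-1000 rounding are reported.
    """
    cm = cost_model or CostModel()
    if n_lines < 0 or n_unique_high < 0:
        raise ValueError("counts must be >= 0")
    if n_unique_high > n_lines:
        raise ValueError("n_unique_high cannot exceed n_lines")
    baseline = n_lines * cm.price_high
    proposed = n_lines * cm.price_shallow + n_unique_high * cm.price_high
    savings = baseline - proposed
    return {
        "baseline": baseline,
        "proposed": proposed,
        "savings": savings,
        "savings_rounded": round(savings / 1000.0) * 1000.0,
    }


@dataclass
class PipelineResult:
    reports: dict[str, clonality_mod.ClonalityReport]
    excluded: list[str]
    assignment: clustering_mod.ClusterAssignment
    plan: SequencingPlan
    unit_counts: list[SiteCounts]
    scores: list[scores_mod.VariantScore]
    sharing: dict
    tree: tree_mod.LineageTree | None
    truth: sim_mod.SimTruth | None = None
    truth_tree: tree_mod.LineageTree | None = None
    metrics: dict[str, float] = field(default_factory=dict)


def collapse_truth_tree(
    truth: sim_mod.SimTruth, unit_members: Mapping[str, Sequence[str]]
) -> tuple[tree_mod.LineageTree, dict[frozenset, int]]:
    """Project the true cell tree onto the analysis units.

    Each tracked edge maps to the set of units owning >= 1 line whose
    founder descends from the edge; edges with identical unit sets merge.
    Returns the truth tree over units and, per clade, the number of
    distinct founder leaves behind it (its sampling support).
    """
    unit_founders = {
        u: {truth.lines[l].founder for l in members}
        for u, members in unit_members.items()
    }
    sharing: dict = {}
    support: dict[frozenset, set] = {}
    for node, muts in truth.edge_mutations.items():
        carriers = frozenset(
            u for u, fs in unit_founders.items()
            if any(f.startswith(node) for f in fs)
        )
        if not carriers or not muts:
            continue
        for s in muts:
            sharing[s] = carriers
        support.setdefault(carriers, set()).update(
            f for fs in unit_founders.values() for f in fs if f.startswith(node)
        )
    groups = tree_mod.group_by_carriers(sharing)
    ttree = tree_mod.build_tree(groups, sorted(unit_members))
    return ttree, {c: len(s) for c, s in support.items()}


def run_simulated_pipeline(
    config: sim_mod.SimConfig,
    params: CallerParams | None = None,
    thresholds: scores_mod.ScoreThresholds | None = None,
    strategy: str = SUM_ALL,
    s_min: float = 0.10,
    j_max: float = 0.02,
    keep_inconclusive: bool = False,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """End-to-end run on synthetic truth: sequence shallow, QC, cluster,
    plan, merge, score pairwise, classify and build the lineage tree.

    Lines whose clonality cannot be confirmed (verdict nonclonal, and by
    default also inconclusive/no-data) are excluded before clustering:
    every downstream unit must be a clonal lineage sample."""
    params = params or CallerParams()
    truth = sim_mod.simulate_lineage(config)
    universe = truth.site_universe()
    bulk = sim_mod.simulate_bulk(truth, sites=universe)

    # (ii)-(iii): shallow sequencing of every line; calls relative to bulk
    line_counts: dict[str, SiteCounts] = {}
    line_calls: dict[str, list[MutationCall]] = {}
    for lid in sorted(truth.lines):
        counts, _ = sim_mod.simulate_sequencing(
            truth, lid, config.shallow_coverage, sites=universe
        )
        line_counts[lid] = counts
        line_calls[lid] = call_pair(counts, bulk, params)

    if len(truth.lines) < 2:
        raise ValueError("pipeline needs at least two lines to compare")

    # clonality QC on raw calls; nonclonal lines are excluded
    reports = {
        lid: clonality_mod.vaf_ratio(calls, sample=lid)
        for lid, calls in line_calls.items()
    }
    bad = {clonality_mod.NONCLONAL, clonality_mod.NO_DATA}
    if not keep_inconclusive:
        bad.add(clonality_mod.INCONCLUSIVE)
    excluded = [lid for lid, rep in reports.items() if rep.verdict in bad]
    kept = [lid for lid in sorted(truth.lines) if lid not in excluded]
    if len(kept) < 2:
        raise ValueError("fewer than two lines passed clonality QC")

    # (iv)-(v): cluster on shared call sites, pool unique lines
    callsets = {lid: {c.site for c in line_calls[lid]} for lid in kept}
    dist = clustering_mod.jaccard_distance(callsets)
    dend = clustering_mod.ward_cluster(dist)
    assignment = clustering_mod.cut_clusters(
        dend, "min_within_similarity", dist=dist, s_min=s_min
    )
    assignment = clustering_mod.detect_unique(dist, assignment, j_max=j_max)

    coverage_classes = {lid: SHALLOW for lid in kept}
    plan = propose_plan(assignment, coverage_classes, strategy=strategy,
                        seed=config.seed)

    # (vi)-(vii): build unit counts - merged clusters keep their summed
    # shallow data, unique/singleton lines are sequenced to high coverage
    unit_counts: list[SiteCounts] = []
    unit_members: dict[str, list[str]] = {}
    for entry in plan.entries:
        if entry.action == MERGE_SHALLOW:
            merged = sum_counts([line_counts[l] for l in entry.lines])
            merged.sample = entry.unit
            unit_counts.append(merged)
            unit_members[entry.unit] = entry.lines
        elif entry.action in (SEQUENCE_HIGH, SEQUENCE_NEW_HIGH, PICK_ONE_HIGH):
            rep = entry.representative or entry.lines[0]
            counts, _ = sim_mod.simulate_sequencing(
                truth, rep, config.high_coverage, sites=universe
            )
            counts.sample = entry.unit
            unit_counts.append(counts)
            unit_members[entry.unit] = [rep]

    table = scores_mod.build_pair_table(unit_counts, params)
    scores = scores_mod.classify_variants(scores_mod.score_all(table), thresholds)
    sharing = scores_mod.sharing_sets(scores)

    groups = tree_mod.group_by_carriers(sharing) if sharing else []
    built = tree_mod.build_tree(groups, [u.sample for u in unit_counts])
    truth_tree, clade_support = collapse_truth_tree(truth, unit_members)
    metrics = tree_mod.compare_trees(built, truth_tree)
    # recovery restricted to true edges sampled by >= 2 units
    tru = truth_tree.internal_clades()
    multi = [c for c in tru if len(c) >= 2]
    rec = built.internal_clades()
    metrics["recovered_multi_unit"] = (
        sum(1 for c in multi if c in rec) / len(multi) if multi else 1.0
    )

    result = PipelineResult(
        reports=reports, excluded=excluded, assignment=assignment,
        plan=plan, unit_counts=unit_counts, scores=scores, sharing=sharing,
        tree=built, truth=truth, truth_tree=truth_tree, metrics=metrics,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    writer(tmp)
    tmp.rename(path)


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _atomic_write(outdir / "clonality.tsv",
                  lambda p: clonality_mod.write_reports(result.reports.values(), p))
    _atomic_write(outdir / "clusters.tsv",
                  lambda p: clustering_mod.write_assignment(result.assignment, p))
    _atomic_write(outdir / "scores.tsv",
                  lambda p: scores_mod.write_scores(result.scores, p))
    _atomic_write(outdir / "score_scatter.csv",
                  lambda p: scores_mod.write_score_scatter(result.scores, p))
    _atomic_write(outdir / "branches.tsv",
                  lambda p: tree_mod.write_branch_table(result.tree, p))
    _atomic_write(outdir / "conflicts.tsv",
                  lambda p: tree_mod.write_conflicts(result.tree, p))
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(tree_mod.to_newick(result.tree) + "\n")
    with open(outdir / "plan.tsv", "w") as fh:
        fh.write("#unit\taction\trepresentative\tlines\trationale\n")
        for e in result.plan.entries:
            fh.write(f"{e.unit}\t{e.action}\t{e.representative or '-'}"
                     f"\t{','.join(e.lines)}\t{e.rationale}\n")
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=1)


def run_pipeline(
    sample_sheet,
    params: CallerParams | None = None,
    thresholds: scores_mod.ScoreThresholds | None = None,
    strategy: str = SUM_ALL,
    s_min: float = 0.10,
    j_max: float = 0.02,
    keep_inconclusive: bool = False,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run QC -> clustering -> planning -> scoring -> tree on a sample
    sheet of pre-called lines.

    The sheet supplies per-line call sets (QC and clustering) and,
    optionally, per-line count tables; without counts the run stops after
    planning (scores/tree empty).  Units queued for new sequencing fall
    back to the representative's existing counts, with a warning.
    """
    from .counts_calls import read_counts
    from .io_model import SampleSheet

    params = params or CallerParams()
    if not isinstance(sample_sheet, SampleSheet):
        sample_sheet = SampleSheet.load(sample_sheet)
    profiles = {p.sample: p for p in sample_sheet.lines}

    reports = {
        sid: clonality_mod.vaf_ratio(p.calls, sample=sid)
        for sid, p in profiles.items()
    }
    if len(profiles) < 2:
        raise ValueError(
            "pipeline stops after clonality QC: need at least two lines for "
            "pairwise comparison"
        )
    bad = {clonality_mod.NONCLONAL, clonality_mod.NO_DATA}
    if not keep_inconclusive:
        bad.add(clonality_mod.INCONCLUSIVE)
    excluded = [s for s, r in reports.items() if r.verdict in bad]
    kept = [s for s in sorted(profiles) if s not in excluded]
    if len(kept) < 2:
        raise ValueError("fewer than two lines passed clonality QC")

    callsets = {s: profiles[s].call_sites() for s in kept}
    dist = clustering_mod.jaccard_distance(callsets)
    dend = clustering_mod.ward_cluster(dist)
    assignment = clustering_mod.cut_clusters(
        dend, "min_within_similarity", dist=dist, s_min=s_min
    )
    assignment = clustering_mod.detect_unique(dist, assignment, j_max=j_max)
    coverage_classes = {s: profiles[s].coverage_class for s in kept}
    plan = propose_plan(assignment, coverage_classes, strategy=strategy, seed=seed)

    have_counts = all(profiles[s].counts_path for s in kept)
    unit_counts: list[SiteCounts] = []
    scores: list[scores_mod.VariantScore] = []
    sharing: dict = {}
    built = None
    if have_counts:
        counts_by_line: dict[str, SiteCounts] = {}
        for s in kept:
            loaded = read_counts(profiles[s].counts_path,
                                 mean_coverage=profiles[s].mean_coverage)
            match = next((c for c in loaded if c.sample == s), loaded[0])
            counts_by_line[s] = match
        for entry in plan.entries:
            if entry.action == MERGE_SHALLOW:
                merged = sum_counts([counts_by_line[l] for l in entry.lines])
                merged.sample = entry.unit
                unit_counts.append(merged)
            elif entry.action == SKIP:
                continue
            else:
                rep = entry.representative or entry.lines[0]
                if entry.action in (SEQUENCE_HIGH, SEQUENCE_NEW_HIGH):
                    logger.warning(
                        "unit %s queued for new sequencing; using existing "
                        "counts of %s", entry.unit, rep)
                counts = counts_by_line[rep]
                counts = SiteCounts(sample=entry.unit, counts=counts.counts,
                                    mean_coverage=counts.mean_coverage)
                unit_counts.append(counts)
        if len(unit_counts) >= 2:
            table = scores_mod.build_pair_table(unit_counts, params)
            scores = scores_mod.classify_variants(scores_mod.score_all(table),
                                                  thresholds)
            sharing = scores_mod.sharing_sets(scores)
            if sharing:
                groups = tree_mod.group_by_carriers(sharing)
                built = tree_mod.build_tree(groups, [u.sample for u in unit_counts])

    result = PipelineResult(
        reports=reports, excluded=excluded, assignment=assignment, plan=plan,
        unit_counts=unit_counts, scores=scores, sharing=sharing, tree=built,
    )
    if outdir is not None:
        _write_pipeline_artifacts(result, Path(outdir))
    return result


def _write_pipeline_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _atomic_write(outdir / "clonality.tsv",
                  lambda p: clonality_mod.write_reports(result.reports.values(), p))
    _atomic_write(outdir / "clusters.tsv",
                  lambda p: clustering_mod.write_assignment(result.assignment, p))
    with open(outdir / "plan.tsv", "w") as fh:
        fh.write("#unit\taction\trepresentative\tlines\trationale\n")
        for e in result.plan.entries:
            fh.write(f"{e.unit}\t{e.action}\t{e.representative or '-'}"
                     f"\t{','.join(e.lines)}\t{e.rationale}\n")
    if result.scores:
        _atomic_write(outdir / "scores.tsv",
                      lambda p: scores_mod.write_scores(result.scores, p))
    if result.tree is not None:
        _atomic_write(outdir / "branches.tsv",
                      lambda p: tree_mod.write_branch_table(result.tree, p))
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(tree_mod.to_newick(result.tree) + "\n")
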