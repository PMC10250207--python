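"""Synthetic truth generator: developmental lineage, biopsy clonal
expansion, sequencing-count emulation and mitochondrial heteroplasmy drift.

The generative model is deliberately simple.  Development is a synchronous
binary tree of ``n_divisions_tracked`` tracked divisions; each daughter
cell gains Poisson(``muts_per_division``) new mosaic mutations at unused
genomic sites, so mutation sets along any root-to-leaf path are disjoint
and a leaf's founder set is exactly the union of the edge sets on its
path.  A tracked "division" is a coarse-grained epoch: with the defaults
(depth 6, 200 mutations per daughter) a founder cell carries ~1200 mosaic
mutations, matching the 1000-2000 carried by real fibroblast-derived
clones, of which roughly half are detected at 5x coverage.

Biopsies sample leaves of the tracked tree as founders of local clonal
expansions; an expansion yields 1 + Poisson(redundancy - 1) clonal lines
that share the founder's entire mutation set (redundant lines).  Each
line additionally acquires private culture mutations at true VAF
Uniform(0.05, 0.3) - below the 30% postfilter by construction.  Nonclonal
lines mix two founders: mutations private to one founder have true VAF
mix/2 or (1-mix)/2, mutations on the shared ancestral path stay at 0.5.

Sequencing of a line is emulated at count level over a fixed site
universe: depth ~ Poisson(coverage) per site (optionally Gamma-Poisson
overdispersed), alt reads ~ Binomial(depth, true VAF), and a mutation is
"detected" iff alt >= ``min_alt_detect``.  No read-level artifacts, error
reads, CNVs or mutational signatures are modelled.

Every random draw comes from an RNG keyed by (seed, stage, entity ids),
so adding a line never perturbs any other line and a fixed seed gives
byte-identical truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .counts_calls import SiteCounts
from .io_model import GenomicSite, MutationCall

_STAGE_SITES = 1
_STAGE_TREE = 2
_STAGE_SAMPLING = 3
_STAGE_CULTURE = 4
_STAGE_SEQ = 5
_STAGE_MITO = 6
_STAGE_BULK = 7
_STAGE_NONCLONAL = 8

_BASES = np.array(list("ACGT"))


def _crc(text: str) -> int:
    return zlib.crc32(text.encode())


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([seed] + [k % (2**32) for k in keys])


@dataclass
class SimConfig:
    """Study conditions of the synthetic lineage experiment.

    The defaults describe the desk-scale study: a depth-6 tracked binary
    lineage, 4 biopsies of 11 clonal lines with mean redundancy 3, two
    nonclonal (two-founder) lines, 5x shallow sequencing with detection at
    >= 3 alt reads, and 30 mitochondrial heteroplasmy sites drifting with
    per-division SD 0.03.
    """

    n_divisions_tracked: int = 6
    muts_per_division: float = 200.0
    n_biopsies: int = 4
    clones_per_biopsy: int = 11
    redundancy: float = 3.0
    culture_mut_rate: float = 20.0
    genome_size: int = 1_000_000
    mito_sites: int = 30
    mito_drift_sd: float = 0.03
    seed: int = 0
    # documented knobs beyond the core model
    n_germline_sites: int = 40
    n_nonclonal: int = 2
    indel_fraction: float = 0.05
    biopsy_bias: float = 0.0        # >0 favours the '0' half of the first division
    depth_overdispersion: float = 0.0  # Gamma-Poisson shape^-1; 0 = pure Poisson
    shallow_coverage: float = 5.0
    high_coverage: float = 30.0
    min_alt_detect: int = 3

    def __post_init__(self) -> None:
        for name in ("muts_per_division", "redundancy", "culture_mut_rate",
                     "mito_drift_sd", "indel_fraction", "depth_overdispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.redundancy < 1:
            raise ValueError("redundancy is expected lines per expansion, must be >= 1")
        if self.n_divisions_tracked < 1:
            raise ValueError("need at least one tracked division")


@dataclass
class SimLine:
    line_id: str
    biopsy: str
    founder: str                 # leaf node id of the tracked tree
    clonal: bool
    founders: tuple[str, ...]    # 1 founder for clonal, 2 for nonclonal
    mix: float | None            # fraction of cells from founders[0]
    true_vaf: dict[GenomicSite, float]
    founder_sites: frozenset[GenomicSite]
    culture_sites: frozenset[GenomicSite]


@dataclass
class SimTruth:
    config: SimConfig
    edge_mutations: dict[str, frozenset[GenomicSite]]  # node id -> gained on edge
    leaves: list[str]
    lines: dict[str, SimLine]
    germline_sites: frozenset[GenomicSite]
    mito_sites: list[GenomicSite]
    mito_node_vaf: dict[str, np.ndarray]
    _site_cursor: int = 0
    _site_perm: np.ndarray | None = None

    # --- tree helpers -------------------------------------------------
    def path_nodes(self, leaf: str) -> list[str]:
        """Nodes on the path root -> leaf, excluding the root 'R'."""
        return [leaf[: k + 2] for k in range(len(leaf) - 1)]

    def founder_set(self, leaf: str) -> frozenset[GenomicSite]:
        out: set[GenomicSite] = set()
        for node in self.path_nodes(leaf):
            out |= self.edge_mutations[node]
        return frozenset(out)

    def site_universe(self) -> list[GenomicSite]:
        """All nuclear sites any line can carry (plus germline sites)."""
        sites: set[GenomicSite] = set(self.germline_sites)
        for line in self.lines.values():
            sites.update(line.true_vaf)
        return sorted(sites)

    def true_groups(self) -> dict[str, str]:
        """Partition of clonal lines by founder (the clustering truth)."""
        return {
            lid: line.founder
            for lid, line in self.lines.items()
            if line.clonal
        }


class GenomeExhaustedError(RuntimeError):
    pass


def _new_sites(truth: SimTruth, n: int, rng: np.random.Generator,
               indel_fraction: float) -> list[GenomicSite]:
    if truth._site_cursor + n > len(truth._site_perm):
        raise GenomeExhaustedError(
            "candidate site pool exhausted; increase SimConfig.genome_size"
        )
    out = []
    for _ in range(n):
        pos = int(truth._site_perm[truth._site_cursor]) + 1
        truth._site_cursor += 1
        ref = str(rng.choice(_BASES))
        if rng.random() < indel_fraction:
            ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 13))))
            alt = ref + ins
        else:
            alt = str(rng.choice([b for b in _BASES if b != ref]))
        out.append(GenomicSite("chr1", pos, ref, alt))
    return out


def simulate_lineage(config: SimConfig) -> SimTruth:
    """Generate the full synthetic truth for one individual."""
    rng_sites = _rng(config.seed, _STAGE_SITES)
    perm = rng_sites.permutation(config.genome_size)

    truth = SimTruth(
        config=config,
        edge_mutations={},
        leaves=[],
        lines={},
        germline_sites=frozenset(),
        mito_sites=[],
        mito_node_vaf={},
        _site_perm=perm,
    )

    # germline heterozygous variants, shared by every line and the bulk
    rng_g = _rng(config.seed, _STAGE_SITES, 1)
    truth.germline_sites = frozenset(
        _new_sites(truth, config.n_germline_sites, rng_g, config.indel_fraction)
    )

    # tracked binary tree: node ids 'R', then binary strings appended
    rng_tree = _rng(config.seed, _STAGE_TREE)
    nodes = ["R"]
    for depth in range(config.n_divisions_tracked):
        nxt = []
        for node in nodes:
            for child_bit in "01":
                child = node + child_bit
                n_mut = int(rng_tree.poisson(config.muts_per_division))
                truth.edge_mutations[child] = frozenset(
                    _new_sites(truth, n_mut, rng_tree, config.indel_fraction)
                )
                nxt.append(child)
        nodes = nxt
    truth.leaves = nodes

    # biopsy sampling: each biopsy draws founder leaves (globally without
    # replacement) and expands each into 1 + Poisson(redundancy - 1) lines
    rng_s = _rng(config.seed, _STAGE_SAMPLING)
    weights = np.array(
        [1.0 + config.biopsy_bias if leaf[1] == "0" else 1.0 for leaf in truth.leaves]
    )
    available = list(range(len(truth.leaves)))
    for b in range(config.n_biopsies):
        biopsy = f"B{b + 1}"
        made = 0
        while made < config.clones_per_biopsy:
            if not available:
                raise GenomeExhaustedError(
                    "tracked tree has too few leaves for the requested biopsies; "
                    "increase n_divisions_tracked"
                )
            w = weights[available] / weights[available].sum()
            pick = int(rng_s.choice(len(available), p=w))
            founder = truth.leaves[available.pop(pick)]
            k = 1 + int(rng_s.poisson(config.redundancy - 1.0))
            k = min(k, config.clones_per_biopsy - made)
            for _ in range(k):
                made += 1
                _add_clonal_line(truth, f"{biopsy}#{made}", biopsy, founder)

    # nonclonal lines: equal-ish mixtures of two distinct founders
    rng_nc = _rng(config.seed, _STAGE_NONCLONAL)
    founders_in_use = sorted({l.founder for l in truth.lines.values()})
    for i in range(config.n_nonclonal):
        fa, fb = rng_nc.choice(founders_in_use, size=2, replace=False)
        mix = float(rng_nc.uniform(0.3, 0.7))
        make_nonclonal_line(truth, str(fa), str(fb), mix, line_id=f"NC#{i + 1}",
                            biopsy=f"B{1 + i % config.n_biopsies}")

    # mitochondrial heteroplasmy: root vector + random walk down the tree
    _simulate_mito_tree(truth)
    return truth


def _add_clonal_line(truth: SimTruth, line_id: str, biopsy: str, founder: str) -> SimLine:
    config = truth.config
    founder_sites = truth.founder_set(founder)
    rng_c = _rng(config.seed, _STAGE_CULTURE, _crc(line_id))
    n_culture = int(rng_c.poisson(config.culture_mut_rate))
    culture = _new_sites(truth, n_culture, rng_c, config.indel_fraction)
    vaf: dict[GenomicSite, float] = {s: 0.5 for s in founder_sites}
    for s in culture:
        vaf[s] = float(rng_c.uniform(0.05, 0.3))
    for s in truth.germline_sites:
        vaf[s] = 0.5
    line = SimLine(
        line_id=line_id,
        biopsy=biopsy,
        founder=founder,
        clonal=True,
        founders=(founder,),
        mix=None,
        true_vaf=vaf,
        founder_sites=founder_sites,
        culture_sites=frozenset(culture),
    )
    truth.lines[line_id] = line
    return line


def make_nonclonal_line(
    truth: SimTruth,
    founder_a: str,
    founder_b: str,
    mix: float,
    line_id: str | None = None,
    biopsy: str = "B1",
) -> SimLine:
    """Add a line grown from two founder cells mixed at ``mix`` : 1-mix.

    Mutations private to founder_a get true VAF mix/2, private to
    founder_b (1-mix)/2; mutations on the shared ancestral path keep 0.5.
    """
    if founder_a == founder_b:
        raise ValueError("nonclonal line needs two distinct founders")
    if not 0 < mix < 1:
        raise ValueError("mix must lie in (0, 1)")
    config = truth.config
    if line_id is None:
        line_id = f"NC#{sum(not l.clonal for l in truth.lines.values()) + 1}"
    set_a = truth.founder_set(founder_a)
    set_b = truth.founder_set(founder_b)
    vaf: dict[GenomicSite, float] = {}
    for s in set_a | set_b:
        if s in set_a and s in set_b:
            vaf[s] = 0.5
        elif s in set_a:
            vaf[s] = mix / 2.0
        else:
            vaf[s] = (1.0 - mix) / 2.0
    rng_c = _rng(config.seed, _STAGE_CULTURE, _crc(line_id))
    n_culture = int(rng_c.poisson(config.culture_mut_rate))
    culture = _new_sites(truth, n_culture, rng_c, config.indel_fraction)
    for s in culture:
        vaf[s] = float(rng_c.uniform(0.05, 0.3))
    for s in truth.germline_sites:
        vaf[s] = 0.5
    line = SimLine(
        line_id=line_id,
        biopsy=biopsy,
        founder=founder_a,
        clonal=False,
        founders=(founder_a, founder_b),
        mix=mix,
        true_vaf=vaf,
        founder_sites=frozenset(set_a | set_b),
        culture_sites=frozenset(culture),
    )
    truth.lines[line_id] = line
    return line


def _depths(rng: np.random.Generator, coverage: float, n: int,
            overdispersion: float) -> np.ndarray:
    if coverage <= 0:
        return np.zeros(n, dtype=np.int64)
    if overdispersion > 0:
        lam = rng.gamma(1.0 / overdispersion, coverage * overdispersion, size=n)
        return rng.poisson(lam)
    return rng.poisson(coverage, size=n)


def simulate_sequencing(
    truth: SimTruth,
    line_id: str,
    coverage: float,
    seed: int = 0,
    sites: Sequence[GenomicSite] | None = None,
    min_alt: int | None = None,
) -> tuple[SiteCounts, list[MutationCall]]:
    """Emulate count-level sequencing of one line.

    Depth ~ Poisson(coverage) at every site of the universe (default: all
    sites any line can carry), alt ~ Binomial(depth, true VAF) with VAF 0
    at sites the line does not carry.  Returns the counts and the calls
    detected at >= ``min_alt`` supporting reads.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    config = truth.config
    line = truth.lines[line_id]
    if min_alt is None:
        min_alt = config.min_alt_detect
    if sites is None:
        sites = truth.site_universe()
    sites = list(sites)
    rng = _rng(config.seed, _STAGE_SEQ, _crc(line_id), int(coverage * 1000), seed)
    depth = _depths(rng, coverage, len(sites), config.depth_overdispersion)
    p = np.array([line.true_vaf.get(s, 0.0) for s in sites])
    alt = rng.binomial(depth, p)
    counts = SiteCounts(
        sample=line_id,
        counts={s: (int(d), int(a)) for s, d, a in zip(sites, depth, alt)},
        mean_coverage=coverage,
    )
    detected = [
        MutationCall.from_counts(s, line_id, int(a), int(d))
        for s, d, a in zip(sites, depth, alt)
        if a >= min_alt
    ]
    return counts, detected


def simulate_bulk(truth: SimTruth, coverage: float | None = None,
                  sites: Sequence[GenomicSite] | None = None) -> SiteCounts:
    """Emulate the reference bulk tissue (e.g. blood) used as control.

    Germline variants sit at VAF 0.5; a mosaic mutation on an *internal*
    tracked edge appears at VAF 0.5 x (fraction of tracked leaves
    descending from the edge), so the earliest mutations are partially
    suppressed in per-line calling against the bulk - exactly the
    behaviour that makes the pairwise rescoring of merged clusters
    necessary.  Mutations on terminal edges are treated as absent from
    the bulk: a tracked leaf is a coarse-grained stand-in for one
    clone-founder lineage, whose late mutations occupy a negligible
    fraction of the body.
    """
    config = truth.config
    if coverage is None:
        coverage = config.high_coverage
    if sites is None:
        sites = truth.site_universe()
    sites = list(sites)
    n_leaves = len(truth.leaves)
    edge_fraction = {
        node: sum(1 for leaf in truth.leaves if leaf.startswith(node)) / n_leaves
        for node in truth.edge_mutations
    }
    terminal_len = config.n_divisions_tracked + 1  # 'R' + one bit per division
    site_vaf: dict[GenomicSite, float] = {s: 0.5 for s in truth.germline_sites}
    for node, muts in truth.edge_mutations.items():
        frac = 0.0 if len(node) == terminal_len else edge_fraction[node]
        for s in muts:
            site_vaf[s] = 0.5 * frac
    rng = _rng(config.seed, _STAGE_BULK, int(coverage * 1000))
    depth = _depths(rng, coverage, len(sites), config.depth_overdispersion)
    p = np.array([site_vaf.get(s, 0.0) for s in sites])
    alt = rng.binomial(depth, p)
    return SiteCounts(
        sample="bulk",
        counts={s: (int(d), int(a)) for s, d, a in zip(sites, depth, alt)},
        mean_coverage=coverage,
        role="control",
    )


def _simulate_mito_tree(truth: SimTruth) -> None:
    config = truth.config
    rng_root = _rng(config.seed, _STAGE_MITO)
    truth.mito_sites = [
        GenomicSite("chrM", pos, "A", "G")
        for pos in sorted(
            rng_root.choice(np.arange(1, 16570), size=config.mito_sites, replace=False)
        )
    ]
    root_vaf = rng_root.uniform(0.05, 0.6, size=config.mito_sites)
    truth.mito_node_vaf = {"R": root_vaf}
    stack = ["R"]
    while stack:
        node = stack.pop()
        for bit in "01":
            child = node + bit
            if child not in truth.edge_mutations:
                continue
            parent_vaf = truth.mito_node_vaf[node]
            rng = _rng(config.seed, _STAGE_MITO, _crc(child))
            step = rng.normal(0.0, config.mito_drift_sd, size=config.mito_sites)
            child_vaf = np.clip(parent_vaf + step, 0.0, 1.0)
            # loss and fixation are absorbing
            child_vaf = np.where(parent_vaf <= 0.0, 0.0, child_vaf)
            child_vaf = np.where(parent_vaf >= 1.0, 1.0, child_vaf)
            truth.mito_node_vaf[child] = child_vaf
            stack.append(child)


def simulate_mito(truth: SimTruth, line_id: str) -> np.ndarray:
    """Heteroplasmy VAF vector of a line over ``truth.mito_sites``.

    The founder leaf's walk value, plus one extra culture-drift step per
    line (keyed by line id).  Nonclonal lines mix their two founders'
    vectors at the mix fraction.
    """
    config = truth.config
    line = truth.lines[line_id]
    if line.clonal:
        base = truth.mito_node_vaf[line.founder]
    else:
        va = truth.mito_node_vaf[line.founders[0]]
        vb = truth.mito_node_vaf[line.founders[1]]
        base = line.mix * va + (1.0 - line.mix) * vb
    rng = _rng(config.seed, _STAGE_MITO, _crc("line:" + line_id))
    step = rng.normal(0.0, config.mito_drift_sd, size=config.mito_sites)
    vaf = np.clip(base + step, 0.0, 1.0)
    vaf = np.where(base <= 0.0, 0.0, vaf)
    vaf = np.where(base >= 1.0, 1.0, vaf)
    return vaf


def simulate_mito_counts(
    truth: SimTruth, line_id: str, coverage: int = 1000
) -> dict[GenomicSite, tuple[int, int]]:
    """Mito read counts {site: (ref, alt)} at deep effective coverage."""
    vaf = simulate_mito(truth, line_id)
    rng = _rng(truth.config.seed, _STAGE_MITO, _crc("counts:" + line_id), coverage)
    depth = rng.poisson(coverage, size=len(truth.mito_sites))
    alt = rng.binomial(depth, vaf)
    return {
        s: (int(d - a), int(a))
        for s, d, a in zip(truth.mito_sites, depth, alt)
    }


# --- truth serialization ---------------------------------------------

def truth_to_json(truth: SimTruth) -> str:
    def site_str(s: GenomicSite) -> str:
        return f"{s.chrom}:{s.pos}:{s.ref}:{s.alt}"

    payload = {
        "config": asdict(truth.config),
        "leaves": truth.leaves,
        "edge_mutations": {
            node: sorted(map(site_str, muts))
            for node, muts in truth.edge_mutations.items()
        },
        "germline_sites": sorted(map(site_str, truth.germline_sites)),
        "lines": {
            lid: {
                "biopsy": line.biopsy,
                "founders": list(line.founders),
                "clonal": line.clonal,
                "mix": line.mix,
                "culture_sites": sorted(map(site_str, line.culture_sites)),
            }
            for lid, line in truth.lines.items()
        },
    }
    return json.dumps(payload, indent=1)


def true_tree_newick(truth: SimTruth) -> str:
    """Newick of the tracked binary tree with leaf labels = node ids."""

    def rec(node: str, depth: int) -> str:
        if depth == truth.config.n_divisions_tracked:
            return node
        children = [rec(node + b, depth + 1) for b in "01"]
        return "(" + ",".join(children) + ")"

    return rec("R", 0) + ";"
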