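"""Core domain types and readers/writers for variant-call data.

Two coordinate conventions coexist in this pipeline: variant sites are
1-based inclusive (VCF convention) while accessibility masks are 0-based
half-open (BED convention).  Conversion between the two happens in exactly
one place, :func:`pos_to_mask_coord`.

The internal tab-separated call dialect is::

    #sample  chrom  pos  ref  alt  alt_count  depth  vclass

with ``#``-prefixed comment/header lines.  It round-trips exactly.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pysam

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

SNV = "SNV"
INDEL = "INDEL"


class GenomicSite(NamedTuple):
    """A variant site identified by the full (chrom, pos, ref, alt) tuple.

    ``pos`` is 1-based inclusive.  An SNV and an indel at the same position
    are distinct sites: identity includes both alleles.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def validate(self) -> "GenomicSite":
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - _BASES:
                raise ValueError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} is not an "
                    "uppercase A/C/G/T string"
                )
        return self

    @property
    def indel_len(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def vclass(self) -> str:
        return SNV if self.indel_len == 0 else INDEL


def pos_to_mask_coord(pos: int) -> int:
    """Convert a 1-based variant position to the 0-based BED coordinate."""
    return pos - 1


@dataclass(frozen=True)
class MutationCall:
    """One somatic call in one sample, with its read support."""

    site: GenomicSite
    sample: str
    alt_count: int
    depth: int
    vaf: float
    vclass: str
    indel_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}] "
                f"at {self.site.chrom}:{self.site.pos}"
            )
        if abs(self.vaf - self.alt_count / self.depth) > 1e-9:
            raise ValueError(f"vaf {self.vaf} inconsistent with counts at {self.site}")
        if (self.vclass == SNV) != (self.indel_len == 0):
            raise ValueError("vclass must be SNV iff indel_len == 0")

    @classmethod
    def from_counts(
        cls, site: GenomicSite, sample: str, alt_count: int, depth: int
    ) -> "MutationCall":
        return cls(
            site=site,
            sample=sample,
            alt_count=alt_count,
            depth=depth,
            vaf=alt_count / depth,
            vclass=site.vclass,
            indel_len=site.indel_len,
        )


TSV_HEADER = "#sample\tchrom\tpos\tref\talt\talt_count\tdepth\tvclass"


def read_calls(
    path: str | Path, sample_id: str | None = None, format: str | None = None
) -> list[MutationCall]:
    """Read somatic calls from a VCF or the internal TSV dialect.

    For VCF input, only PASS (or unfiltered) records are returned; records
    with other FILTER values are skipped and counted in the log.
    Multiallelic records are split into biallelic calls using per-allele AD.
    A missing AD or DP field is a hard error naming the offending record.
    """
    path = Path(path)
    fmt = (format or _infer_format(path)).upper()
    if fmt == "TSV":
        return _read_calls_tsv(path, sample_id)
    if fmt == "VCF":
        return _read_calls_vcf(path, sample_id)
    raise ValueError(f"unknown call format {fmt!r} (expected VCF or TSV)")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz")):
        return "VCF"
    return "TSV"


def _read_calls_tsv(path: Path, sample_id: str | None) -> list[MutationCall]:
    calls: list[MutationCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected >= 7 columns, got {len(fields)}")
            sample, chrom, pos, ref, alt, alt_count, depth = fields[:7]
            if sample_id is not None and sample != sample_id:
                continue
            site = GenomicSite(chrom, int(pos), ref.upper(), alt.upper()).validate()
            calls.append(MutationCall.from_counts(site, sample, int(alt_count), int(depth)))
    return calls


def _read_calls_vcf(path: Path, sample_id: str | None) -> list[MutationCall]:
    calls: list[MutationCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns (AD/DP required)")
        if sample_id is not None and sample_id in samples:
            column = sample_id
        else:
            column = samples[0]
        out_sample = sample_id if sample_id is not None else column
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                n_skipped += 1
                continue
            fmt = rec.samples[column]
            ad = fmt.get("AD")
            if ad is None or any(x is None for x in ad):
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks AD")
            depth = fmt.get("DP")
            if depth is None:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks DP")
            for i, alt in enumerate(rec.alts or ()):
                site = GenomicSite(rec.chrom, rec.pos, rec.ref.upper(), alt.upper()).validate()
                calls.append(
                    MutationCall.from_counts(site, out_sample, int(ad[i + 1]), int(depth))
                )
    if n_skipped:
        logger.info("read_calls(%s): skipped %d non-PASS records", path, n_skipped)
    return calls


def write_calls(
    calls: Iterable[MutationCall], path: str | Path, format: str | None = None
) -> None:
    """Write calls as internal TSV (round-trip exact) or VCF with AD/DP."""
    path = Path(path)
    fmt = (format or _infer_format(path)).upper()
    if fmt == "TSV":
        _write_calls_tsv(calls, path)
    elif fmt == "VCF":
        _write_calls_vcf(calls, path)
    else:
        raise ValueError(f"unknown call format {fmt!r}")


def _write_calls_tsv(calls: Iterable[MutationCall], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(TSV_HEADER + "\n")
        for c in sorted(calls, key=lambda c: (c.sample, c.site)):
            s = c.site
            fh.write(
                f"{c.sample}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}"
                f"\t{c.alt_count}\t{c.depth}\t{c.vclass}\n"
            )


def _write_calls_vcf(calls: Iterable[MutationCall], path: Path) -> None:
    calls = list(calls)
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                                     ("Description", "Allelic depths")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                     ("Description", "Read depth")])
    chroms = sorted({c.site.chrom for c in calls})
    for chrom in chroms:
        header.contigs.add(chrom)
    samples = sorted({c.sample for c in calls}) or ["SAMPLE"]
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.site.chrom, c.site.pos, c.site.ref, c.site.alt)):
            rec = vcf.new_record(
                contig=c.site.chrom,
                start=c.site.pos - 1,
                stop=c.site.pos - 1 + len(c.site.ref),
                alleles=(c.site.ref, c.site.alt),
            )
            rec.filter.add("PASS")
            rec.samples[c.sample]["AD"] = (c.depth - c.alt_count, c.alt_count)
            rec.samples[c.sample]["DP"] = c.depth
            vcf.write(rec)


@dataclass
class GenomeMask:
    """Accessible-region mask from a BED3 file (0-based half-open, merged)."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomeMask":
        raw: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed BED line (need 3 columns)")
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed BED coordinates") from exc
                if end < start:
                    raise ValueError(f"{path}:{lineno}: end < start")
                raw.setdefault(chrom, []).append((start, end))
        return cls(intervals={c: _merge(iv) for c, iv in raw.items()})

    @classmethod
    def from_intervals(cls, intervals: Mapping[str, Sequence[tuple[int, int]]]) -> "GenomeMask":
        return cls(intervals={c: _merge(list(iv)) for c, iv in intervals.items()})

    def contains(self, site: GenomicSite) -> bool:
        iv = self.intervals.get(site.chrom)
        if not iv:
            return False
        x = pos_to_mask_coord(site.pos)
        idx = bisect_right(iv, (x, float("inf"))) - 1
        return idx >= 0 and iv[idx][0] <= x < iv[idx][1]

    __contains__ = contains


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def read_mask(path: str | Path) -> GenomeMask:
    """Read an accessibility mask (e.g. a mappability mask) from BED3."""
    return GenomeMask.from_bed(path)


SHALLOW = "shallow"
HIGH = "high"


@dataclass
class LineProfile:
    """One clonal line: identity, provenance and its somatic call set."""

    sample: str
    biopsy: str
    coverage_class: str
    mean_coverage: float
    calls: list[MutationCall] = field(default_factory=list)
    calls_path: str | None = None
    counts_path: str | None = None

    def __post_init__(self) -> None:
        if self.coverage_class not in (SHALLOW, HIGH):
            raise ValueError(f"coverage_class must be shallow/high, got {self.coverage_class}")
        if self.coverage_class == SHALLOW and self.mean_coverage > 10:
            logger.warning(
                "line %s declared shallow but mean_coverage=%.1f > 10",
                self.sample, self.mean_coverage,
            )
        sites = [c.site for c in self.calls]
        if len(sites) != len(set(sites)):
            raise ValueError(f"duplicate call sites in line {self.sample}")

    def call_sites(self) -> set[GenomicSite]:
        return {c.site for c in self.calls}


@dataclass
class SampleSheet:
    """Line descriptors plus file paths, loaded from a TSV.

    Columns: ``sample biopsy coverage_class mean_coverage calls_path
    [counts_path]``; paths are resolved relative to the sheet location and
    must exist at load time.
    """

    lines: list[LineProfile]

    def __post_init__(self) -> None:
        ids = [p.sample for p in self.lines]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids in sheet are not unique")

    @classmethod
    def load(cls, path: str | Path, load_calls: bool = True) -> "SampleSheet":
        path = Path(path)
        lines: list[LineProfile] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise ValueError(f"{path}:{lineno}: expected >= 5 columns")
                sample, biopsy, cov_class, mean_cov, calls_path = fields[:5]
                counts_path = fields[5] if len(fields) > 5 and fields[5] else None
                cpath = (path.parent / calls_path).resolve()
                if not cpath.exists():
                    raise FileNotFoundError(f"{path}:{lineno}: missing calls file {cpath}")
                if counts_path is not None:
                    kpath = (path.parent / counts_path).resolve()
                    if not kpath.exists():
                        raise FileNotFoundError(f"{path}:{lineno}: missing counts file {kpath}")
                    counts_path = str(kpath)
                calls = read_calls(cpath, sample_id=sample) if load_calls else []
                lines.append(
                    LineProfile(
                        sample=sample,
                        biopsy=biopsy,
                        coverage_class=cov_class,
                        mean_coverage=float(mean_cov),
                        calls=calls,
                        calls_path=str(cpath),
                        counts_path=counts_path,
                    )
                )
        return cls(lines=lines)
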