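"""Alignment cleaning and per-site counting.

COBRA-seq reads must begin with the retained portion of the enzyme
recognition site (the remnant, e.g. CGA for TaqI) and must align exactly at
an in silico predicted cut coordinate.  This module filters an alignment
stream on those two conditions -- tolerating one base of sequencing error in
the remnant trimer via a bounded Levenshtein distance -- and tallies the
survivors per cut site and strand, which is the method's quantification unit
("relative methylation level based on read counts").  Rejected records are
retained in the output stream with the unmapped flag (0x4) set, mirroring
how the alignments were post-processed upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .digest import (
    CutSiteIndex,
    Enzyme,
    MethylationAssumption,
    VERTEBRATE_CG,
    iupac_expansions,
    reverse_complement,
)

__all__ = [
    "FLAG_UNMAPPED",
    "FLAG_REVERSE",
    "FLAG_SECONDARY",
    "FLAG_DUPLICATE",
    "FLAG_SUPPLEMENTARY",
    "AlignmentRecord",
    "CleaningConfig",
    "SiteCountTable",
    "CleaningStats",
    "CleanResult",
    "bounded_levenshtein",
    "expected_trimers",
    "clean_and_count",
    "clean_sam",
    "export_bedgraph",
    "parse_bedgraph",
    "compare_libraries",
]

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


@dataclass
class AlignmentRecord:
    """Minimal mapped-read record (SAM semantics, 0-based half-open span).

    ``seq`` is stored in reference-forward orientation as in SAM, so forward
    reads carry the remnant as a prefix and reverse reads as a suffix.
    """

    name: str
    flag: int
    chrom: str | None
    start: int
    end: int  # exclusive
    seq: str
    mapq: int = 60

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED) or self.chrom is None

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @classmethod
    def from_pysam(cls, rec) -> "AlignmentRecord":
        return cls(
            name=rec.query_name or "",
            flag=rec.flag,
            chrom=rec.reference_name,
            start=rec.reference_start if rec.reference_start is not None else -1,
            end=rec.reference_end if rec.reference_end is not None else -1,
            seq=rec.query_sequence or "",
            mapq=rec.mapping_quality,
        )

    def to_sam_line(self, rname: str | None = None) -> str:
        chrom = rname or self.chrom or "*"
        pos = self.start + 1 if self.start >= 0 else 0
        cigar = f"{len(self.seq)}M" if self.seq and self.start >= 0 else "*"
        return "\t".join(
            [
                self.name,
                str(self.flag),
                chrom,
                str(pos),
                str(self.mapq),
                cigar,
                "*",
                "0",
                "0",
                self.seq or "*",
                "I" * len(self.seq) if self.seq else "*",
            ]
        )


@dataclass(frozen=True)
class CleaningConfig:
    """Knobs of the cleaning algorithm; defaults follow the published run."""

    max_edit: int = 1
    require_site_match: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_duplicates: bool = False
    min_mapq: int = 0
    rescue_observed_sites: bool = False

    def __post_init__(self) -> None:
        if self.max_edit < 0:
            raise ValueError("max_edit must be >= 0")


# ---------------------------------------------------------------------------
# Bounded Levenshtein distance
# ---------------------------------------------------------------------------


def bounded_levenshtein(a: str, b: str, bound: int) -> int:
    """Edit distance if it is <= ``bound``; otherwise the sentinel ``bound+1``.

    Plain dynamic programming with row-minimum early exit -- the strings here
    are remnant trimers, so the table is tiny.
    """
    sentinel = bound + 1
    if abs(len(a) - len(b)) > bound:
        return sentinel
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        if min(cur) > bound:
            return sentinel
        prev = cur
    return prev[-1] if prev[-1] <= bound else sentinel


class TrimerMatcher:
    """Min bounded edit distance of observed trimers against an IUPAC trimer.

    Degenerate expected trimers are compared by minimum distance over all
    concrete expansions; results are memoised since only ~64 observed trimers
    occur.
    """

    def __init__(self, expected: str, bound: int):
        self.expected = expected.upper()
        self.bound = bound
        self._expansions = iupac_expansions(self.expected)
        self._cache: dict[str, int] = {}

    def distance(self, observed: str) -> int:
        observed = observed.upper()
        hit = self._cache.get(observed)
        if hit is None:
            hit = min(
                bounded_levenshtein(observed, exp, self.bound)
                for exp in self._expansions
            )
            self._cache[observed] = hit
        return hit

    def matches(self, observed: str) -> bool:
        return self.distance(observed) <= self.bound


def expected_trimers(
    enzyme: Enzyme, assumption: MethylationAssumption = VERTEBRATE_CG
) -> tuple[str, str]:
    """(forward-read prefix, reverse-read suffix) remnant trimers.

    The forward prefix is the first <=3 bases of the remnant as it survives
    at a cut (interrogated cytosines are methylated, hence protected); the
    reverse suffix is the reverse complement of the remnant in
    reference-forward orientation (last <=3 bases).  TaqI -> ("CGA", "TCG").
    """
    if not enzyme.cleavable:
        raise ValueError(
            f"{enzyme.name} leaves no remnant on reads; cannot be cleaned"
        )
    n = min(3, len(enzyme.remnant))
    forward = enzyme.remnant[:n]
    reverse = reverse_complement(enzyme.remnant)[-n:]
    return forward, reverse


# ---------------------------------------------------------------------------
# Count table and stats
# ---------------------------------------------------------------------------

SiteKey = tuple[str, str, int]  # (chrom, strand, coord)


@dataclass
class SiteCountTable:
    """Per-site, per-strand read tallies for one library."""

    label: str = ""
    counts: dict[SiteKey, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, key: SiteKey) -> None:
        self.counts[key] = self.counts.get(key, 0) + 1

    def strand_summed(self) -> dict[tuple[str, int], int]:
        out: dict[tuple[str, int], int] = {}
        for (chrom, _strand, coord), n in self.counts.items():
            out[(chrom, coord)] = out.get((chrom, coord), 0) + n
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, SiteCountTable) and self.counts == other.counts


@dataclass
class CleaningStats:
    """Read accounting; ``input == kept + sum(dropped_*)`` always holds."""

    input: int = 0
    kept: int = 0
    dropped_secondary: int = 0
    dropped_unmapped: int = 0
    dropped_remnant: int = 0
    dropped_offsite: int = 0
    dropped_other: int = 0

    @property
    def dropped(self) -> int:
        return (
            self.dropped_secondary
            + self.dropped_unmapped
            + self.dropped_remnant
            + self.dropped_offsite
            + self.dropped_other
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "kept": self.kept,
            "dropped_secondary": self.dropped_secondary,
            "dropped_unmapped": self.dropped_unmapped,
            "dropped_remnant": self.dropped_remnant,
            "dropped_offsite": self.dropped_offsite,
            "dropped_other": self.dropped_other,
        }


@dataclass
class CleanResult:
    table: SiteCountTable
    stats: CleaningStats
    records: list[AlignmentRecord]
    rescued: SiteCountTable | None = None


# ---------------------------------------------------------------------------
# The cleaning algorithm
# ---------------------------------------------------------------------------


def clean_and_count(
    alignments: Iterable[AlignmentRecord],
    sites: CutSiteIndex,
    enzyme: Enzyme | None = None,
    config: CleaningConfig = CleaningConfig(),
    label: str = "",
) -> CleanResult:
    """Filter an alignment stream to bona fide cut-site reads and tally them.

    A record is kept iff it is mapped and primary (per ``config``), its
    remnant trimer (prefix for forward reads, suffix for reverse) is within
    ``max_edit`` Levenshtein of the expected trimer, and its proximal
    coordinate (start for forward, inclusive end for reverse) equals a
    predicted cut coordinate on the matching orientation.  Rejects are
    emitted with the unmapped bit set.  With ``rescue_observed_sites`` reads
    failing only the coordinate check are tallied in a separate table.
    """
    enzyme = enzyme or sites.enzyme
    if not enzyme.cleavable:
        raise ValueError(f"{enzyme.name} is not cleanable (empty remnant)")
    fwd_trimer, rev_trimer = expected_trimers(enzyme, sites.assumption)
    fwd_match = TrimerMatcher(fwd_trimer, config.max_edit)
    rev_match = TrimerMatcher(rev_trimer, config.max_edit)
    fwd_ok, rev_ok = sites.read_match_sets(passing_only=True)

    table = SiteCountTable(label=label)
    rescued = SiteCountTable(label=f"{label}:rescued") if config.rescue_observed_sites else None
    stats = CleaningStats()
    out: list[AlignmentRecord] = []

    def reject(rec: AlignmentRecord) -> None:
        out.append(replace(rec, flag=rec.flag | FLAG_UNMAPPED))

    for rec in alignments:
        stats.input += 1
        if rec.is_unmapped:
            stats.dropped_unmapped += 1
            reject(rec)
            continue
        if (config.drop_secondary and rec.is_secondary) or (
            config.drop_supplementary and rec.is_supplementary
        ):
            stats.dropped_secondary += 1
            reject(rec)
            continue
        if config.drop_duplicates and rec.is_duplicate:
            stats.dropped_other += 1
            reject(rec)
            continue
        if rec.mapq < config.min_mapq:
            stats.dropped_other += 1
            reject(rec)
            continue
        if len(rec.seq) < 3 or rec.start < 0 or rec.end <= rec.start:
            stats.dropped_other += 1
            reject(rec)
            continue
        if rec.is_reverse:
            trimer_ok = rev_match.matches(rec.seq[-3:])
            key: SiteKey = (rec.chrom, "-", rec.end - 1)
            coord_ok = rec.end - 1 in rev_ok.get(rec.chrom, ())
        else:
            trimer_ok = fwd_match.matches(rec.seq[:3])
            key = (rec.chrom, "+", rec.start)
            coord_ok = rec.start in fwd_ok.get(rec.chrom, ())
        if not trimer_ok:
            stats.dropped_remnant += 1
            reject(rec)
            continue
        if config.require_site_match and not coord_ok:
            stats.dropped_offsite += 1
            if rescued is not None:
                rescued.add(key)
            reject(rec)
            continue
        stats.kept += 1
        table.add(key)
        out.append(rec)
    return CleanResult(table=table, stats=stats, records=out, rescued=rescued)


def clean_sam(
    in_path: str | Path,
    sites: CutSiteIndex,
    out_path: str | Path | None = None,
    enzyme: Enzyme | None = None,
    config: CleaningConfig = CleaningConfig(),
    label: str = "",
) -> CleanResult:
    """Run :func:`clean_and_count` over a SAM/BAM file via pysam.

    When ``out_path`` is given, the annotated stream (rejects flagged
    unmapped) is written in the same header context as the input.
    """
    import pysam

    in_path = str(in_path)
    mode = "rb" if in_path.endswith(".bam") else "r"
    with pysam.AlignmentFile(in_path, mode, check_sq=False) as fh:
        pys_records = list(fh)
        header = fh.header
    records = [AlignmentRecord.from_pysam(r) for r in pys_records]
    result = clean_and_count(records, sites, enzyme, config, label=label)
    if out_path is not None:
        out_path = str(out_path)
        wmode = "wb" if out_path.endswith(".bam") else "w"
        with pysam.AlignmentFile(out_path, wmode, header=header) as out:
            for orig, cleaned in zip(pys_records, result.records):
                orig.flag = cleaned.flag
                out.write(orig)
    return result


# ---------------------------------------------------------------------------
# bedGraph export / import and inter-library concordance
# ---------------------------------------------------------------------------


def export_bedgraph(
    table: SiteCountTable,
    path: str | Path,
    by_strand: bool = False,
) -> list[Path]:
    """Write counts as bedGraph ``chrom  coord  coord+1  count`` lines.

    With ``by_strand`` two files are produced (suffixes ``.plus``/``.minus``
    before the extension); otherwise counts are summed over strands per
    coordinate.  Lines are sorted by chromosome then coordinate.
    """
    path = Path(path)

    def _write(target: Path, items: dict[tuple[str, int], int]) -> None:
        with open(target, "w") as fh:
            for (chrom, coord), n in sorted(items.items()):
                fh.write(f"{chrom}\t{coord}\t{coord + 1}\t{n}\n")

    if by_strand:
        written = []
        for strand, tag in (("+", "plus"), ("-", "minus")):
            items = {
                (c, pos): n
                for (c, s, pos), n in table.counts.items()
                if s == strand
            }
            target = path.with_name(f"{path.stem}.{tag}{path.suffix or '.bedGraph'}")
            _write(target, items)
            written.append(target)
        return written
    _write(path, table.strand_summed())
    return [path]


def parse_bedgraph(path: str | Path, strand: str = ".") -> SiteCountTable:
    """Read a bedGraph written by :func:`export_bedgraph` back into a table."""
    table = SiteCountTable(label=Path(path).stem)
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, _end, value = line.split("\t")
        table.counts[(chrom, strand, int(start))] = int(value)
    return table


def compare_libraries(table_a: SiteCountTable, table_b: SiteCountTable) -> dict:
    """Inter-library concordance of log-transformed per-site counts.

    Counts are aligned over the union of stored sites (absent = 0),
    transformed as log10(count + 0.5), and summarised by the squared Pearson
    correlation -- the statistic used to compare the PCR-amplified and
    linearly amplified libraries of the same sample.
    """
    from scipy import stats as sps

    keys = sorted(set(table_a.counts) | set(table_b.counts))
    shared = [k for k in keys if k in table_a.counts and k in table_b.counts]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} shared sites; concordance undefined"
        )
    a = np.log10(np.array([table_a.counts.get(k, 0) for k in keys]) + 0.5)
    b = np.log10(np.array([table_b.counts.get(k, 0) for k in keys]) + 0.5)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant counts; concordance undefined")
    r = float(sps.pearsonr(a, b).statistic)
    return {
        "n_union_sites": len(keys),
        "n_shared_sites": len(shared),
        "r_squared": r * r,
    }
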