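"""CpG dyad annotation: island/shore/ocean, promoter/gene-body/intergenic.

Classifies every CpG dyad in a genome into two mutually exclusive partitions
plus an enhancer overlay, then reports how much of each feature class an
accessible-site set covers.  Definitions: shores are the 2 kb flanks of CpG
islands (island bases excluded); promoters are TSS +/- 4 kb windows taking
precedence over gene bodies; everything else is intergenic.  Intervals are
0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FeatureIntervals",
    "CpGCatalog",
    "FeatureReport",
    "enumerate_cpgs",
    "classify_island_context",
    "classify_gene_context",
    "coverage_report",
    "merge_intervals",
]

ISLAND_CLASSES = ("island", "shore", "ocean")
GENE_CLASSES = ("promoter", "genebody", "intergenic")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping half-open intervals into sorted disjoint ones."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    starts: list[int] = []
    ends: list[int] = []
    for s, e in ivs:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _points_in(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Membership of points in merged intervals (vectorised stab query)."""
    if len(starts) == 0 or len(pos) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


@dataclass
class FeatureIntervals:
    """Labelled, merged, per-chromosome half-open intervals."""

    label: str
    intervals: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_list(
        cls, label: str, items: Iterable[tuple[str, int, int]]
    ) -> "FeatureIntervals":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in items:
            per_chrom.setdefault(chrom, []).append((start, end))
        return cls(label, {c: merge_intervals(v) for c, v in per_chrom.items()})

    @classmethod
    def from_bed(cls, label: str, path: str | Path) -> "FeatureIntervals":
        items = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            items.append((f[0], int(f[1]), int(f[2])))
        return cls.from_list(label, items)

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        starts, ends = self.intervals.get(chrom, (np.empty(0, np.int64),) * 2)
        return _points_in(starts, ends, pos)

    def shifted_union(self, flank: int) -> "FeatureIntervals":
        """Intervals expanded by ``flank`` on both sides, re-merged."""
        out = {}
        for chrom, (starts, ends) in self.intervals.items():
            out[chrom] = merge_intervals(
                zip((starts - flank).clip(min=0), ends + flank)
            )
        return FeatureIntervals(f"{self.label}+/-{flank}", out)


def enumerate_cpgs(genome: Mapping[str, str]) -> dict[str, np.ndarray]:
    """Plus-strand C positions of every CpG dyad, per chromosome."""
    out: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        if len(b) < 2:
            out[chrom] = np.empty(0, dtype=np.int64)
            continue
        mask = (b[:-1] == ord("C")) & (b[1:] == ord("G"))
        out[chrom] = np.flatnonzero(mask).astype(np.int64)
    return out


@dataclass
class CpGCatalog:
    """Every CpG dyad with its island-context and gene-context class labels."""

    positions: dict[str, np.ndarray]
    island_class: dict[str, np.ndarray] = field(default_factory=dict)  # int8 codes
    gene_class: dict[str, np.ndarray] = field(default_factory=dict)
    enhancer: dict[str, np.ndarray] = field(default_factory=dict)  # bool

    @property
    def n_total(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))

    def class_counts(self, which: str) -> dict[str, int]:
        names = ISLAND_CLASSES if which == "island" else GENE_CLASSES
        codes = self.island_class if which == "island" else self.gene_class
        counts = dict.fromkeys(names, 0)
        for arr in codes.values():
            for i, name in enumerate(names):
                counts[name] += int((arr == i).sum())
        return counts


def classify_island_context(
    catalog: CpGCatalog,
    islands: FeatureIntervals | None,
    shore_flank: int = 2000,
) -> CpGCatalog:
    """Assign island / shore / ocean to every dyad.

    Shore = within ``shore_flank`` bp of an island boundary but outside every
    island (half-open flanks, so a dyad exactly ``shore_flank`` bp away is
    ocean).  With no islands supplied everything is ocean.
    """
    flanked = islands.shifted_union(shore_flank) if islands is not None else None
    for chrom, pos in catalog.positions.items():
        codes = np.full(len(pos), ISLAND_CLASSES.index("ocean"), dtype=np.int8)
        if islands is not None:
            in_island = islands.contains(chrom, pos)
            in_flank = flanked.contains(chrom, pos)
            codes[in_flank & ~in_island] = ISLAND_CLASSES.index("shore")
            codes[in_island] = ISLAND_CLASSES.index("island")
        catalog.island_class[chrom] = codes
    return catalog


def classify_gene_context(
    catalog: CpGCatalog,
    tss: Sequence[tuple[str, int, str]] | None,
    genes: FeatureIntervals | None,
    promoter_flank: int = 4000,
) -> CpGCatalog:
    """Assign promoter / genebody / intergenic with promoter precedence.

    A dyad within ``promoter_flank`` bp of any TSS (symmetric, strand of the
    TSS ignored for the window) is a promoter dyad even when inside a gene
    body; the three classes partition the catalog exactly.
    """
    promoters = None
    if tss:
        promoters = FeatureIntervals.from_list(
            "promoter",
            [
                (chrom, max(0, p - promoter_flank), p + promoter_flank + 1)
                for chrom, p, _strand in tss
            ],
        )
    for chrom, pos in catalog.positions.items():
        codes = np.full(len(pos), GENE_CLASSES.index("intergenic"), dtype=np.int8)
        if genes is not None:
            codes[genes.contains(chrom, pos)] = GENE_CLASSES.index("genebody")
        if promoters is not None:
            codes[promoters.contains(chrom, pos)] = GENE_CLASSES.index("promoter")
        catalog.gene_class[chrom] = codes
    return catalog


def flag_enhancers(catalog: CpGCatalog, enhancers: FeatureIntervals | None) -> CpGCatalog:
    """Overlay flag: dyad falls inside an enhancer interval (not a partition)."""
    for chrom, pos in catalog.positions.items():
        catalog.enhancer[chrom] = (
            enhancers.contains(chrom, pos)
            if enhancers is not None
            else np.zeros(len(pos), dtype=bool)
        )
    return catalog


def build_catalog(
    genome: Mapping[str, str],
    islands: FeatureIntervals | None = None,
    tss: Sequence[tuple[str, int, str]] | None = None,
    genes: FeatureIntervals | None = None,
    enhancers: FeatureIntervals | None = None,
    shore_flank: int = 2000,
    promoter_flank: int = 4000,
) -> CpGCatalog:
    """Enumerate dyads and run both classifications plus the enhancer overlay."""
    catalog = CpGCatalog(positions=enumerate_cpgs(genome))
    classify_island_context(catalog, islands, shore_flank)
    classify_gene_context(catalog, tss, genes, promoter_flank)
    flag_enhancers(catalog, enhancers)
    return catalog


@dataclass
class FeatureReport:
    """Coverage accounting of an accessible-dyad set against the catalog.

    For each class: ``fraction_of_feature`` = |accessible ∩ class| / |class|
    and ``composition`` = |accessible ∩ class| / |accessible|.  Accessible
    positions missing from the catalog are tallied, never silently dropped.
    """

    n_accessible: int
    n_total: int
    n_mismatch: int
    island: dict[str, dict[str, float]]
    gene: dict[str, dict[str, float]]
    enhancer: dict[str, float]

    def to_rows(self) -> list[dict]:
        rows = []
        for partition, classes in (("island_context", self.island), ("gene_context", self.gene)):
            for name, vals in classes.items():
                rows.append({"partition": partition, "class": name, **vals})
        rows.append(
            {"partition": "overlay", "class": "enhancer", **self.enhancer}
        )
        return rows


def coverage_report(
    accessible: Mapping[str, np.ndarray], catalog: CpGCatalog
) -> FeatureReport:
    """Feature coverage of a set of accessible dyads (plus-strand C positions)."""
    n_mismatch = 0
    isl_acc = dict.fromkeys(ISLAND_CLASSES, 0)
    gene_acc = dict.fromkeys(GENE_CLASSES, 0)
    enh_acc = 0
    n_accessible = 0
    for chrom, pos in accessible.items():
        pos = np.asarray(pos, dtype=np.int64)
        n_accessible += len(pos)
        cat_pos = catalog.positions.get(chrom, np.empty(0, np.int64))
        if len(cat_pos) == 0:
            idx = np.zeros(len(pos), dtype=np.int64)
            ok = np.zeros(len(pos), dtype=bool)
        else:
            idx = np.searchsorted(cat_pos, pos)
            ok = (idx < len(cat_pos)) & (
                cat_pos[idx.clip(max=len(cat_pos) - 1)] == pos
            )
        n_mismatch += int((~ok).sum())
        hit = idx[ok]
        for i, name in enumerate(ISLAND_CLASSES):
            isl_acc[name] += int((catalog.island_class[chrom][hit] == i).sum())
        for i, name in enumerate(GENE_CLASSES):
            gene_acc[name] += int((catalog.gene_class[chrom][hit] == i).sum())
        enh_acc += int(catalog.enhancer[chrom][hit].sum())

    isl_tot = catalog.class_counts("island")
    gene_tot = catalog.class_counts("gene")
    enh_tot = int(sum(arr.sum() for arr in catalog.enhancer.values()))
    n_matched = n_accessible - n_mismatch

    def _stats(acc: int, tot: int) -> dict[str, float]:
        return {
            "n_accessible": acc,
            "n_feature": tot,
            "fraction_of_feature": acc / tot if tot else 0.0,
            "composition": acc / n_matched if n_matched else 0.0,
        }

    return FeatureReport(
        n_accessible=n_accessible,
        n_total=catalog.n_total,
        n_mismatch=n_mismatch,
        island={name: _stats(isl_acc[name], isl_tot[name]) for name in ISLAND_CLASSES},
        gene={name: _stats(gene_acc[name], gene_tot[name]) for name in GENE_CLASSES},
        enhancer=_stats(enh_acc, enh_tot),
    )


def read_genes_bed(path: str | Path) -> tuple[list[tuple[str, int, str]], FeatureIntervals]:
    """BED6 genes -> (strand-aware TSS list, merged gene-body intervals)."""
    tss: list[tuple[str, int, str]] = []
    items: list[tuple[str, int, int]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        strand = f[5] if len(f) > 5 else "+"
        tss.append((chrom, start if strand != "-" else end - 1, strand))
        items.append((chrom, start, end))
    return tss, FeatureIntervals.from_list("genes", items)
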