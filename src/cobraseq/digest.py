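"""In silico bisulfite-aware restriction digestion.

COBRA-seq predicts where a restriction enzyme will cut *bisulfite-converted*
genomic DNA.  Unmethylated cytosines read as thymine after conversion, so a
recognition site containing a cytosine survives only where that cytosine is
methylated (and conversion can also *create* sites, e.g. CCGA -> TCGA).  The
in silico digest therefore (1) converts each genome strand under a
methylation-context assumption (vertebrate default: every CpG cytosine is
methylated, everything else converts), (2) scans both converted strands for
IUPAC recognition-site matches, and (3) maps cut coordinates and the
interrogated CpG dyads back to plus-strand genome coordinates.

Coordinates are 0-based, half-open internally (BED convention).  A cut site's
``coord`` is the plus-strand position where a kept sequencing read's proximal
base aligns: for plus-strand sites the first remnant base
(``occ_start + cut_offset``); for minus-strand sites the rightmost aligned
reference base of a reverse read (``occ_start + len - 1 - cut_offset``,
assuming the palindromic/symmetric cut geometry of all shipped enzymes).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "IUPAC",
    "Enzyme",
    "MethylationAssumption",
    "VERTEBRATE_CG",
    "ALL_PROTECTED",
    "FULL_CONVERSION",
    "CutSite",
    "CutSiteIndex",
    "DEFAULT_ENZYMES",
    "parse_enzyme",
    "load_enzyme_config",
    "reverse_complement",
    "bisulfite_convert",
    "find_sites",
    "apply_fragment_filter",
    "accessible_cpg_fraction",
    "read_fasta",
    "write_fasta",
]

# ---------------------------------------------------------------------------
# IUPAC nucleotide code
# ---------------------------------------------------------------------------

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN" + "tgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement; accepts IUPAC degeneracy codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_expansions(pattern: str) -> tuple[str, ...]:
    """All concrete A/C/G/T strings matching an IUPAC pattern."""
    out = [""]
    for letter in pattern:
        try:
            choices = IUPAC[letter.upper()]
        except KeyError:
            raise ValueError(f"invalid IUPAC letter {letter!r}") from None
        out = [prefix + c for prefix in out for c in choices]
    return tuple(out)


def _iupac_regex(pattern: str) -> re.Pattern[str]:
    # Overlapping matches via lookahead; genome N never matches (classes
    # contain only ACGT).
    body = "".join(f"[{IUPAC[letter.upper()]}]" for letter in pattern)
    return re.compile(f"(?=({body}))")


# ---------------------------------------------------------------------------
# Enzyme model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme as a recognition pattern plus top-strand cut offset.

    ``cut_offset`` is the 0-based position within the recognition site where
    the top strand is cleaved (TaqI T/CGA -> 1).  The *remnant*
    (``recognition[cut_offset:]``) is what stays at the 5' end of the
    downstream fragment -- COBRA-seq reads begin with it.  Enzymes cutting
    at/after the 3' end of their site (empty remnant, e.g. Hpy99I CGACG/)
    are usable for site accounting but not for read cleaning.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        for letter in rec:
            if letter not in IUPAC:
                raise ValueError(
                    f"{self.name}: invalid IUPAC letter {letter!r} in recognition site"
                )
        if not rec:
            raise ValueError(f"{self.name}: empty recognition site")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside 0..{len(rec)}"
            )

    @property
    def remnant(self) -> str:
        return self.recognition[self.cut_offset:]

    @property
    def cleavable(self) -> bool:
        """True if reads retain recognition bases usable for cleaning."""
        return len(self.remnant) > 0

    @property
    def palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition

    @property
    def overhang(self) -> str | None:
        """Single-stranded overhang for palindromic, symmetric cutters."""
        if not self.palindromic:
            return None
        k, n = self.cut_offset, len(self.recognition)
        lo, hi = min(k, n - k), max(k, n - k)
        return self.recognition[lo:hi]

    def __str__(self) -> str:  # e.g. "TaqI(T/CGA)"
        r = self.recognition
        return f"{self.name}({r[: self.cut_offset]}/{r[self.cut_offset:]})"


def parse_enzyme(name: str, recognition: str, cut_offset: int) -> Enzyme:
    """Validate and build an :class:`Enzyme` (raises ``ValueError`` on bad input)."""
    return Enzyme(name=name, recognition=recognition, cut_offset=int(cut_offset))


#: Enzymes shipped with the package (palindromic CpG / CpN cutters plus the
#: non-cleavable Hpy99I, kept for addressable-site statistics only).
DEFAULT_ENZYMES: dict[str, Enzyme] = {
    e.name: e
    for e in (
        parse_enzyme("TaqI", "TCGA", 1),
        parse_enzyme("HpyCH4IV", "ACGT", 1),
        parse_enzyme("BstUI", "CGCG", 2),
        parse_enzyme("CviQI", "GTAC", 1),
        parse_enzyme("Sau3AI", "GATC", 0),
        parse_enzyme("HinP1I", "GCGC", 1),
        parse_enzyme("AclI", "AACGTT", 2),
        parse_enzyme("BstBI", "TTCGAA", 2),
        parse_enzyme("ClaI", "ATCGAT", 2),
        parse_enzyme("Hpy99I", "CGACG", 5),
    )
}


def load_enzyme_config(path: str | Path) -> dict[str, Enzyme]:
    """Read a flat enzyme table: ``name<TAB>recognition<TAB>cut_offset`` per line.

    Lines starting with ``#`` (and a ``name`` header line) are skipped.
    """
    enzymes: dict[str, Enzyme] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("name"):
            continue
        parts = re.split(r"[\t,=\s]+", line)
        if len(parts) != 3:
            raise ValueError(f"bad enzyme config line: {raw!r}")
        name, recognition, offset = parts
        enzymes[name] = parse_enzyme(name, recognition, int(offset))
    return enzymes


# ---------------------------------------------------------------------------
# Methylation assumption and bisulfite conversion
# ---------------------------------------------------------------------------

_VALID_CONTEXTS = {"CG", "CHG", "CHH", "ALL", "NONE"}


@dataclass(frozen=True)
class MethylationAssumption:
    """Which cytosine contexts are assumed methylated (conversion-protected).

    ``{"CG"}`` is the vertebrate default; ``{"ALL"}`` protects every C (for
    CpN enzymes); ``{"NONE"}`` converts every C.  Context of a cytosine is
    read from the next 1-2 bases on the same strand (H = A/C/T); an N or the
    sequence end never completes a context, so such cytosines convert.
    """

    contexts: frozenset[str] = frozenset({"CG"})

    def __post_init__(self) -> None:
        ctx = frozenset(c.upper() for c in self.contexts)
        object.__setattr__(self, "contexts", ctx)
        if not ctx:
            raise ValueError("contexts must be nonempty")
        bad = ctx - _VALID_CONTEXTS
        if bad:
            raise ValueError(f"unknown contexts: {sorted(bad)}")
        if ("NONE" in ctx or "ALL" in ctx) and len(ctx) > 1:
            raise ValueError("ALL/NONE must be the only context")

    @classmethod
    def from_string(cls, text: str) -> "MethylationAssumption":
        return cls(frozenset(t for t in re.split(r"[,+]", text) if t))

    @property
    def protect_all(self) -> bool:
        return "ALL" in self.contexts

    @property
    def convert_all(self) -> bool:
        return "NONE" in self.contexts


VERTEBRATE_CG = MethylationAssumption(frozenset({"CG"}))
ALL_PROTECTED = MethylationAssumption(frozenset({"ALL"}))
FULL_CONVERSION = MethylationAssumption(frozenset({"NONE"}))

_A, _C, _G, _T = (ord(b) for b in "ACGT")


def _protected_mask(b: np.ndarray, assumption: MethylationAssumption) -> np.ndarray:
    """Boolean mask over ``b`` (uint8 bases): cytosines that stay cytosine."""
    is_c = b == _C
    if assumption.protect_all:
        return is_c
    if assumption.convert_all:
        return np.zeros_like(is_c)
    n = len(b)
    nxt1 = np.zeros(n, dtype=np.uint8)
    nxt2 = np.zeros(n, dtype=np.uint8)
    if n > 1:
        nxt1[:-1] = b[1:]
    if n > 2:
        nxt2[:-2] = b[2:]
    is_h1 = (nxt1 == _A) | (nxt1 == _C) | (nxt1 == _T)
    protected = np.zeros(n, dtype=bool)
    if "CG" in assumption.contexts:
        protected |= nxt1 == _G
    if "CHG" in assumption.contexts:
        protected |= is_h1 & (nxt2 == _G)
    if "CHH" in assumption.contexts:
        is_h2 = (nxt2 == _A) | (nxt2 == _C) | (nxt2 == _T)
        protected |= is_h1 & is_h2
    return is_c & protected


def bisulfite_convert(sequence: str, assumption: MethylationAssumption) -> str:
    """Convert every unprotected cytosine to thymine (C -> T).

    Protection is decided per cytosine from its strand-local context under
    ``assumption``; all other bases pass through unchanged.
    """
    if not sequence:
        return sequence
    b = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8).copy()
    protected = _protected_mask(b, assumption)
    b[(b == _C) & ~protected] = _T
    return b.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Cut sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CutSite:
    """One predicted cut, anchored to the strand the occurrence was found on.

    ``coord`` is the plus-strand coordinate a kept read's proximal base aligns
    to (see module docstring); ``occ_start``/``occ_end`` delimit the
    recognition occurrence as a plus-strand half-open interval; ``cpg_dyads``
    lists plus-strand C positions of CpG dyads interrogated by the site.
    """

    chrom: str
    strand: str
    coord: int
    occ_start: int
    occ_end: int
    cpg_dyads: tuple[int, ...]
    passes_length_filter: bool = True
    coordinate_ambiguous: bool = False


def _plus_dyads(seq: str, start: int, end: int) -> tuple[int, ...]:
    n = len(seq)
    return tuple(
        q for q in range(start, end)
        if seq[q] == "C" and q + 1 < n and seq[q + 1] == "G"
    )


def _minus_dyads(seq: str, start: int, end: int) -> tuple[int, ...]:
    # Minus-strand cytosines sit opposite plus-strand Gs; the dyad is named
    # by its plus-strand C at g-1 (which may fall one base left of the
    # footprint, mirroring the plus-strand rule at the right edge).
    return tuple(
        g - 1 for g in range(start, end)
        if seq[g] == "G" and g - 1 >= 0 and seq[g - 1] == "C"
    )


@dataclass
class CutSiteIndex:
    """Per-chromosome, per-strand sorted cut-site records with provenance."""

    sites: list[CutSite]
    chrom_lengths: dict[str, int]
    enzyme: Enzyme
    assumption: MethylationAssumption
    min_fragment: int | None = None
    _by_key: dict[tuple[str, str], list[CutSite]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self.sites = sorted(self.sites, key=lambda s: (s.chrom, s.strand, s.coord))
        self._by_key = {}
        for site in self.sites:
            self._by_key.setdefault((site.chrom, site.strand), []).append(site)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def sites_for(self, chrom: str, strand: str) -> list[CutSite]:
        return self._by_key.get((chrom, strand), [])

    def coords(self, chrom: str, strand: str, passing_only: bool = True) -> np.ndarray:
        sites = self.sites_for(chrom, strand)
        return np.array(
            [s.coord for s in sites if s.passes_length_filter or not passing_only],
            dtype=np.int64,
        )

    def read_match_sets(
        self, passing_only: bool = True
    ) -> tuple[dict[str, set[int]], dict[str, set[int]]]:
        """Coordinate sets accepting forward-read starts / reverse-read ends.

        The post-PCR library molecule is a duplex, so an occurrence found on
        either converted strand can template reads in both orientations:
        forward reads start at ``occ_start + cut_offset`` and reverse reads
        end (inclusive) at ``occ_start + L - 1 - cut_offset``.
        """
        k = self.enzyme.cut_offset
        length = len(self.enzyme.recognition)
        fwd: dict[str, set[int]] = {}
        rev: dict[str, set[int]] = {}
        for site in self.sites:
            if passing_only and not site.passes_length_filter:
                continue
            fwd.setdefault(site.chrom, set()).add(site.occ_start + k)
            rev.setdefault(site.chrom, set()).add(site.occ_start + length - 1 - k)
        return fwd, rev

    # -- persistence --------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        """BED6: one line per site (name = enzyme, score = 0)."""
        with open(path, "w") as fh:
            for s in self.sites:
                fh.write(
                    f"{s.chrom}\t{s.coord}\t{s.coord + 1}\t"
                    f"{self.enzyme.name}\t0\t{s.strand}\n"
                )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "#enzyme={}\trecognition={}\tcut_offset={}\tcontexts={}\t"
                "min_fragment={}\tchrom_lengths={}\n".format(
                    self.enzyme.name,
                    self.enzyme.recognition,
                    self.enzyme.cut_offset,
                    ",".join(sorted(self.assumption.contexts)),
                    self.min_fragment,
                    ",".join(f"{c}:{l}" for c, l in sorted(self.chrom_lengths.items())),
                )
            )
            fh.write(
                "chrom\tstrand\tcoord\tocc_start\tocc_end\tcpg_dyads\t"
                "passes_length_filter\tcoordinate_ambiguous\n"
            )
            for s in self.sites:
                dyads = ",".join(map(str, s.cpg_dyads)) or "."
                fh.write(
                    f"{s.chrom}\t{s.strand}\t{s.coord}\t{s.occ_start}\t{s.occ_end}"
                    f"\t{dyads}\t{int(s.passes_length_filter)}"
                    f"\t{int(s.coordinate_ambiguous)}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CutSiteIndex":
        lines = Path(path).read_text().splitlines()
        meta = dict(
            item.split("=", 1)
            for item in lines[0].lstrip("#").split("\t")
            if "=" in item
        )
        enzyme = parse_enzyme(
            meta["enzyme"], meta["recognition"], int(meta["cut_offset"])
        )
        assumption = MethylationAssumption.from_string(meta["contexts"])
        min_fragment = None if meta["min_fragment"] == "None" else int(meta["min_fragment"])
        chrom_lengths = {}
        if meta.get("chrom_lengths"):
            for item in meta["chrom_lengths"].split(","):
                chrom, length = item.rsplit(":", 1)
                chrom_lengths[chrom] = int(length)
        sites = []
        for line in lines[2:]:
            if not line.strip():
                continue
            chrom, strand, coord, s0, s1, dyads, passes, ambig = line.split("\t")
            sites.append(
                CutSite(
                    chrom=chrom,
                    strand=strand,
                    coord=int(coord),
                    occ_start=int(s0),
                    occ_end=int(s1),
                    cpg_dyads=()
                    if dyads == "."
                    else tuple(int(d) for d in dyads.split(",")),
                    passes_length_filter=bool(int(passes)),
                    coordinate_ambiguous=bool(int(ambig)),
                )
            )
        return cls(sites, chrom_lengths, enzyme, assumption, min_fragment)


def find_sites(
    genome: Mapping[str, str],
    enzyme: Enzyme,
    assumption: MethylationAssumption = VERTEBRATE_CG,
) -> CutSiteIndex:
    """Predict cut sites on both strands of the bisulfite-converted genome.

    Plus-strand sites come from scanning the converted plus strand; minus
    sites from scanning the converted reverse complement, with coordinates
    mapped back to plus.  ``cpg_dyads`` are extracted from the *unconverted*
    sequence under each occurrence footprint.  Duplicate (chrom, strand,
    coord) records are collapsed with their dyad lists unioned.
    """
    pattern = _iupac_regex(enzyme.recognition)
    k, length = enzyme.cut_offset, len(enzyme.recognition)
    ambiguous = not enzyme.cleavable
    seen: dict[tuple[str, str, int], CutSite] = {}
    chrom_lengths: dict[str, int] = {}
    for chrom, raw in genome.items():
        seq = raw.upper()
        n = len(seq)
        chrom_lengths[chrom] = n
        conv = bisulfite_convert(seq, assumption)
        for match in pattern.finditer(conv):
            s = match.start()
            site = CutSite(
                chrom=chrom,
                strand="+",
                coord=s + k,
                occ_start=s,
                occ_end=s + length,
                cpg_dyads=_plus_dyads(seq, s, s + length),
                coordinate_ambiguous=ambiguous,
            )
            _absorb(seen, site)
        conv_rc = bisulfite_convert(reverse_complement(seq), assumption)
        for match in pattern.finditer(conv_rc):
            p = match.start()
            s = n - p - length  # plus-strand footprint start
            site = CutSite(
                chrom=chrom,
                strand="-",
                coord=s + length - 1 - k,
                occ_start=s,
                occ_end=s + length,
                cpg_dyads=_minus_dyads(seq, s, s + length),
                coordinate_ambiguous=ambiguous,
            )
            _absorb(seen, site)
    return CutSiteIndex(list(seen.values()), chrom_lengths, enzyme, assumption)


def _absorb(seen: dict, site: CutSite) -> None:
    key = (site.chrom, site.strand, site.coord)
    prior = seen.get(key)
    if prior is None:
        seen[key] = site
    else:
        seen[key] = replace(
            prior, cpg_dyads=tuple(sorted(set(prior.cpg_dyads) | set(site.cpg_dyads)))
        )


# ---------------------------------------------------------------------------
# Fragment-length filter and accessibility statistics
# ---------------------------------------------------------------------------


def apply_fragment_filter(index: CutSiteIndex, min_fragment: int = 70) -> CutSiteIndex:
    """Flag sites whose read-direction fragment is <= ``min_fragment`` bp.

    The fragment a read sequences into runs from the cut coordinate to the
    next cut on the same strand (rightward for plus sites, leftward for
    minus) or to the chromosome boundary; a site passes iff that fragment is
    strictly longer than ``min_fragment``.  Small downstream fragments are
    lost during library size selection, so their sites yield no reads.
    """
    new_sites: list[CutSite] = []
    for (chrom, strand), sites in index._by_key.items():
        coords = [s.coord for s in sites]  # sorted
        n = index.chrom_lengths.get(chrom, 0)
        for i, site in enumerate(sites):
            if strand == "+":
                nxt = coords[i + 1] if i + 1 < len(coords) else n
                frag = nxt - site.coord
            else:
                prev = coords[i - 1] if i > 0 else -1
                frag = site.coord - prev
            new_sites.append(replace(site, passes_length_filter=frag > min_fragment))
    return CutSiteIndex(
        new_sites, index.chrom_lengths, index.enzyme, index.assumption, min_fragment
    )


_CTX_CODES = ("CG", "CHG", "CHH", "CN")  # CN: trailing C with no context base


def _cytosine_context(seq: str, pos: int) -> str:
    n = len(seq)
    b1 = seq[pos + 1] if pos + 1 < n else ""
    b2 = seq[pos + 2] if pos + 2 < n else ""
    if b1 == "G":
        return "CG"
    if b1 in "ACT":
        if b2 == "G":
            return "CHG"
        if b2 in "ACT":
            return "CHH"
    return "CN"


def accessible_cpg_fraction(
    index: CutSiteIndex, genome: Mapping[str, str]
) -> dict:
    """Fraction of the genome's CpG dyads interrogated by passing sites.

    A dyad is accessible iff at least one site passing the fragment filter
    lists it; dyads are identified by plus-strand C position and counted
    once.  The per-context breakdown classifies each accessible interrogated
    cytosine (strand-locally) -- informative for CpN enzymes run under the
    ``ALL`` assumption, where non-CpG contexts appear.
    """
    from .annotate import enumerate_cpgs  # local import to avoid cycle

    dyads_by_chrom = enumerate_cpgs(genome)
    n_total = int(sum(len(v) for v in dyads_by_chrom.values()))
    accessible: dict[str, set[int]] = {}
    context_counts = {c: 0 for c in _CTX_CODES}
    counted: set[tuple[str, str, int]] = set()
    n_passing = 0
    for site in index.sites:
        if not site.passes_length_filter:
            continue
        n_passing += 1
        accessible.setdefault(site.chrom, set()).update(site.cpg_dyads)
        seq = genome[site.chrom].upper()
        if site.strand == "+":
            c_positions = [
                q for q in range(site.occ_start, site.occ_end) if seq[q] == "C"
            ]
            for q in c_positions:
                if (site.chrom, "+", q) not in counted:
                    counted.add((site.chrom, "+", q))
                    context_counts[_cytosine_context(seq, q)] += 1
        else:
            # minus-strand Cs sit opposite plus-strand Gs in the footprint
            for g in range(site.occ_start, site.occ_end):
                if seq[g] == "G":
                    key = (site.chrom, "-", g)
                    if key not in counted:
                        counted.add(key)
                        # strand-local context reads leftward on plus
                        b1 = seq[g - 1] if g - 1 >= 0 else ""
                        b2 = seq[g - 2] if g - 2 >= 0 else ""
                        if b1 == "C":
                            ctx = "CG"
                        elif b1 in "AGT":
                            ctx = "CHG" if b2 == "C" else (
                                "CHH" if b2 in "AGT" else "CN"
                            )
                        else:
                            ctx = "CN"
                        context_counts[ctx] += 1
    n_accessible = int(sum(len(v) for v in accessible.values()))
    return {
        "n_accessible_dyads": n_accessible,
        "n_total_dyads": n_total,
        "fraction": (n_accessible / n_total) if n_total else 0.0,
        "n_passing_sites": n_passing,
        "context_breakdown": context_counts,
        "accessible_dyads": {c: np.array(sorted(v), dtype=np.int64) for c, v in accessible.items()},
    }


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (possibly gzipped) multi-record FASTA into a chrom -> seq dict."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
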