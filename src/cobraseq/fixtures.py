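"""Synthetic genomes, methylomes and protocol-faithful COBRA-seq libraries.

The generator emulates the wet protocol step by step so the digestion,
cleaning and counting code can be exercised end to end with known truth:
sonicated fragments (150-500 bp) are drawn uniformly from a synthetic
genome; each molecule's CpG dyads are methylated by independent Bernoulli
draws from per-dyad beta values; bisulfite conversion deaminates
unmethylated cytosines (default efficiency 99.4%, methylated cytosines never
convert); the converted molecule is digested at surviving recognition-site
matches; and -- mirroring dual-biotin depletion of uncut and adapter-2-side
material -- a molecule yields exactly one read of up to 100 bp, templated
from the surviving cut nearest the randomly assigned adapter-2 end and
reading into the retained piece, 5' remnant first.  Uncut molecules yield
nothing, which is why an all-unmethylated methylome produces an empty
library.  Reads are written as FASTQ plus a correctly coordinated SAM
(no aligner involved), alongside per-read origin and per-site truth tables.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .cleaning import (
    FLAG_REVERSE,
    FLAG_SECONDARY,
    AlignmentRecord,
    SiteKey,
    bounded_levenshtein,
    expected_trimers,
)
from .digest import (
    CutSiteIndex,
    Enzyme,
    MethylationAssumption,
    VERTEBRATE_CG,
    _iupac_regex,
    iupac_expansions,
    reverse_complement,
    find_sites,
)
from .simulate import BetaDistSpec

__all__ = [
    "SyntheticGenomeSpec",
    "Methylome",
    "ProtocolParams",
    "LibraryResult",
    "make_genome",
    "make_methylome",
    "simulate_library",
    "expected_counts",
]

_A, _C, _G, _T = (ord(b) for b in "ACGT")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Random-genome parameters: iid base model with a CpG enrichment knob.

    Bases are drawn from a first-order chain where the probability of G
    following a C is multiplied by ``1 + cpg_enrichment`` (other bases
    renormalised); ``cpg_enrichment = 0`` recovers the iid model with CpG
    density gc^2/4.
    """

    n_chroms: int = 1
    lengths: tuple[int, ...] = (100_000,)
    gc: float = 0.45
    cpg_enrichment: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lengths) != self.n_chroms:
            raise ValueError("lengths must have n_chroms entries")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.cpg_enrichment < 0:
            raise ValueError("cpg_enrichment must be >= 0")
        pg_after_c = (self.gc / 2) * (1 + self.cpg_enrichment)
        if pg_after_c >= 1:
            raise ValueError("cpg_enrichment too large for this GC fraction")


def make_genome(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    """Generate a reproducible genome and its CpG dyad list."""
    from .annotate import enumerate_cpgs

    rng = np.random.default_rng(spec.seed)
    base_p = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )  # A C G T
    after_c = base_p.copy()
    after_c[2] *= 1 + spec.cpg_enrichment
    rest = 1.0 - after_c[2]
    scale = rest / (base_p[0] + base_p[1] + base_p[3])
    after_c[[0, 1, 3]] = base_p[[0, 1, 3]] * scale
    alphabet = np.array([_A, _C, _G, _T], dtype=np.uint8)
    cum_base = np.cumsum(base_p)
    cum_after_c = np.cumsum(after_c)
    genome: dict[str, str] = {}
    for ci, length in enumerate(spec.lengths):
        u = rng.random(length)
        out = np.empty(length, dtype=np.uint8)
        prev_is_c = False
        for i in range(length):
            cum = cum_after_c if prev_is_c else cum_base
            j = int(np.searchsorted(cum, u[i], side="right"))
            j = min(j, 3)
            out[i] = alphabet[j]
            prev_is_c = j == 1
        genome[f"chr{ci + 1}"] = out.tobytes().decode("ascii")
    return genome, enumerate_cpgs(genome)


@dataclass
class Methylome:
    """Ground-truth beta per CpG dyad (plus-strand C position), per chromosome."""

    positions: dict[str, np.ndarray]
    betas: dict[str, np.ndarray]

    def beta_at(self, chrom: str, pos: int) -> float:
        arr = self.positions[chrom]
        i = int(np.searchsorted(arr, pos))
        if i >= len(arr) or arr[i] != pos:
            raise KeyError(f"no dyad at {chrom}:{pos}")
        return float(self.betas[chrom][i])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tbeta\n")
            for chrom in sorted(self.positions):
                for p, b in zip(self.positions[chrom], self.betas[chrom]):
                    fh.write(f"{chrom}\t{p}\t{b:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Methylome":
        pos: dict[str, list[int]] = {}
        bet: dict[str, list[float]] = {}
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            chrom, p, b = line.split("\t")
            pos.setdefault(chrom, []).append(int(p))
            bet.setdefault(chrom, []).append(float(b))
        return cls(
            {c: np.array(v, dtype=np.int64) for c, v in pos.items()},
            {c: np.array(v, dtype=float) for c, v in bet.items()},
        )


def make_methylome(
    genome: Mapping[str, str],
    beta_spec: BetaDistSpec = BetaDistSpec(),
    seed: int = 0,
) -> Methylome:
    """Draw one beta per CpG dyad of ``genome`` from ``beta_spec``."""
    from .annotate import enumerate_cpgs

    rng = np.random.default_rng(seed)
    positions = enumerate_cpgs(genome)
    betas = {c: beta_spec.sample(len(p), rng) for c, p in positions.items()}
    return Methylome(positions, betas)


@dataclass(frozen=True)
class ProtocolParams:
    """Library-preparation and sequencing parameters.

    Fragment sizes and read length follow the pilot protocol (sonication to
    150-500 bp, 100 bp single-end reads); conversion efficiency defaults to
    the 99.4% completeness observed for the real libraries.  Decoy fractions
    inject labelled artefact reads (secondary records, reads at non-site
    coordinates, remnant-mutated reads) to exercise the cleaner.
    """

    fragment_range: tuple[int, int] = (150, 500)
    read_length: int = 100
    min_read_length: int = 40
    conversion_efficiency: float = 0.994
    sequencing_error: float = 0.001
    n_molecules: int = 10_000
    decoy_secondary: float = 0.0
    decoy_offsite: float = 0.0
    decoy_remnant: float = 0.0
    remnant_edit_distance: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fragment_range
        if not 1 <= lo <= hi:
            raise ValueError("bad fragment_range")
        if self.read_length > lo:
            raise ValueError("read_length must be <= min fragment length")
        for rate in (
            self.conversion_efficiency,
            self.sequencing_error,
            self.decoy_secondary,
            self.decoy_offsite,
            self.decoy_remnant,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class LibraryResult:
    """Reads plus ground truth for one simulated library."""

    label: str
    records: list[AlignmentRecord]
    reads_fastq: list[tuple[str, str]]  # (name, 5'->3' bases)
    truth_origin: dict[str, dict]  # read name -> origin/decoy annotation
    truth_counts: dict[SiteKey, int]  # non-decoy reads per site
    skipped: dict[str, int]
    params: ProtocolParams
    chrom_lengths: dict[str, int]

    @property
    def n_reads(self) -> int:
        return len(self.records)

    def sam_text(self) -> str:
        lines = ["@HD\tVN:1.6\tSO:unknown"]
        for chrom, length in sorted(self.chrom_lengths.items()):
            lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
        lines += [rec.to_sam_line() for rec in self.records]
        return "\n".join(lines) + "\n"

    def fastq_text(self) -> str:
        chunks = []
        for name, bases in self.reads_fastq:
            chunks.append(f"@{name}\n{bases}\n+\n{'I' * len(bases)}\n")
        return "".join(chunks)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sam": outdir / f"{self.label}.sam",
            "fastq": outdir / f"{self.label}.fastq",
            "origins": outdir / f"{self.label}.origins.tsv",
            "counts": outdir / f"{self.label}.truth_counts.tsv",
            "manifest": outdir / f"{self.label}.manifest.json",
        }
        paths["sam"].write_text(self.sam_text())
        paths["fastq"].write_text(self.fastq_text())
        with open(paths["origins"], "w") as fh:
            fh.write("read\tkind\tchrom\tstrand\tcoord\n")
            for name, origin in self.truth_origin.items():
                fh.write(
                    f"{name}\t{origin['kind']}\t{origin.get('chrom', '.')}\t"
                    f"{origin.get('strand', '.')}\t{origin.get('coord', '.')}\n"
                )
        with open(paths["counts"], "w") as fh:
            fh.write("chrom\tstrand\tcoord\tcount\n")
            for (chrom, strand, coord), n in sorted(self.truth_counts.items()):
                fh.write(f"{chrom}\t{strand}\t{coord}\t{n}\n")
        manifest = {
            "label": self.label,
            "n_reads": self.n_reads,
            "skipped": self.skipped,
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.params).items()
            },
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2))
        return paths


def _mutated_trimer(
    expected: str, distance: int, rng: np.random.Generator
) -> str:
    """A random trimer at exactly ``distance`` (min over IUPAC expansions)."""
    expansions = iupac_expansions(expected)
    candidates = []
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                t = a + b + c
                d = min(bounded_levenshtein(t, e, 3) for e in expansions)
                if d == distance:
                    candidates.append(t)
    if not candidates:
        raise ValueError(f"no trimer at distance {distance} from {expected}")
    return candidates[int(rng.integers(len(candidates)))]


def simulate_library(
    genome: Mapping[str, str],
    methylome: Methylome,
    enzyme: Enzyme,
    params: ProtocolParams = ProtocolParams(),
    assumption: MethylationAssumption = VERTEBRATE_CG,
    label: str = "lib",
) -> LibraryResult:
    """Emulate library construction and sequencing for one library.

    Only palindromic recognition sites are supported: digestion acts on the
    post-PCR duplex, and for palindromes scanning the single converted
    strand finds every duplex site.
    """
    if not enzyme.cleavable:
        raise ValueError(f"{enzyme.name} is not cleanable; no read geometry")
    if not enzyme.palindromic:
        raise ValueError(
            f"{enzyme.name}: only palindromic recognition sites are supported"
        )
    rng = np.random.default_rng(params.seed)
    pattern = _iupac_regex(enzyme.recognition)
    k, rec_len = enzyme.cut_offset, len(enzyme.recognition)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    chrom_weights = lengths / lengths.sum()
    lo, hi = params.fragment_range
    eff = params.conversion_efficiency
    rl_max = params.read_length

    records: list[AlignmentRecord] = []
    fastq: list[tuple[str, str]] = []
    truth_origin: dict[str, dict] = {}
    truth_counts: Counter = Counter()
    skipped = Counter(uncut=0, chrom_too_short=0, piece_too_short=0)

    # one batch of randomness per molecule keeps the stream reproducible
    mol_chrom = rng.choice(len(chroms), size=params.n_molecules, p=chrom_weights)
    mol_len = rng.integers(lo, hi + 1, size=params.n_molecules)
    mol_strand = rng.integers(0, 2, size=params.n_molecules)  # 0:'+', 1:'-'
    mol_a2_right = rng.integers(0, 2, size=params.n_molecules).astype(bool)

    for j in range(params.n_molecules):
        chrom = chroms[mol_chrom[j]]
        seq = genome[chrom]
        n_chrom = len(seq)
        frag_len = int(mol_len[j])
        if n_chrom < frag_len:
            skipped["chrom_too_short"] += 1
            continue
        start = int(rng.integers(0, n_chrom - frag_len + 1))
        minus = bool(mol_strand[j])

        dyad_pos = methylome.positions[chrom]
        dyad_beta = methylome.betas[chrom]
        i0 = int(np.searchsorted(dyad_pos, start - 1))
        i1 = int(np.searchsorted(dyad_pos, start + frag_len))
        local_dyads = dyad_pos[i0:i1]
        methylated = rng.random(i1 - i0) < dyad_beta[i0:i1]

        sub = seq[start: start + frag_len]
        if minus:
            sub = reverse_complement(sub)
        b = np.frombuffer(sub.encode("ascii"), dtype=np.uint8).copy()
        protected = np.zeros(frag_len, dtype=bool)
        if minus:
            # minus-strand C of dyad q sits at plus q+1 -> local frag_len-2-(q-start)
            loc = start + frag_len - 2 - local_dyads[methylated]
        else:
            loc = local_dyads[methylated] - start
        loc = loc[(loc >= 0) & (loc < frag_len)]
        protected[loc] = True
        is_c = b == _C
        convert = is_c & ~protected & (rng.random(frag_len) < eff)
        b[convert] = _T
        conv = b.tobytes().decode("ascii")

        cuts = [m.start() + k for m in pattern.finditer(conv)]
        if not cuts:
            skipped["uncut"] += 1
            continue
        if mol_a2_right[j]:
            # retained piece right of the last cut; read on the molecule strand
            c = cuts[-1]
            piece = frag_len - c
            if piece < params.min_read_length:
                skipped["piece_too_short"] += 1
                continue
            rl = min(rl_max, piece)
            local_seq = conv[c: c + rl]
            read_side_fwd = True
            local_proximal = c
        else:
            # retained piece left of the first cut; read on the complement
            m0 = cuts[0] - k
            e = m0 + rec_len - 1 - k  # complement-strand 5' base, local coords
            piece = e + 1
            if piece < params.min_read_length:
                skipped["piece_too_short"] += 1
                continue
            rl = min(rl_max, piece)
            local_seq = conv[e - rl + 1: e + 1]
            read_side_fwd = False
            local_proximal = e

        # map to genome coordinates; reference-forward stored sequence
        if not minus:
            if read_side_fwd:
                strand, pos = "+", start + local_proximal
                stored = local_seq
            else:
                strand = "-"
                end_incl = start + local_proximal
                pos = end_incl - rl + 1
                stored = local_seq
        else:
            if read_side_fwd:
                strand = "-"
                end_incl = start + frag_len - 1 - local_proximal
                pos = end_incl - rl + 1
                stored = reverse_complement(local_seq)
            else:
                strand = "+"
                pos = start + frag_len - 1 - local_proximal
                stored = reverse_complement(local_seq)

        if params.sequencing_error > 0:
            sb = np.frombuffer(stored.encode("ascii"), dtype=np.uint8).copy()
            err = rng.random(rl) < params.sequencing_error
            if err.any():
                for i in np.flatnonzero(err):
                    others = [x for x in (_A, _C, _G, _T) if x != sb[i]]
                    sb[i] = others[int(rng.integers(3))]
                stored = sb.tobytes().decode("ascii")

        name = f"{label}:mol{j}"
        flag = 0 if strand == "+" else FLAG_REVERSE
        rec = AlignmentRecord(
            name=name, flag=flag, chrom=chrom, start=pos, end=pos + rl, seq=stored
        )
        coord = pos if strand == "+" else pos + rl - 1
        records.append(rec)
        fastq.append((name, stored if strand == "+" else reverse_complement(stored)))
        truth_origin[name] = {
            "kind": "site",
            "chrom": chrom,
            "strand": strand,
            "coord": coord,
        }
        truth_counts[(chrom, strand, coord)] += 1

    _inject_decoys(
        records, fastq, truth_origin, genome, enzyme, assumption, params, rng, label
    )
    return LibraryResult(
        label=label,
        records=records,
        reads_fastq=fastq,
        truth_origin=truth_origin,
        truth_counts=dict(truth_counts),
        skipped=dict(skipped),
        params=params,
        chrom_lengths={c: len(genome[c]) for c in chroms},
    )


def _inject_decoys(
    records: list[AlignmentRecord],
    fastq: list[tuple[str, str]],
    truth_origin: dict[str, dict],
    genome: Mapping[str, str],
    enzyme: Enzyme,
    assumption: MethylationAssumption,
    params: ProtocolParams,
    rng: np.random.Generator,
    label: str,
) -> None:
    n_real = len(records)
    if n_real == 0:
        return
    fwd_trimer, _ = expected_trimers(enzyme, assumption)
    n_secondary = int(round(params.decoy_secondary * n_real))
    n_offsite = int(round(params.decoy_offsite * n_real))
    n_remnant = int(round(params.decoy_remnant * n_real))
    site_coords: dict[str, set[int]] = {}
    if n_offsite:
        fwd_ok, _rev_ok = find_sites(genome, enzyme, assumption).read_match_sets()
        site_coords = fwd_ok
    forward_real = [r for r in records[:n_real] if not r.flag & FLAG_REVERSE]
    for i in range(n_secondary):
        src = records[int(rng.integers(n_real))]
        name = f"{label}:decoy_secondary{i}"
        rec = AlignmentRecord(
            name=name,
            flag=src.flag | FLAG_SECONDARY,
            chrom=src.chrom,
            start=src.start,
            end=src.end,
            seq=src.seq,
        )
        records.append(rec)
        truth_origin[name] = {"kind": "decoy_secondary"}
    chroms = sorted(genome)
    concrete_fwd = iupac_expansions(fwd_trimer)
    for i in range(n_offsite):
        chrom = chroms[int(rng.integers(len(chroms)))]
        n_chrom = len(genome[chrom])
        rl = params.read_length
        while True:
            pos = int(rng.integers(0, max(1, n_chrom - rl)))
            if pos not in site_coords.get(chrom, set()):
                break
        body = "".join(
            "ACGT"[int(x)] for x in rng.integers(0, 4, size=rl - 3)
        )
        seqr = concrete_fwd[int(rng.integers(len(concrete_fwd)))] + body
        name = f"{label}:decoy_offsite{i}"
        records.append(
            AlignmentRecord(name=name, flag=0, chrom=chrom, start=pos, end=pos + rl, seq=seqr)
        )
        fastq.append((name, seqr))
        truth_origin[name] = {"kind": "decoy_offsite"}
    for i in range(n_remnant):
        if not forward_real:
            break
        src = forward_real[int(rng.integers(len(forward_real)))]
        trimer = _mutated_trimer(fwd_trimer, params.remnant_edit_distance, rng)
        seqr = trimer + src.seq[3:]
        name = f"{label}:decoy_remnant{i}"
        records.append(
            AlignmentRecord(
                name=name, flag=0, chrom=src.chrom, start=src.start, end=src.end, seq=seqr
            )
        )
        fastq.append((name, seqr))
        truth_origin[name] = {
            "kind": f"decoy_remnant_d{params.remnant_edit_distance}",
            "chrom": src.chrom,
            "strand": "+",
            "coord": src.start,
        }


def expected_counts(
    methylome: Methylome,
    sites: CutSiteIndex,
    params: ProtocolParams,
    genome: Mapping[str, str],
) -> dict[SiteKey, float]:
    """Closed-form expected read count per site, up to a shared constant.

    expectation ~ (molecules overlapping the site) x P(site survives
    conversion) where survival is the product of the betas of the site's
    CpG dyads times a conversion-success factor for every cytosine the
    recognition match requires to read as T.  Used as the oracle in
    count-recovery tests; absolute scale is approximate (read-side and
    multi-cut geometry contribute a common factor), correlations are exact.
    """
    total_len = sum(len(s) for s in genome.values())
    mean_frag = 0.5 * (params.fragment_range[0] + params.fragment_range[1])
    coverage = params.n_molecules * mean_frag / total_len
    eff = params.conversion_efficiency
    out: dict[SiteKey, float] = {}
    for site in sites:
        seq = genome[site.chrom]
        prob = 1.0
        for q in site.cpg_dyads:
            prob *= methylome.beta_at(site.chrom, q)
        if site.strand == "+":
            n_conv = sum(
                1
                for q in range(site.occ_start, site.occ_end)
                if seq[q] == "C" and not (q + 1 < len(seq) and seq[q + 1] == "G")
            )
        else:
            n_conv = sum(
                1
                for g in range(site.occ_start, site.occ_end)
                if seq[g] == "G" and not (g - 1 >= 0 and seq[g - 1] == "C")
            )
        prob *= eff ** n_conv
        out[(site.chrom, site.strand, site.coord)] = 0.5 * coverage * prob
    return out
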