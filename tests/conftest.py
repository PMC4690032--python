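"""Shared fixtures and independent oracles for the test suite.

The site-finding oracle below is deliberately naive and self-contained
(its own IUPAC table, base-by-base conversion, window sliding over a fully
expanded concrete-string set) so it shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import cobraseq as cs

ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_ORACLE_COMP.get(b, "N") for b in reversed(seq))


def oracle_convert(seq: str, contexts: frozenset[str]) -> str:
    """Base-by-base bisulfite conversion (independent of the numpy path)."""
    out = []
    for i, b in enumerate(seq):
        if b != "C":
            out.append(b)
            continue
        nxt1 = seq[i + 1] if i + 1 < len(seq) else ""
        nxt2 = seq[i + 2] if i + 2 < len(seq) else ""
        ctx = None
        if nxt1 == "G":
            ctx = "CG"
        elif nxt1 in "ACT":
            if nxt2 == "G":
                ctx = "CHG"
            elif nxt2 in "ACT":
                ctx = "CHH"
        protected = "ALL" in contexts or (ctx is not None and ctx in contexts)
        if "NONE" in contexts:
            protected = False
        out.append("C" if protected else "T")
    return "".join(out)


def oracle_sites(
    genome: dict[str, str], recognition: str, cut_offset: int, contexts: frozenset[str]
) -> set[tuple[str, str, int]]:
    """Expand-and-slide cut-site prediction: the independent oracle."""
    concrete = {
        "".join(p)
        for p in itertools.product(*(ORACLE_IUPAC[l] for l in recognition))
    }
    length, k = len(recognition), cut_offset
    found: set[tuple[str, str, int]] = set()
    for chrom, seq in genome.items():
        n = len(seq)
        conv = oracle_convert(seq, contexts)
        for s in range(n - length + 1):
            if conv[s: s + length] in concrete:
                found.add((chrom, "+", s + k))
        conv_rc = oracle_convert(oracle_revcomp(seq), contexts)
        for p in range(n - length + 1):
            if conv_rc[p: p + length] in concrete:
                s = n - p - length
                found.add((chrom, "-", s + length - 1 - k))
    return found


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def uniform_site_genome(
    n_blocks: int = 100, block: int = 600, seed: int = 7
) -> tuple[dict[str, str], cs.Methylome]:
    """One isolated TaqI site per A/T-filler block, uniform random betas.

    Sites are spaced further apart than the longest library fragment, so no
    molecule spans two sites and every site has identical accessibility.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for _ in range(n_blocks):
        filler = "".join("AT"[j] for j in rng.integers(0, 2, size=block - 4))
        blocks.append(filler[:100] + "TCGA" + filler[100:])
    genome = {"chr1": "".join(blocks)}
    dyads = cs.enumerate_cpgs(genome)["chr1"]
    assert len(dyads) == n_blocks
    betas = rng.uniform(0.02, 1.0, size=n_blocks)
    return genome, cs.Methylome({"chr1": dyads}, {"chr1": betas})


def per_occurrence_counts(
    counts: dict, index: cs.CutSiteIndex
) -> dict[tuple[str, int], int]:
    """Sum the two strand-key tallies of each recognition occurrence."""
    key_to_occ = {}
    k, L = index.enzyme.cut_offset, len(index.enzyme.recognition)
    for site in index:
        key_to_occ[(site.chrom, "+", site.occ_start + k)] = (site.chrom, site.occ_start)
        key_to_occ[(site.chrom, "-", site.occ_start + L - 1 - k)] = (
            site.chrom,
            site.occ_start,
        )
    out: dict[tuple[str, int], int] = {}
    for key, n in counts.items():
        occ = key_to_occ[key]
        out[occ] = out.get(occ, 0) + n
    return out


@pytest.fixture(scope="session")
def taqi() -> cs.Enzyme:
    return cs.DEFAULT_ENZYMES["TaqI"]


@pytest.fixture(scope="session")
def small_genome() -> dict[str, str]:
    genome, _ = cs.make_genome(
        cs.SyntheticGenomeSpec(lengths=(30_000,), gc=0.45, cpg_enrichment=1.0, seed=3)
    )
    return genome


@pytest.fixture(scope="session")
def small_methylome(small_genome) -> cs.Methylome:
    return cs.make_methylome(small_genome, seed=4)


@pytest.fixture(scope="session")
def small_index(small_genome, taqi) -> cs.CutSiteIndex:
    return cs.find_sites(small_genome, taqi)
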