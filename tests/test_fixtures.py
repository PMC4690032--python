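"""Synthetic genome/methylome generation and protocol-faithful libraries."""

import numpy as np
import pytest

import cobraseq as cs
from cobraseq.cleaning import FLAG_REVERSE
from cobraseq.simulate import BetaDistSpec


class TestMakeGenome:
    def test_deterministic_and_correct_shape(self):
        spec = cs.SyntheticGenomeSpec(n_chroms=2, lengths=(10_000, 5_000), seed=7)
        g1, d1 = cs.make_genome(spec)
        g2, _ = cs.make_genome(spec)
        assert g1 == g2
        assert len(g1["chr1"]) == 10_000 and len(g1["chr2"]) == 5_000
        assert set("".join(g1.values())) <= set("ACGT")
        assert (d1["chr1"] == cs.enumerate_cpgs(g1)["chr1"]).all()

    def test_zero_enrichment_recovers_iid_cpg_density(self):
        spec = cs.SyntheticGenomeSpec(
            lengths=(60_000,), gc=0.5, cpg_enrichment=0.0, seed=1
        )
        genome, dyads = cs.make_genome(spec)
        n = len(genome["chr1"]) - 1
        p = 0.5 * 0.5 / 4 * 4  # P(C) * P(G) = gc^2 / 4
        p = 0.25 * 0.25
        se = np.sqrt(p * (1 - p) / n)
        assert abs(len(dyads["chr1"]) / n - p) < 3 * se

    def test_enrichment_raises_cpg_density(self):
        lo = cs.make_genome(
            cs.SyntheticGenomeSpec(lengths=(30_000,), cpg_enrichment=0.0, seed=2)
        )[1]["chr1"]
        hi = cs.make_genome(
            cs.SyntheticGenomeSpec(lengths=(30_000,), cpg_enrichment=2.0, seed=2)
        )[1]["chr1"]
        assert len(hi) > 1.5 * len(lo)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            cs.SyntheticGenomeSpec(n_chroms=2, lengths=(100,))
        with pytest.raises(ValueError):
            cs.SyntheticGenomeSpec(gc=0.9, cpg_enrichment=3.0)


class TestMakeMethylome:
    def test_extreme_specs(self, small_genome):
        zero = cs.make_methylome(small_genome, BetaDistSpec.point_mass(0.0), seed=0)
        one = cs.make_methylome(small_genome, BetaDistSpec.point_mass(1.0), seed=0)
        assert all((v == 0).all() for v in zero.betas.values())
        assert all((v == 1).all() for v in one.betas.values())

    def test_every_dyad_covered_once(self, small_genome, small_methylome):
        dyads = cs.enumerate_cpgs(small_genome)
        for chrom in dyads:
            assert (small_methylome.positions[chrom] == dyads[chrom]).all()

    def test_mixture_mean_within_three_se(self, small_genome):
        spec = BetaDistSpec()
        meth = cs.make_methylome(small_genome, spec, seed=5)
        betas = np.concatenate(list(meth.betas.values()))
        se = betas.std() / np.sqrt(len(betas))
        assert abs(betas.mean() - spec.mean) < 3 * se

    def test_tsv_round_trip(self, small_methylome, tmp_path):
        path = tmp_path / "meth.tsv"
        small_methylome.to_tsv(path)
        loaded = cs.Methylome.from_tsv(path)
        for chrom in small_methylome.positions:
            assert (loaded.positions[chrom] == small_methylome.positions[chrom]).all()
            assert np.allclose(loaded.betas[chrom], small_methylome.betas[chrom])


def _clean_params(**kwargs):
    defaults = dict(
        n_molecules=2_000, conversion_efficiency=1.0, sequencing_error=0.0, seed=11
    )
    defaults.update(kwargs)
    return cs.ProtocolParams(**defaults)


class TestSimulateLibrary:
    def test_fully_methylated_single_site_read_geometry(self, taqi):
        genome = {"chr1": "T" * 200 + "TCGA" + "T" * 200}
        meth = cs.make_methylome(genome, BetaDistSpec.point_mass(1.0))
        lib = cs.simulate_library(genome, meth, taqi, _clean_params())
        assert lib.n_reads > 0
        for rec in lib.records:
            if rec.flag & FLAG_REVERSE:
                assert rec.end - 1 == 202 and rec.seq[-3:] == "TCG"
            else:
                assert rec.start == 201 and rec.seq[:3] == "CGA"

    def test_unmethylated_molecules_never_yield_reads(self, small_genome, taqi):
        meth = cs.make_methylome(small_genome, BetaDistSpec.point_mass(0.0))
        lib = cs.simulate_library(small_genome, meth, taqi, _clean_params())
        assert lib.n_reads == 0
        assert lib.skipped["uncut"] > 0

    def test_byte_identical_outputs_for_fixed_seed(self, small_genome, small_methylome, taqi):
        params = _clean_params(n_molecules=500, sequencing_error=0.01)
        a = cs.simulate_library(small_genome, small_methylome, taqi, params)
        b = cs.simulate_library(small_genome, small_methylome, taqi, params)
        assert a.sam_text() == b.sam_text()
        assert a.fastq_text() == b.fastq_text()

    def test_truth_counts_account_for_every_non_decoy_read(
        self, small_genome, small_methylome, taqi
    ):
        lib = cs.simulate_library(
            small_genome, small_methylome, taqi,
            _clean_params(decoy_offsite=0.05, decoy_secondary=0.05),
        )
        n_site_reads = sum(
            1 for o in lib.truth_origin.values() if o["kind"] == "site"
        )
        assert sum(lib.truth_counts.values()) == n_site_reads
        assert n_site_reads < lib.n_reads  # decoys present on top

    def test_non_palindromic_or_non_cleanable_enzymes_rejected(
        self, small_genome, small_methylome
    ):
        with pytest.raises(ValueError, match="palindromic"):
            cs.simulate_library(
                small_genome, small_methylome,
                cs.parse_enzyme("odd", "GACGC", 1), _clean_params(),
            )
        with pytest.raises(ValueError, match="not cleanable"):
            cs.simulate_library(
                small_genome, small_methylome,
                cs.DEFAULT_ENZYMES["Hpy99I"], _clean_params(),
            )

    def test_reads_validate_against_written_sam(self, small_genome, small_methylome, taqi, tmp_path):
        import pysam

        lib = cs.simulate_library(
            small_genome, small_methylome, taqi, _clean_params(n_molecules=300)
        )
        path = tmp_path / "lib.sam"
        path.write_text(lib.sam_text())
        with pysam.AlignmentFile(str(path), "r") as fh:
            recs = list(fh)
        assert len(recs) == lib.n_reads
        # SAM stores reference-forward sequence; check against the genome for
        # a few fully methylated-context reads
        for rec in recs[:20]:
            ref = small_genome[rec.reference_name][
                rec.reference_start: rec.reference_end
            ]
            assert len(rec.query_sequence) == len(ref)


class TestPipelineClosure:
    def test_error_free_library_is_fully_recovered(self, small_genome, small_methylome, taqi):
        index = cs.find_sites(small_genome, taqi)
        lib = cs.simulate_library(small_genome, small_methylome, taqi, _clean_params())
        result = cs.clean_and_count(lib.records, index)
        assert result.stats.kept == lib.n_reads
        assert result.stats.dropped == 0
        assert result.table.counts == lib.truth_counts

    def test_taqi_closure_robust_to_incomplete_conversion(
        self, small_genome, small_methylome, taqi
    ):
        # every cytosine of TCGA is CpG-context by construction, so a
        # conversion failure can never cut where the index does not predict
        index = cs.find_sites(small_genome, taqi)
        lib = cs.simulate_library(
            small_genome, small_methylome, taqi,
            _clean_params(conversion_efficiency=0.9, n_molecules=4_000),
        )
        result = cs.clean_and_count(lib.records, index)
        assert result.stats.kept == result.stats.input > 0

    def test_sau3ai_conversion_failures_yield_offsite_reads(
        self, small_genome, small_methylome
    ):
        # GATC's terminal cytosine can sit in a non-CpG context; an
        # unconverted one creates a cut the reference prediction lacks, and
        # the cleaner drops exactly those reads
        sau = cs.DEFAULT_ENZYMES["Sau3AI"]
        index = cs.find_sites(small_genome, sau)
        lib = cs.simulate_library(
            small_genome, small_methylome, sau,
            _clean_params(conversion_efficiency=0.9, n_molecules=4_000),
        )
        stats = cs.clean_and_count(lib.records, index).stats
        assert stats.dropped_offsite > 0
        assert stats.dropped_remnant == 0 and stats.dropped_secondary == 0
        assert stats.kept + stats.dropped_offsite == stats.input


class TestExpectedCounts:
    def test_zero_beta_site_expects_zero(self, taqi):
        genome = {"chr1": "T" * 100 + "TCGA" + "T" * 100}
        meth = cs.make_methylome(genome, BetaDistSpec.point_mass(0.0))
        index = cs.find_sites(genome, taqi)
        expected = cs.expected_counts(meth, index, _clean_params(), genome)
        assert all(v == 0.0 for v in expected.values())

    def test_single_dyad_expectation_proportional_to_beta(self, taqi):
        genome = {"chr1": "T" * 100 + "TCGA" + "T" * 100 + "TCGA" + "T" * 100}
        meth = cs.make_methylome(genome, BetaDistSpec.point_mass(1.0))
        meth.betas["chr1"][0] = 0.5  # first site half methylated
        index = cs.find_sites(genome, taqi)
        expected = cs.expected_counts(meth, index, _clean_params(), genome)
        plus = {k: v for k, v in expected.items() if k[1] == "+"}
        vals = [plus[k] for k in sorted(plus)]
        assert vals[0] == pytest.approx(0.5 * vals[1])

    def test_multi_dyad_site_uses_product_rule(self):
        # BstUI interrogates two dyads: survival = beta1 * beta2
        genome = {"chr1": "T" * 100 + "CGCG" + "T" * 100}
        meth = cs.make_methylome(genome, BetaDistSpec.point_mass(0.5))
        index = cs.find_sites(genome, cs.DEFAULT_ENZYMES["BstUI"])
        expected = cs.expected_counts(meth, index, _clean_params(), genome)
        full = cs.expected_counts(
            cs.make_methylome(genome, BetaDistSpec.point_mass(1.0)),
            index, _clean_params(), genome,
        )
        for key in expected:
            assert expected[key] == pytest.approx(0.25 * full[key])

    def test_counts_correlate_with_expectation(self, taqi):
        # expectation is the product form without inter-site competition, so
        # it is exact on a uniform-accessibility genome with isolated sites;
        # depth 200 molecules/locus keeps counting noise below the 0.95 bar
        from conftest import uniform_site_genome

        genome, methylome = uniform_site_genome(n_blocks=100, seed=7)
        index = cs.find_sites(genome, taqi)
        glen = len(genome["chr1"])
        n_mol = int(200 * glen / 325)
        params = _clean_params(n_molecules=n_mol, seed=5)
        lib = cs.simulate_library(genome, methylome, taqi, params)
        expected = cs.expected_counts(methylome, index, params, genome)
        keys = sorted(expected)
        obs = np.array([lib.truth_counts.get(k, 0) for k in keys], dtype=float)
        exp = np.array([expected[k] for k in keys])
        assert np.corrcoef(obs, exp)[0, 1] > 0.95


class TestLibraryOutputs:
    def test_write_produces_parsable_files(self, small_genome, small_methylome, taqi, tmp_path):
        lib = cs.simulate_library(
            small_genome, small_methylome, taqi, _clean_params(n_molecules=300)
        )
        paths = lib.write(tmp_path)
        assert all(p.exists() for p in paths.values())
        fastq_lines = paths["fastq"].read_text().splitlines()
        assert len(fastq_lines) == 4 * len(lib.reads_fastq)
        assert fastq_lines[0].startswith("@") and fastq_lines[2] == "+"
        origins = paths["origins"].read_text().splitlines()
        assert len(origins) == 1 + len(lib.truth_origin)
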