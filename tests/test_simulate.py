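"""Simulator contracts: rates, determinism, inheritance, reads, S-locus."""

import numpy as np
import pandas as pd
import pytest

from hybridseer import simulate as sim
from hybridseer.config import ConfigError, SimulationConfig
from hybridseer.simulate import GSIError, SimulationError, decode_seq, encode_seq


def _cfg(**kw) -> SimulationConfig:
    base = dict(
        genome_length=100_000,
        n_genes=50,
        gene_length_mean=1_000,
        coverage=5.0,
        rng_seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestParents:
    def test_zero_rates_give_identical_parents(self):
        cfg = _cfg(interspecies_divergence=0.0, intraspecies_heterozygosity=0.0)
        m, p, anc = sim.simulate_parents(cfg)
        for g in (m, p):
            assert np.array_equal(g.sequence("a"), anc)
            assert np.array_equal(g.sequence("b"), anc)
            assert len(g.variant_list()) == 0

    def test_divergence_counts_match_binomial_oracle(self):
        # substitution-only run; per-seed counts should concentrate around
        # the Binomial(G, d) mean, and the 20-seed average even more tightly
        G, d = 100_000, 0.01
        mean, sd = G * d, np.sqrt(G * d * (1 - d))
        counts = []
        for seed in range(20):
            cfg = _cfg(
                interspecies_divergence=d,
                intraspecies_heterozygosity=0.0,
                indel_fraction=0.0,
                rng_seed=seed,
            )
            m, p, _ = sim.simulate_parents(cfg)
            counts.append(len(sim.diagnostic_sites(m, p)))
        counts = np.asarray(counts, float)
        assert np.all(np.abs(counts - mean) < 4 * sd)
        assert abs(counts.mean() - mean) < 3 * sd / np.sqrt(len(counts))

    def test_heterozygosity_counts_match_binomial_oracle(self):
        G, h = 100_000, 0.005
        mean, sd = G * h, np.sqrt(G * h * (1 - h))
        counts = []
        for seed in range(20):
            cfg = _cfg(
                interspecies_divergence=0.0,
                intraspecies_heterozygosity=h,
                indel_fraction=0.0,
                rng_seed=seed,
            )
            m, _, _ = sim.simulate_parents(cfg)
            counts.append(len(m.variant_list()))
        counts = np.asarray(counts, float)
        assert abs(counts.mean() - mean) < 3 * sd / np.sqrt(len(counts))

    def test_same_seed_reproduces_fasta_bytes(self, tmp_path):
        for run in ("one", "two"):
            m, _, _ = sim.simulate_parents(_cfg(rng_seed=42))
            m.write_fasta(tmp_path / f"{run}.fasta")
        assert (tmp_path / "one.fasta").read_bytes() == (tmp_path / "two.fasta").read_bytes()

    def test_excessive_rates_rejected(self):
        with pytest.raises(ConfigError, match="no longer identifiable"):
            _cfg(interspecies_divergence=0.3, intraspecies_heterozygosity=0.25)

    def test_variant_list_reconstructs_haplotype_b(self):
        cfg = _cfg(intraspecies_heterozygosity=0.01, indel_fraction=0.3, rng_seed=5)
        m, _, _ = sim.simulate_parents(cfg)
        assert np.array_equal(m.reconstruct_b_from_a(), m.sequence("b"))

    def test_indel_fraction_zero_keeps_haplotype_lengths(self):
        cfg = _cfg(indel_fraction=0.0)
        m, p, anc = sim.simulate_parents(cfg)
        for g in (m, p):
            assert g.hap_length("a") == len(anc)
            assert g.hap_length("b") == len(anc)


class TestOffspring:
    def test_f1_truth_has_one_donor_per_parent(self, small_cross):
        truth = small_cross["truth"]
        assert set(truth.genes["donor_hap_a"]) == {"maternal"}
        assert set(truth.genes["donor_hap_b"]) == {"paternal"}
        assert len(truth.genes) == len(small_cross["genes"])
        assert truth.genes["gene_id"].is_unique

    def test_f1_haplotypes_copy_parent_haplotypes(self, small_cross):
        child = small_cross["child"]
        m, p = small_cross["maternal"], small_cross["paternal"]
        assert any(
            np.array_equal(child.sequence("a"), m.sequence(w)) for w in "ab"
        )
        assert any(
            np.array_equal(child.sequence("b"), p.sequence(w)) for w in "ab"
        )

    def test_bc1_without_recombination_is_single_block(self):
        cfg = _cfg(offspring_type="BC1", bc_recomb_rate=0.0)
        m, p, _ = sim.simulate_parents(cfg)
        genes = sim.emit_gene_annotation(cfg)
        child, truth = sim.simulate_offspring(m, p, cfg, genes=genes)
        assert truth.n_donor_switches() == 0
        assert truth.genes["donor_hap_a"].nunique() == 1
        assert set(truth.genes["donor_hap_b"]) == {"maternal"}

    def test_bc1_switch_count_matches_poisson_oracle(self):
        rate, n_seeds = 2.0, 50
        switches = []
        for seed in range(n_seeds):
            cfg = _cfg(offspring_type="BC1", bc_recomb_rate=rate, rng_seed=seed)
            m, p, _ = sim.simulate_parents(cfg)
            _, truth = sim.simulate_offspring(m, p, cfg)
            switches.append(truth.n_donor_switches())
        mean = np.mean(switches)
        assert abs(mean - rate) < 3 * np.sqrt(rate / n_seeds)

    def test_mismatched_frames_rejected(self):
        m1, _, _ = sim.simulate_parents(_cfg(rng_seed=1))
        _, p2, _ = sim.simulate_parents(_cfg(rng_seed=2))
        with pytest.raises(SimulationError, match="coordinate system"):
            sim.simulate_offspring(m1, p2, _cfg())


class TestGeneAnnotation:
    def test_zero_genes_gives_empty_frame(self):
        cfg = _cfg(n_genes=0)
        assert len(sim.emit_gene_annotation(cfg)) == 0

    def test_intervals_sorted_and_non_overlapping(self, small_cross):
        genes = small_cross["genes"]
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()
        assert (ends > starts).all()
        assert ends[-1] <= small_cross["config"].genome_length

    def test_mean_length_near_target(self):
        cfg = SimulationConfig(
            genome_length=600_000, n_genes=300, gene_length_mean=1_000,
            coverage=1, rng_seed=3,
        )
        genes = sim.emit_gene_annotation(cfg)
        mean = (genes["end"] - genes["start"]).mean()
        assert abs(mean - 1_000) / 1_000 < 0.10

    def test_impossible_placement_raises(self):
        cfg = _cfg()
        object.__setattr__(cfg, "n_genes", 200)
        object.__setattr__(cfg, "gene_length_mean", 1_000)
        with pytest.raises(SimulationError, match="cannot place"):
            sim.emit_gene_annotation(cfg)


class TestReads:
    def test_coverage_conservation(self, small_cross, small_reads):
        cfg = small_cross["config"]
        child = small_cross["child"]
        diploid = child.hap_length("a") + child.hap_length("b")
        realized = small_reads.total_bases / diploid
        assert abs(realized - cfg.coverage) / cfg.coverage < 0.02

    def test_error_free_reads_are_exact_substrings(self):
        cfg = _cfg(error_rate=0.0, coverage=2.0, genome_length=50_000, n_genes=10)
        m, _, _ = sim.simulate_parents(cfg)
        reads = sim.simulate_reads(m, cfg)
        haps = {0: m.sequence("a"), 1: m.sequence("b")}
        for i in range(0, reads.n_reads, 97):
            expect = haps[reads.hap[i]][
                reads.start[i] : reads.start[i] + reads.read_length
            ]
            got = reads.seqs[i]
            if reads.strand[i] == 1:
                got = 3 - got[::-1]
            assert np.array_equal(got, expect)

    def test_fastq_is_wellformed_and_matches_sidecar(self, small_reads, tmp_path):
        fq = tmp_path / "reads.fastq"
        sc = tmp_path / "origin.tsv"
        small_reads.write_fastq(fq)
        small_reads.write_sidecar(sc)
        lines = fq.read_text().splitlines()
        assert len(lines) == 4 * small_reads.n_reads
        for off in range(0, 400, 4):
            assert lines[off].startswith("@")
            assert lines[off + 2] == "+"
            assert len(lines[off + 1]) == len(lines[off + 3])
        back = sim.ReadSet.from_files(fq, sc, small_reads.genome)
        assert np.array_equal(back.seqs, small_reads.seqs)
        assert np.array_equal(back.start, small_reads.start)

    def test_read_length_longer_than_genome_rejected(self):
        with pytest.raises(ConfigError):
            _cfg(genome_length=100, n_genes=0, read_length=150)


class TestSLocus:
    def test_every_accession_heterozygous(self):
        _, truth = sim.simulate_s_locus(12, 8, seed=4)
        for pair in truth.values():
            assert pair[0] != pair[1]

    def test_trio_child_inherits_one_class_per_parent(self):
        pedigree = [("acc05", "acc01", "acc02")]
        _, truth = sim.simulate_s_locus(6, 8, pedigree=pedigree, seed=9)
        child, mother, father = (set(truth[a]) for a in ("acc05", "acc01", "acc02"))
        maternal = child & mother
        paternal = child - mother
        assert len(maternal) >= 1
        assert paternal <= father

    def test_fully_incompatible_pedigree_raises(self):
        # force mother's and father's class pairs to coincide via a chain
        with pytest.raises((GSIError, SimulationError)):
            for seed in range(40):  # some seed must draw identical founder pairs
                sim.simulate_s_locus(
                    2, 2, pedigree=[("acc02", "acc01", "acc01")], seed=seed
                )

    def test_sequence_divergence_contract(self):
        records, truth = sim.simulate_s_locus(4, 4, seed=1)
        from hybridseer.slocus import pairwise_identity

        by_class: dict = {}
        for acc, gene, copy, seq in records:
            label = truth[acc][copy - 1]
            by_class.setdefault((gene, label), []).append(seq)
        within = [
            pairwise_identity(seqs[0], seqs[1])
            for seqs in by_class.values()
            if len(seqs) >= 2
        ]
        labels = sorted({k for k in by_class if k[0] == "S-RNase"})
        between = [
            pairwise_identity(by_class[labels[i]][0], by_class[labels[j]][0])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        assert all(w > 0.995 for w in within)
        assert all(b < 0.95 for b in between)


class TestPanel:
    def test_f1_between_parents_in_allele_counts(self, small_cross):
        cfg = small_cross["config"]
        samples, sites, gts = sim.simulate_panel(
            small_cross["maternal"], small_cross["paternal"], cfg
        )
        assert len(samples) == 6
        assert gts.shape == (6, len(sites), 2)
        # F1s are heterozygous at every called divergence-derived site
        called = (gts[4] >= 0).all(axis=1)
        div = sites.index[called].to_numpy()
        # maternal accessions never carry the paternal-deviant allele
        assert set(np.unique(gts[gts >= 0])) <= {0, 1}

    def test_panel_vcf_roundtrip(self, small_cross, tmp_path):
        from hybridseer.io import write_vcf
        from hybridseer.variome import GenotypeMatrix

        cfg = small_cross["config"]
        samples, sites, gts = sim.simulate_panel(
            small_cross["maternal"], small_cross["paternal"], cfg
        )
        path = tmp_path / "panel.vcf"
        write_vcf(path, samples, sites, gts, contigs={"chr1": cfg.genome_length})
        gm = GenotypeMatrix.from_vcf(path)
        assert gm.samples == samples
        assert gm.n_sites == len(sites)
        assert np.array_equal(np.sort(gm.genotypes, axis=2), np.sort(gts, axis=2))


def test_encode_decode_roundtrip():
    s = "ACGTACGTTTGCA"
    assert decode_seq(encode_seq(s)) == s
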