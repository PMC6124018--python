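"""End-to-end pipeline: simulate, then run every analysis on the outputs.

Stages run in dependency order (simulate feeds kmer/phase/variome/slocus);
each run writes a resolved-config copy and a manifest with per-output
checksums so that deterministic stages can be verified to reproduce
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from hybridseer import __version__, kmer, phasing, simulate, slocus, variome
from hybridseer.config import PipelineConfig
from hybridseer.io import write_newick, write_tsv, write_vcf

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "kmer", "phase", "variome", "slocus")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    stages: list[dict] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def record(self, stage: str, outputs: list[Path], wall_time: float) -> None:
        for p in outputs:
            self.checksums[p.name] = _sha256(p)
        self.stages.append(
            {
                "stage": stage,
                "outputs": [p.name for p in outputs],
                "wall_time_s": round(wall_time, 3),
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "stages": self.stages,
                    "checksums": self.checksums,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = ALL_STAGES,
) -> RunManifest:
    """Execute the selected stages and write outputs under ``config.out_dir``.

    The simulate stage materialises every downstream input (reads, gene
    annotation, pileups, panel VCF, S-allele FASTA); later stages read those
    files back, so partial re-runs see exactly what a file-based user would.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    manifest = RunManifest()
    manifest.checksums["resolved_config.yaml"] = _sha256(out / "resolved_config.yaml")

    try:
        for stage in ALL_STAGES:
            if stage not in stages:
                continue
            t0 = time.monotonic()
            outputs = _STAGE_FUNCS[stage](config, out)
            manifest.record(stage, outputs, time.monotonic() - t0)
            logger.info("stage %s done (%.1fs)", stage, time.monotonic() - t0)
    finally:
        manifest.write(out / "manifest.json")
    return manifest


def _stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    sim = config.simulate
    maternal, paternal, _anc = simulate.simulate_parents(sim)
    genes = simulate.emit_gene_annotation(sim)
    child, truth = simulate.simulate_offspring(maternal, paternal, sim, genes=genes)
    reads_child = simulate.simulate_reads(child, sim)
    inputs = simulate.make_phasing_inputs(maternal, paternal, child, truth, genes, sim)
    vconf = config.variome
    samples, sites, gts = simulate.simulate_panel(
        maternal,
        paternal,
        sim,
        n_maternal=vconf.get("n_per_group", 2),
        n_paternal=vconf.get("n_per_group", 2),
        n_f1=vconf.get("n_per_group", 2),
    )
    sconf = config.slocus
    n_acc = sconf.get("n_accessions", 12)
    records, s_truth = simulate.simulate_s_locus(
        accessions=n_acc,
        pool_size=sconf.get("pool_size", 8),
        seed=sim.rng_seed,
    )
    truth.true_s_haplotypes = s_truth

    paths = {
        "maternal.fasta": lambda p: maternal.write_fasta(p),
        "paternal.fasta": lambda p: paternal.write_fasta(p),
        "child.fasta": lambda p: child.write_fasta(p),
        "genes.gff3": lambda p: simulate.write_genes_gff3(p, genes),
        "child_reads.fastq": lambda p: reads_child.write_fastq(p),
        "child_reads_origin.tsv": lambda p: reads_child.write_sidecar(p),
        "truth_genes.tsv": lambda p: truth.to_tsv(p),
        "pileup.tsv": lambda p: phasing.write_pileup_tsv(p, inputs.sites),
        "gene_coverage.tsv": lambda p: write_tsv(p, inputs.coverage),
        "phasing_truth.tsv": lambda p: write_tsv(p, inputs.truth),
        "panel.vcf": lambda p: write_vcf(
            p, samples, sites, gts,
            contigs={maternal.seq_name: sim.genome_length},
        ),
        "s_alleles.fasta": lambda p: simulate.write_s_allele_fasta(p, records),
        "s_truth.tsv": lambda p: write_tsv(
            p,
            pd.DataFrame(
                [(a, c1, c2) for a, (c1, c2) in sorted(s_truth.items())],
                columns=["accession", "class1", "class2"],
            ),
        ),
    }
    written = []
    for name, writer in paths.items():
        writer(out / name)
        written.append(out / name)
    return written


def _stage_kmer(config: PipelineConfig, out: Path) -> list[Path]:
    kconf = config.kmer
    spectrum = kmer.count_kmers(
        out / "child_reads.fastq",
        k=kconf.get("k", kmer.DEFAULT_K),
        max_multiplicity=kconf.get("max_multiplicity", kmer.DEFAULT_MAX_MULTIPLICITY),
    )
    spectrum.to_tsv(out / "spectrum.tsv")
    peaks = kmer.fit_peaks(spectrum)
    kmer.estimate_genome_size(spectrum, peaks, basis=kconf.get("basis", "kmers"))
    with open(out / "peaks.json", "w") as fh:
        json.dump(peaks.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [out / "spectrum.tsv", out / "peaks.json"]


def _stage_phase(config: PipelineConfig, out: Path) -> list[Path]:
    from hybridseer.io import read_gff3, read_tsv, write_bed

    pconf = config.phase
    genes = read_gff3(out / "genes.gff3")
    sites = phasing.read_pileup_tsv(out / "pileup.tsv")
    coverage = read_tsv(out / "gene_coverage.tsv")
    evidence = phasing.collect_evidence(
        genes, sites, coverage=coverage, min_depth=pconf.get("min_depth", 2)
    )
    calls = phasing.classify_all(
        evidence,
        fold=pconf.get("fold", 2.0),
        min_support=pconf.get("min_support", 1),
        min_breadth=pconf.get("min_breadth", 0.5),
    )
    phasing.write_calls_tsv(out / "phase_calls.tsv", calls, params=pconf)
    summary = phasing.summarize(calls)
    write_tsv(out / "phase_summary.tsv", summary.to_frame())
    track = phasing.paint_chromosomes(calls)
    write_bed(out / "phase_track.bed", track, extra_cols=["call"])
    return [out / "phase_calls.tsv", out / "phase_summary.tsv", out / "phase_track.bed"]


def _stage_variome(config: PipelineConfig, out: Path) -> list[Path]:
    vconf = config.variome
    gm = variome.GenotypeMatrix.from_vcf(out / "panel.vcf")
    if vconf.get("snps_only", False):
        gm = gm.snps_only()
    write_tsv(out / "variome_summary.tsv", variome.summarize_variome(gm))
    dm = variome.allele_distance(gm, normalize=vconf.get("normalize", False))
    dm.to_tsv(out / "distances.tsv")
    coords = variome.classical_mds(dm, dims=2)
    variome.write_mds_tsv(out / "mds.tsv", coords)
    write_newick(out / "tree.nwk", variome.nj_tree(dm))
    return [
        out / "variome_summary.tsv", out / "distances.tsv",
        out / "mds.tsv", out / "tree.nwk",
    ]


def _stage_slocus(config: PipelineConfig, out: Path) -> list[Path]:
    sconf = config.slocus
    alleles = slocus.parse_allele_fasta(out / "s_alleles.fasta")
    assignment = slocus.cluster_alleles(
        alleles, identity_threshold=sconf.get("identity_threshold", 0.99)
    )
    assignment.to_tsv(out / "s_assignments.tsv")
    g = slocus.build_network(assignment)
    slocus.write_edges_tsv(out / "s_edges.tsv", g)
    slocus.write_graphml(out / "s_network.graphml", g)
    return [out / "s_assignments.tsv", out / "s_edges.tsv", out / "s_network.graphml"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "kmer": _stage_kmer,
    "phase": _stage_phase,
    "variome": _stage_variome,
    "slocus": _stage_slocus,
}
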