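"""End-to-end orchestration of the synthetic-community pipeline.

``run_pipeline`` executes the stages in dependency order — simulate,
reduce-db, classify-reads, contig-tax, recruit, ani, morphometrics — inside
a run directory, with every stage's outputs written in standard formats and
a manifest recording seeds, per-stage counts, and SHA-256 digests of every
output file. All randomness flows from one master seed through per-stage
derived seeds, so identical configs produce byte-identical outputs and
toggling one stage off leaves the others unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as pio
from .ani import ani_matrix, clusters_to_frame, species_clusters
from .classify import assignments_to_frame, classify_reads
from .contigs import assign_table
from .morphometrics import biomass_share, population_summary
from .recruitment import profiles_to_frame, recruitment_profile
from .reduce import greedy_cluster
from .sequences import mutate
from .synthetic import (CellPopulationSpec, CommunitySpec, Read, ReferenceDB,
                        class_ancestors, evolve_reference_db, mutate_genome,
                        simulate_cells, simulate_gene_hit_table,
                        simulate_genome, simulate_reads)

_STAGES = ("simulate", "reduce_db", "classify", "contig_tax", "recruit",
           "ani", "morphometrics")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the published cutoffs."""

    seed: int = 0
    outdir: str = "pelagiq_run"
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})

    # synthetic community
    root_length: int = 1200
    n_classes: int = 5
    per_class_divergence: float = 0.16
    seqs_per_class: int = 3
    n_reads: int = 2000
    read_length: int = 100
    error_rate: float = 0.005
    focal_phylum: str = "Bac_P01"
    focal_cluster: str = "Bac_CL01"
    focal_fraction: float = 0.10

    # screening / classification
    cluster_threshold: float = 0.85
    screen_evalue: float = 1e-5
    max_reads: int = 10_000_000
    min_identity: float = 80.0
    min_aln: int = 90

    # contig taxonomy
    contig_min_length: int = 5000
    n_contigs: int = 40

    # recruitment
    genome_length: int = 12_000
    recruit_min_len: int = 50
    recruit_min_identity: float = 95.0
    recruit_evalue: float = 1e-5
    n_genome_reads: int = 300
    genome_read_divergence: float = 0.01

    # ANI / species
    ani_frag_len: int = 1020
    ani_min_id: float = 70.0
    ani_min_cov: float = 0.7
    species_threshold: float = 95.0
    ani_divergences: tuple = (0.02, 0.10)

    # morphometrics
    n_focal_cells: int = 150
    n_background_cells: int = 850

    def __post_init__(self) -> None:
        if not 0 < self.cluster_threshold < 1:
            raise ValueError("cluster_threshold must be in (0, 1)")
        for name in ("screen_evalue", "recruit_evalue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")
        if self.genome_length < self.ani_frag_len:
            raise ValueError("genome_length must be >= ani_frag_len")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["ani_divergences"] = list(self.ani_divergences)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "ani_divergences" in data:
            data["ani_divergences"] = tuple(data["ani_divergences"])
        return cls(**data)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    ss = np.random.SeedSequence(master, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _genome_reads(genome_seq: str, n_reads: int, read_length: int,
                  divergence: float, seed: int, prefix: str) -> list[Read]:
    """Reads sampled from a diverged copy of a genome (species-level noise)."""
    rng = np.random.default_rng(seed)
    diverged, _ = mutate(genome_seq, divergence, rng)
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, len(diverged) - read_length + 1))
        reads.append(Read(f"{prefix}{i:06d}",
                          diverged[start:start + read_length]))
    return reads


def _build_references(cfg: RunConfig):
    seed = stage_seed(cfg.seed, "simulate")
    bacteria = evolve_reference_db(
        root_length=cfg.root_length, n_classes=cfg.n_classes,
        per_class_divergence=cfg.per_class_divergence,
        seqs_per_class=cfg.seqs_per_class, seed=seed, domain="Bacteria",
        n_phyla=2, label_prefix="Bac")
    archaea = evolve_reference_db(
        root_length=cfg.root_length, n_classes=2,
        per_class_divergence=cfg.per_class_divergence, seqs_per_class=2,
        seed=seed + 1, domain="Archaea", n_phyla=1, label_prefix="Arc")
    eukaryota = evolve_reference_db(
        root_length=cfg.root_length, n_classes=2,
        per_class_divergence=cfg.per_class_divergence, seqs_per_class=2,
        seed=seed + 2, domain="Eukaryota", n_phyla=1, label_prefix="Euk")
    full_db = bacteria.merged_with(archaea).merged_with(eukaryota)
    domain_refs = {"Archaea": class_ancestors(archaea),
                   "Bacteria": class_ancestors(bacteria),
                   "Eukaryota": class_ancestors(eukaryota)}
    return full_db, domain_refs


def default_community(cfg: RunConfig, full_db: ReferenceDB) -> CommunitySpec:
    """Focal cluster at ``focal_fraction``; the rest spread evenly over the
    remaining bacterial clusters."""
    clusters = sorted(c for c in full_db.by_cluster if c.startswith("Bac_"))
    others = [c for c in clusters if c != cfg.focal_cluster]
    fractions = {cfg.focal_cluster: cfg.focal_fraction}
    rest = (1.0 - cfg.focal_fraction) / len(others)
    for c in others:
        fractions[c] = rest
    return CommunitySpec(fractions=fractions, n_reads=cfg.n_reads,
                         read_length=cfg.read_length,
                         error_rate=cfg.error_rate,
                         seed=stage_seed(cfg.seed, "simulate") + 10)


def run_pipeline(config: RunConfig) -> Path:
    """Run all enabled stages; returns the run directory.

    Fails fast with the stage name when a required input stage is disabled
    and its outputs are absent.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "files": {}}
    on = {s: config.stages.get(s, True) for s in _STAGES}

    full_db = domain_refs = reads = truth = None
    genome = None
    cells = None

    if on["simulate"]:
        sim_seed = stage_seed(config.seed, "simulate")
        full_db, domain_refs = _build_references(config)
        spec = default_community(config, full_db)
        reads, truth = simulate_reads(full_db, spec)
        genome = simulate_genome(
            config.genome_length, seed=sim_seed + 20, genome_id="genomeA",
            rrna_intervals=[(1000, 2500)])
        cells = simulate_cells([
            CellPopulationSpec(
                label="focal", shape="rod", n_cells=config.n_focal_cells,
                length_dist=("normal", {"mean": 0.92, "sd": 0.2}),
                width_dist=("normal", {"mean": 0.28, "sd": 0.04}),
                seed=sim_seed + 30),
            CellPopulationSpec(
                label="background", shape="sphere",
                n_cells=config.n_background_cells,
                length_dist=("lognormal", {"mean": -1.15, "sd": 0.35}),
                seed=sim_seed + 31),
        ])
        gene_hits = simulate_gene_hit_table(
            config.n_contigs, config.focal_phylum,
            ["Bac_P02", "Other_P01"], seed=sim_seed + 40)
        pio.write_reference_fasta(full_db, outdir / "references.fasta",
                                  seed=sim_seed)
        pio.write_reads_fastq(reads, outdir / "reads.fastq")
        pio.write_tsv(truth, outdir / "truth.tsv", seed=spec.seed)
        pio.write_genome_fasta(genome, outdir / "genomeA.fasta")
        pio.write_intervals_bed(genome.id, genome.rrna_intervals,
                                outdir / "genomeA.rrna.bed")
        pio.write_tsv(cells, outdir / "cells.tsv", seed=sim_seed + 30)
        pio.write_tsv(gene_hits, outdir / "gene_hits.tsv", seed=sim_seed + 40)
        manifest["stages"]["simulate"] = {
            "seed": sim_seed, "n_references": len(full_db),
            "n_reads": len(reads), "n_cells": int(len(cells))}

    reduced = None
    if on["reduce_db"]:
        if full_db is None:
            _require(outdir / "references.fasta", "reduce_db")
            full_db = pio.read_reference_fasta(outdir / "references.fasta")
        reduced = greedy_cluster(full_db, config.cluster_threshold)
        pio.write_tsv(reduced.to_frame(), outdir / "membership.tsv")
        pio.write_reference_fasta(ReferenceDB(reduced.centroids),
                                  outdir / "centroids.fasta")
        manifest["stages"]["reduce_db"] = {
            "n_input": len(full_db), "n_centroids": len(reduced.centroids),
            "threshold": config.cluster_threshold}

    if on["classify"]:
        for dep, obj in (("simulate", reads), ("reduce_db", reduced)):
            if obj is None:
                raise RuntimeError(
                    f"stage 'classify' requires outputs of stage '{dep}'")
        assignments, prof, counts = classify_reads(
            reads, reduced, full_db, domain_refs, config.focal_phylum,
            evalue_cutoff=config.screen_evalue,
            min_identity=config.min_identity, min_aln=config.min_aln,
            max_reads=config.max_reads)
        pio.write_tsv(assignments_to_frame(assignments),
                      outdir / "assignments.tsv")
        pio.write_tsv(prof.to_frame(), outdir / "profile.tsv")
        profile_json = {
            "denominator": prof.denominator,
            "focal_phylum": prof.focal_phylum,
            "taxa": {t: {"reads": n, "pct": p}
                     for t, (n, p) in sorted(prof.taxa.items())},
            "subclusters": dict(sorted(prof.subclusters.items())),
        }
        (outdir / "profile.json").write_text(
            json.dumps(profile_json, indent=2) + "\n")
        manifest["stages"]["classify"] = {
            "examined": counts.examined, "candidates": counts.candidates,
            "assigned": counts.assigned, "by_domain": counts.by_domain,
            "discarded": counts.discarded}

    if on["contig_tax"]:
        path = outdir / "gene_hits.tsv"
        _require(path, "contig_tax")
        calls = assign_table(pio.read_tsv(path), config.focal_phylum,
                             config.contig_min_length)
        pio.write_tsv(calls, outdir / "contig_calls.tsv")
        manifest["stages"]["contig_tax"] = {
            "n_contigs": int(len(calls)),
            "decisions": calls["decision"].value_counts().to_dict()}

    if on["recruit"]:
        if genome is None:
            _require(outdir / "genomeA.fasta", "recruit")
            genome = pio.read_genome_fasta(outdir / "genomeA.fasta",
                                           outdir / "genomeA.rrna.bed")
        greads = _genome_reads(genome.sequence, config.n_genome_reads,
                               config.read_length,
                               config.genome_read_divergence,
                               stage_seed(config.seed, "recruit"), "gread")
        profile_, hits = recruitment_profile(
            genome, greads, metagenome_id="synthetic_metagenome",
            min_len=config.recruit_min_len,
            min_identity=config.recruit_min_identity,
            evalue_cutoff=config.recruit_evalue)
        from .align import hits_to_outfmt6
        pio.write_tsv(hits_to_outfmt6(hits), outdir / "recruit_hits.tsv")
        pio.write_tsv(profiles_to_frame([profile_]), outdir / "rpkg.tsv")
        manifest["stages"]["recruit"] = {
            "n_reads": len(greads), "n_hits": profile_.n_hits,
            "rpkg": profile_.rpkg}

    if on["ani"]:
        if genome is None:
            _require(outdir / "genomeA.fasta", "ani")
            genome = pio.read_genome_fasta(outdir / "genomeA.fasta")
        ani_seed = stage_seed(config.seed, "ani")
        genomes = {genome.id: genome.sequence}
        for d in config.ani_divergences:
            mut = mutate_genome(genome, d, seed=ani_seed + int(d * 1000))
            genomes[mut.id] = mut.sequence
        matrix = ani_matrix(genomes, config.ani_frag_len, config.ani_min_id,
                            config.ani_min_cov)
        clusters = species_clusters(matrix, config.species_threshold)
        matrix.values.round(4).to_csv(outdir / "ani_matrix.tsv", sep="\t")
        pio.write_tsv(clusters_to_frame(clusters), outdir / "species.tsv")
        manifest["stages"]["ani"] = {
            "n_genomes": len(genomes), "n_species": len(clusters.clusters)}

    if on["morphometrics"]:
        if cells is None:
            _require(outdir / "cells.tsv", "morphometrics")
            cells = pio.read_tsv(outdir / "cells.tsv")
        share = biomass_share(cells, "focal")
        summary = {
            "focal": population_summary(cells, "focal"),
            "all": {**(population_summary(
                cells.assign(population="all"), "all") or {})},
            "abundance_pct": share.abundance_pct,
            "biomass_pct": share.biomass_pct,
            "biomass_to_abundance_ratio": share.ratio,
        }
        (outdir / "morphometrics.json").write_text(
            json.dumps(summary, indent=2) + "\n")
        manifest["stages"]["morphometrics"] = {
            "n_cells": int(len(cells)), "ratio": share.ratio}

    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["files"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return outdir


def _require(path: Path, stage: str) -> None:
    if not path.exists():
        raise RuntimeError(f"stage '{stage}' missing required input: {path}")
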