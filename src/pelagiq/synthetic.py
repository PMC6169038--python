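"""Synthetic community generation: every input the pipeline needs.

Produces lineage-annotated 16S reference databases, metagenomic read sets
drawn from communities with known class-level composition, genome pairs at
controlled nucleotide divergence, and cell-size populations — each with a
fixed seed and an emitted truth table, so downstream stages can be scored
against known ground truth.

The substitution process everywhere is uniform replacement by one of the 3
alternative bases (Jukes–Cantor-like), giving the analytic identity oracle
``P(site equal) = (1-d1)(1-d2) + d1*d2/3`` for two sequences at divergences
d1, d2 from a common ancestor. Reads carry i.i.d. substitution errors only
(no indels, chimeras, or quality models). All coordinates are 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import mutate, random_dna, revcomp

TRUTH_COLUMNS = ["read_id", "source_id", "domain", "phylum", "class", "cluster"]

DOMAIN_BACTERIA = "Bacteria"
DOMAIN_ARCHAEA = "Archaea"
DOMAIN_EUKARYOTA = "Eukaryota"


@dataclass(frozen=True)
class TaxonLineage:
    """A nested domain -> phylum -> class -> (optional) sub-cluster lineage."""

    domain: str
    phylum: str
    class_: str
    cluster: str | None = None

    def __post_init__(self) -> None:
        for rank in (self.domain, self.phylum, self.class_):
            if not rank:
                raise ValueError("lineage labels must be non-empty")
        if self.cluster is not None and not self.cluster:
            raise ValueError("cluster label must be non-empty when present")


@dataclass
class RefSequenceRecord:
    """One lineage-annotated reference 16S/18S sequence."""

    id: str
    sequence: str
    lineage: TaxonLineage

    def __post_init__(self) -> None:
        if len(self.sequence) < 500:
            raise ValueError("synthetic 16S reference must be >= 500 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference alphabet restricted to A/C/G/T")


class ReferenceDB:
    """An ordered collection of reference records with lookup indices."""

    def __init__(self, records: list[RefSequenceRecord]):
        if not records:
            raise ValueError("empty reference database")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids")
        self.records = list(records)
        self.by_id = {r.id: r for r in records}
        self.by_cluster: dict[str, list[RefSequenceRecord]] = {}
        for r in records:
            if r.lineage.cluster is not None:
                self.by_cluster.setdefault(r.lineage.cluster, []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def total_nt(self) -> int:
        return sum(len(r.sequence) for r in self.records)

    def merged_with(self, other: "ReferenceDB") -> "ReferenceDB":
        return ReferenceDB(self.records + other.records)


@dataclass
class Read:
    id: str
    sequence: str


@dataclass(frozen=True)
class CommunitySpec:
    """Composition and sequencing parameters of a simulated read set.

    ``fractions`` maps sub-cluster labels (keys of ``ReferenceDB.by_cluster``)
    to their share of the read pool; they must sum to 1. ``error_rate`` is the
    per-base substitution probability.
    """

    fractions: dict[str, float]
    n_reads: int
    read_length: int = 100
    error_rate: float = 0.005
    seed: int = 0
    revcomp_fraction: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if not 0.0 <= self.revcomp_fraction <= 1.0:
            raise ValueError("revcomp_fraction must be in [0, 1]")


@dataclass
class SimGenome:
    """A simulated genome with rRNA and gene interval annotations.

    Intervals are 0-based half-open. ``gene_intervals`` entries are
    ``(start, end, true_taxon)``; ``n_substitutions`` records the realized
    substitution count when the genome came out of :func:`mutate_genome`.
    """

    id: str
    sequence: str
    rrna_intervals: list[tuple[int, int]] = field(default_factory=list)
    gene_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    n_substitutions: int | None = None

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for s, e in self.rrna_intervals:
            if not 0 <= s <= e <= L:
                raise ValueError(f"rRNA interval [{s}, {e}) out of bounds")
        for s, e, _ in self.gene_intervals:
            if not 0 <= s <= e <= L:
                raise ValueError(f"gene interval [{s}, {e}) out of bounds")
        ordered = sorted(self.rrna_intervals)
        for (s1, e1), (s2, e2) in zip(ordered[:-1], ordered[1:]):
            if s2 < e1:
                raise ValueError("rRNA intervals must be pairwise disjoint")


@dataclass(frozen=True)
class CellPopulationSpec:
    """One measured cell population for the morphometrics simulator.

    ``length_dist``/``width_dist`` are ``(name, params)`` pairs with name in
    {"normal", "lognormal", "fixed"}; parameters are in micrometres
    (for "lognormal" they are the log-scale mean/sd).
    """

    label: str
    shape: str
    n_cells: int
    length_dist: tuple[str, dict]
    width_dist: tuple[str, dict] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("rod", "sphere", "ovoid"):
            raise ValueError("shape must be rod, sphere, or ovoid")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.shape != "sphere" and self.width_dist is None:
            raise ValueError("rods/ovoids need a width distribution")


def evolve_reference_db(root_length: int = 1500, n_classes: int = 4,
                        per_class_divergence: float = 0.10,
                        seqs_per_class: int = 5, seed: int = 0, *,
                        domain: str = DOMAIN_BACTERIA, n_phyla: int = 2,
                        within_class_factor: float = 0.2,
                        label_prefix: str | None = None) -> ReferenceDB:
    """Evolve a star-topology reference database with known lineages.

    A random root sequence spawns ``n_classes`` class ancestors, each at
    ``per_class_divergence`` substitutions/site from the root; every class
    then spawns ``seqs_per_class`` leaves at
    ``per_class_divergence * within_class_factor`` from its ancestor, so
    within-class identity exceeds between-class identity in expectation.
    Classes are assigned round-robin to ``n_phyla`` phyla and each class
    carries one sub-cluster label. Deterministic for a fixed seed.
    """
    if not 0.0 <= per_class_divergence < 0.5:
        raise ValueError("per_class_divergence must be in [0, 0.5)")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_phyla < 1 or n_phyla > n_classes:
        raise ValueError("n_phyla must be in [1, n_classes]")
    if root_length < 500:
        raise ValueError("root_length must be >= 500")
    prefix = label_prefix if label_prefix is not None else domain[:3]
    rng = np.random.default_rng(seed)
    root = random_dna(root_length, rng)
    records: list[RefSequenceRecord] = []
    within = per_class_divergence * within_class_factor
    for c in range(n_classes):
        ancestor, _ = mutate(root, per_class_divergence, rng)
        lineage = TaxonLineage(
            domain=domain,
            phylum=f"{prefix}_P{c % n_phyla + 1:02d}",
            class_=f"{prefix}_C{c + 1:02d}",
            cluster=f"{prefix}_CL{c + 1:02d}",
        )
        for k in range(seqs_per_class):
            leaf, _ = mutate(ancestor, within, rng)
            records.append(RefSequenceRecord(
                id=f"{lineage.cluster}_seq{k + 1:03d}",
                sequence=leaf, lineage=lineage))
    return ReferenceDB(records)


def class_ancestors(db: ReferenceDB) -> list[RefSequenceRecord]:
    """One representative (the first leaf) per class, for domain validation."""
    seen: dict[str, RefSequenceRecord] = {}
    for r in db:
        seen.setdefault(r.lineage.class_, r)
    return list(seen.values())


def simulate_reads(db: ReferenceDB, spec: CommunitySpec) -> tuple[list[Read], pd.DataFrame]:
    """Draw a read set from a community with known composition.

    Per-taxon counts are a multinomial draw from ``spec.fractions``; each
    read is a uniformly placed forward-strand substring of a uniformly chosen
    reference of its cluster (reverse-complemented with probability
    ``spec.revcomp_fraction``), with i.i.d. substitution errors at
    ``spec.error_rate``. Returns the reads and a truth table with one row per
    read in fixed column order.
    """
    missing = [k for k in spec.fractions if k not in db.by_cluster]
    if missing:
        raise KeyError(f"unknown cluster labels in fractions: {missing}")
    min_len = min(len(r.sequence) for r in db)
    if spec.read_length > min_len:
        raise ValueError("read_length exceeds shortest reference")
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.fractions)
    counts = rng.multinomial(spec.n_reads, [spec.fractions[l] for l in labels])
    reads: list[Read] = []
    rows = []
    idx = 0
    for label, count in zip(labels, counts):
        members = db.by_cluster[label]
        for _ in range(count):
            src = members[rng.integers(0, len(members))]
            start = int(rng.integers(0, len(src.sequence) - spec.read_length + 1))
            seq = src.sequence[start:start + spec.read_length]
            if spec.error_rate > 0:
                seq, _ = mutate(seq, spec.error_rate, rng)
            if spec.revcomp_fraction > 0 and rng.random() < spec.revcomp_fraction:
                seq = revcomp(seq)
            read_id = f"read{idx:07d}"
            reads.append(Read(read_id, seq))
            lin = src.lineage
            rows.append((read_id, src.id, lin.domain, lin.phylum, lin.class_,
                         lin.cluster))
            idx += 1
    # interleave deterministically so read order does not encode the taxon
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame([rows[i] for i in order], columns=TRUTH_COLUMNS)
    return reads, truth


def simulate_genome(length: int, seed: int = 0, *, genome_id: str = "genome",
                    rrna_intervals: list[tuple[int, int]] | None = None) -> SimGenome:
    """A uniform random genome with optional rRNA interval annotations."""
    rng = np.random.default_rng(seed)
    return SimGenome(id=genome_id, sequence=random_dna(length, rng),
                     rrna_intervals=list(rrna_intervals or []))


def mutate_genome(genome: SimGenome, divergence: float, seed: int = 0) -> SimGenome:
    """Per-site substitution at the given rate; annotations carried over.

    Length and all interval annotations are preserved exactly; the realized
    substitution count is recorded on the returned genome.
    """
    if not 0.0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    seq, n_sub = mutate(genome.sequence, divergence, rng)
    return SimGenome(id=f"{genome.id}_div{divergence:g}", sequence=seq,
                     rrna_intervals=list(genome.rrna_intervals),
                     gene_intervals=list(genome.gene_intervals),
                     n_substitutions=n_sub)


_MAX_RESAMPLE = 1000


def _sample_positive(dist: tuple[str, dict], n: int, rng: np.random.Generator) -> np.ndarray:
    name, params = dist
    out = np.empty(n)
    filled = 0
    for _ in range(_MAX_RESAMPLE):
        need = n - filled
        if name == "normal":
            draw = rng.normal(params["mean"], params["sd"], size=need)
        elif name == "lognormal":
            draw = rng.lognormal(params["mean"], params["sd"], size=need)
        elif name == "fixed":
            draw = np.full(need, float(params["value"]))
        else:
            raise ValueError(f"unknown distribution {name!r}")
        ok = draw > 0
        out[filled:filled + int(ok.sum())] = draw[ok]
        filled += int(ok.sum())
        if filled == n:
            return out
    raise ValueError(f"could not sample positive dimensions from {dist!r}")


def simulate_cells(pops: list[CellPopulationSpec]) -> pd.DataFrame:
    """Sample a cell-measurement table, one row per cell.

    Columns: cell_id, population, shape, length_um, width_um. For spheres the
    width equals the length (the diameter). For rods/ovoids, pairs with
    width > length are resampled (bounded retries). Deterministic per
    population seed.
    """
    if not pops:
        raise ValueError("need at least one population")
    frames = []
    for p in pops:
        rng = np.random.default_rng(p.seed)
        if p.shape == "sphere":
            d = _sample_positive(p.length_dist, p.n_cells, rng)
            length, width = d, d.copy()
        else:
            length = _sample_positive(p.length_dist, p.n_cells, rng)
            width = _sample_positive(p.width_dist, p.n_cells, rng)
            for _ in range(_MAX_RESAMPLE):
                bad = width > length
                if not bad.any():
                    break
                nbad = int(bad.sum())
                length[bad] = _sample_positive(p.length_dist, nbad, rng)
                width[bad] = _sample_positive(p.width_dist, nbad, rng)
            else:
                raise ValueError(
                    f"population {p.label!r}: could not sample length >= width")
        frames.append(pd.DataFrame({
            "cell_id": [f"{p.label}_cell{i + 1:05d}" for i in range(p.n_cells)],
            "population": p.label,
            "shape": p.shape,
            "length_um": length,
            "width_um": width,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_gene_hit_table(n_contigs: int, target_phylum: str,
                            other_phyla: list[str], seed: int = 0, *,
                            target_fraction: float = 0.5,
                            max_genes: int = 20,
                            min_length: int = 1000,
                            max_length: int = 50_000) -> pd.DataFrame:
    """Random per-gene best-hit tables for the contig-taxonomy stage.

    Each contig gets a random length, gene count, and per-gene best-hit
    phylum (target with probability ``target_fraction``, otherwise a uniform
    other phylum or no hit). Columns: contig_id, contig_length, gene_id,
    best_hit_phylum ("" for no hit).
    """
    rng = np.random.default_rng(seed)
    rows = []
    pool = list(other_phyla) + [""]
    for c in range(n_contigs):
        cid = f"contig{c + 1:05d}"
        clen = int(rng.integers(min_length, max_length + 1))
        for g in range(int(rng.integers(1, max_genes + 1))):
            if rng.random() < target_fraction:
                hit = target_phylum
            else:
                hit = pool[rng.integers(0, len(pool))]
            rows.append((cid, clen, f"{cid}_g{g + 1:03d}", hit))
    return pd.DataFrame(rows, columns=["contig_id", "contig_length",
                                       "gene_id", "best_hit_phylum"])
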