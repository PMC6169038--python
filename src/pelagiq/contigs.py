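"""Contig taxonomy by majority vote over per-gene best hits.

A contig is assigned to the target phylum when it is longer than the length
cutoff (strictly greater than 5 kb by default) and strictly more than half
of its genes *with* best hits point at that phylum. Genes without any hit
are excluded from the denominator; an exact tie is not a majority.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

ASSIGNED = "assigned"
UNASSIGNED = "unassigned"
TOO_SHORT = "too_short"


@dataclass
class ContigGeneHits:
    """Per-gene best-hit phyla for one contig; None/"" marks a hitless gene."""

    contig_id: str
    contig_length: int
    gene_hits: list[tuple[str, str | None]]

    def __post_init__(self) -> None:
        if self.contig_length <= 0:
            raise ValueError("contig_length must be positive")
        gene_ids = [g for g, _ in self.gene_hits]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError(f"duplicate gene ids on contig {self.contig_id}")


@dataclass
class ContigCall:
    contig_id: str
    decision: str  # assigned | unassigned | too_short
    n_genes: int
    n_genes_with_hits: int
    n_target_hits: int


def assign_contig(hits: ContigGeneHits, target_phylum: str,
                  min_length: int = 5000) -> ContigCall:
    """Majority-vote phylum assignment for one contig.

    ``too_short`` when contig_length <= min_length (the cutoff is strict:
    "longer than"); otherwise ``assigned`` iff at least one gene has a hit
    and strictly more than half of the genes with hits best-hit the target
    phylum.
    """
    n_genes = len(hits.gene_hits)
    with_hits = [p for _, p in hits.gene_hits if p]
    n_target = sum(1 for p in with_hits if p == target_phylum)
    if hits.contig_length <= min_length:
        decision = TOO_SHORT
    elif with_hits and 2 * n_target > len(with_hits):
        decision = ASSIGNED
    else:
        decision = UNASSIGNED
    return ContigCall(hits.contig_id, decision, n_genes, len(with_hits),
                      n_target)


def assign_table(table: pd.DataFrame, target_phylum: str,
                 min_length: int = 5000) -> pd.DataFrame:
    """Apply :func:`assign_contig` to a long-format gene-hit table.

    Expects columns contig_id, contig_length, gene_id, best_hit_phylum
    (empty/NaN = no hit). Returns one row per contig with the decision and
    vote counts.
    """
    rows = []
    for contig_id, group in table.groupby("contig_id", sort=True):
        lengths = group["contig_length"].unique()
        if len(lengths) != 1:
            raise ValueError(f"inconsistent lengths for contig {contig_id}")
        gene_hits = [
            (str(g), None if pd.isna(p) or p == "" else str(p))
            for g, p in zip(group["gene_id"], group["best_hit_phylum"])
        ]
        call = assign_contig(
            ContigGeneHits(str(contig_id), int(lengths[0]), gene_hits),
            target_phylum, min_length)
        rows.append((call.contig_id, int(lengths[0]), call.decision,
                     call.n_genes, call.n_genes_with_hits, call.n_target_hits))
    return pd.DataFrame(rows, columns=[
        "contig_id", "contig_length", "decision", "n_genes",
        "n_genes_with_hits", "n_target_hits"])
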