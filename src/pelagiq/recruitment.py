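"""rRNA-masked metagenomic fragment recruitment and RPKG.

Recruitment estimates a genome's abundance in a metagenome by aligning every
read against the genome (rRNA intervals hard-masked to N so that conserved
rRNA cannot inflate counts) and keeping at most one best hit per read when it
is at least 50 bp long, above 95% identity (strict), and at e-value <= 1e-5.
Counts are normalized to RPKG: reads recruited per kilobase of genome per
gigabase of metagenome.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import (DEFAULT_SCHEME, AlignmentHit, ScoringScheme, SubjectIndex,
                    align_to_subject, best_scores, evalue)
from .synthetic import Read, SimGenome


@dataclass
class RecruitmentProfile:
    """Hit count and RPKG for one genome x metagenome pair."""

    genome_id: str
    metagenome_id: str
    n_hits: int
    genome_length: int
    metagenome_size: int
    rpkg: float


def mask_rrna(genome: SimGenome) -> str:
    """Replace bases inside the genome's rRNA intervals with N.

    Length is preserved; interval validity is enforced by ``SimGenome``.
    """
    if not genome.rrna_intervals:
        return genome.sequence
    chars = list(genome.sequence)
    for s, e in genome.rrna_intervals:
        chars[s:e] = "N" * (e - s)
    return "".join(chars)


def rpkg(n_hits: int, genome_length: int, metagenome_size: int) -> float:
    """Reads per kilobase of genome per gigabase of metagenome."""
    if genome_length <= 0 or metagenome_size <= 0:
        raise ValueError("genome_length and metagenome_size must be positive")
    if n_hits < 0:
        raise ValueError("n_hits must be non-negative")
    return n_hits / (genome_length / 1e3) / (metagenome_size / 1e9)


def recruit(reads: list[Read], masked_genome: str, *, genome_id: str = "genome",
            min_len: int = 50, min_identity: float = 95.0,
            evalue_cutoff: float = 1e-5,
            scheme: ScoringScheme = DEFAULT_SCHEME) -> list[AlignmentHit]:
    """Best-hit-per-read recruitment against one masked genome.

    A read contributes (at most one) hit iff its best local alignment has
    aln_length >= min_len, identity strictly greater than min_identity, and
    e-value <= evalue_cutoff. The e-value database size is the genome length.
    """
    if not masked_genome:
        raise ValueError("empty genome sequence")
    index = SubjectIndex([(genome_id, masked_genome)])
    n = len(masked_genome)
    hits: list[AlignmentHit] = []
    for read in reads:
        scores, t_ends, strands = best_scores(read.sequence, index, scheme)
        score = int(scores[0])
        if score <= 0 or evalue(score, len(read.sequence), n, scheme) > evalue_cutoff:
            continue
        hit = align_to_subject(read.sequence, index, 0, str(strands[0]),
                               int(t_ends[0]), score, scheme,
                               query_id=read.id, db_len=n)
        if hit.aln_length >= min_len and hit.identity_pct > min_identity:
            hits.append(hit)
    return hits


def recruitment_profile(genome: SimGenome, reads: list[Read], *,
                        metagenome_id: str = "metagenome",
                        metagenome_size: int | None = None,
                        min_len: int = 50, min_identity: float = 95.0,
                        evalue_cutoff: float = 1e-5,
                        scheme: ScoringScheme = DEFAULT_SCHEME,
                        ) -> tuple[RecruitmentProfile, list[AlignmentHit]]:
    """Mask, recruit, and normalize in one step.

    ``metagenome_size`` defaults to the total bases in the read set. The
    normalizing genome length is the full (unmasked) genome length.
    """
    masked = mask_rrna(genome)
    hits = recruit(reads, masked, genome_id=genome.id, min_len=min_len,
                   min_identity=min_identity, evalue_cutoff=evalue_cutoff,
                   scheme=scheme)
    size = (metagenome_size if metagenome_size is not None
            else sum(len(r.sequence) for r in reads))
    prof = RecruitmentProfile(
        genome_id=genome.id, metagenome_id=metagenome_id, n_hits=len(hits),
        genome_length=len(genome.sequence), metagenome_size=size,
        rpkg=rpkg(len(hits), len(genome.sequence), size))
    return prof, hits


def profiles_to_frame(profiles: list[RecruitmentProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.genome_id, p.metagenome_id, p.n_hits, p.genome_length,
          p.metagenome_size, p.rpkg) for p in profiles],
        columns=["genome_id", "metagenome_id", "n_hits", "genome_length",
                 "metagenome_size", "rpkg"])
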