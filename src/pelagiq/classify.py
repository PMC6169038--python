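"""Two-stage 16S rRNA read classification and community profiling.

Stage 1 (screen): reads are compared against the reduced centroid database;
a read is a 16S candidate iff its best hit has e-value <= 1e-5 (at most the
first ``max_reads`` reads of a dataset are examined, default 10 million).

Stage 2: candidates are segregated into archaeal / bacterial / eukaryotic
rRNA or non-rRNA by their best hit among pooled domain-representative
sequences, then prokaryotic candidates are compared against the complete
reference database and assigned the taxon of the best-bit-score hit if the
alignment has identity >= 80% and length >= 90 bp; failures are discarded
with a reason.

The community profile expresses each class as a percentage of the
prokaryotic denominator (archaeal + bacterial reads that received a taxon)
and further splits a focal phylum by the best-hit sub-cluster label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import (DEFAULT_SCHEME, AlignmentHit, ScoringScheme, SubjectIndex,
                    align_to_subject, best_scores, evalue)
from .synthetic import Read, RefSequenceRecord, ReferenceDB, TaxonLineage

DOMAIN_CALLS = ("archaeal", "bacterial", "eukaryotic", "non_rrna")

_DOMAIN_CALL = {"Archaea": "archaeal", "Bacteria": "bacterial",
                "Eukaryota": "eukaryotic"}


@dataclass
class CandidateRead:
    """A screened read: candidate iff best-hit e-value passed the cutoff."""

    read: Read
    best_screen_hit: AlignmentHit | None
    passed_screen: bool
    domain_call: str | None = None
    domain_ambiguous: bool = False


@dataclass
class TaxAssignment:
    """Final classification of one read."""

    read_id: str
    domain_call: str
    assigned_taxon: TaxonLineage | None
    identity_pct: float | None = None
    aln_length: int | None = None
    best_subject_id: str | None = None
    discarded: bool = False
    reason: str | None = None  # low_identity | short_alignment | non_prokaryotic


@dataclass
class CommunityProfile:
    """Per-class percentages of the prokaryotic read pool.

    ``taxa`` maps class label -> (reads, pct of prokaryotes); ``subclusters``
    maps sub-cluster label -> reads for the focal phylum only.
    """

    taxa: dict[str, tuple[int, float]]
    denominator: int
    focal_phylum: str
    subclusters: dict[str, int] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.denominator == 0

    def pct(self, class_label: str) -> float:
        return self.taxa.get(class_label, (0, 0.0))[1]

    def subcluster_pct(self, cluster_label: str) -> float:
        """Sub-cluster reads as a percentage of the prokaryotic pool."""
        if self.denominator == 0:
            return 0.0
        return 100.0 * self.subclusters.get(cluster_label, 0) / self.denominator

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t, n, p) for t, (n, p) in sorted(self.taxa.items())],
            columns=["taxon", "reads", "pct_of_prokaryotes"])


def _db_index(db: ReferenceDB) -> SubjectIndex:
    return SubjectIndex([(r.id, r.sequence) for r in db])


def _records_index(records: list[RefSequenceRecord]) -> SubjectIndex:
    return SubjectIndex([(r.id, r.sequence) for r in records])


def screen(reads: list[Read], reduced, evalue_cutoff: float = 1e-5,
           max_reads: int = 10_000_000,
           scheme: ScoringScheme = DEFAULT_SCHEME) -> list[CandidateRead]:
    """Screen reads against the reduced centroid database.

    At most ``max_reads`` reads are examined (all of them when the dataset is
    smaller). The database size for the e-value is the total nucleotide count
    of the centroid set. Returns one :class:`CandidateRead` per examined read.
    """
    if not reads:
        return []
    index = _records_index(reduced.centroids)
    out: list[CandidateRead] = []
    for read in reads[:max_reads]:
        scores, t_ends, strands = best_scores(read.sequence, index, scheme)
        best = int(scores.argmax())
        score = int(scores[best])
        if score <= 0:
            out.append(CandidateRead(read, None, False))
            continue
        e = evalue(score, len(read.sequence), index.total_nt, scheme)
        passed = e <= evalue_cutoff
        hit = align_to_subject(read.sequence, index, best, str(strands[best]),
                               int(t_ends[best]), score, scheme,
                               query_id=read.id, db_len=index.total_nt)
        out.append(CandidateRead(read, hit, passed))
    return out


def validate_domain(candidates: list[CandidateRead],
                    domain_references: dict[str, list[RefSequenceRecord]],
                    evalue_cutoff: float = 1e-5,
                    scheme: ScoringScheme = DEFAULT_SCHEME) -> list[CandidateRead]:
    """Assign each candidate to the domain of its best pooled-reference hit.

    ``domain_references`` must contain non-empty "Archaea", "Bacteria", and
    "Eukaryota" sets. A read whose best hit fails the e-value cutoff is
    called ``non_rrna``. An exact score tie between two domains is broken by
    pool order and flagged ``domain_ambiguous``. Domain calls are written
    onto the candidates, which are returned for chaining.
    """
    for dom in ("Archaea", "Bacteria", "Eukaryota"):
        if not domain_references.get(dom):
            raise ValueError(f"missing domain reference set: {dom}")
    pooled: list[RefSequenceRecord] = []
    domains: list[str] = []
    for dom in ("Archaea", "Bacteria", "Eukaryota"):
        for rec in domain_references[dom]:
            pooled.append(rec)
            domains.append(dom)
    index = _records_index(pooled)
    for cand in candidates:
        if not cand.passed_screen:
            cand.domain_call = "non_rrna"
            continue
        scores, _, _ = best_scores(cand.read.sequence, index, scheme)
        best = int(scores.argmax())
        score = int(scores[best])
        if score <= 0 or evalue(score, len(cand.read.sequence),
                                index.total_nt, scheme) > evalue_cutoff:
            cand.domain_call = "non_rrna"
            continue
        cand.domain_call = _DOMAIN_CALL[domains[best]]
        tied_domains = {domains[i] for i in np.nonzero(scores == score)[0]}
        cand.domain_ambiguous = len(tied_domains) > 1
    return candidates


def classify(validated: list[CandidateRead], full_db: ReferenceDB,
             min_identity: float = 80.0, min_aln: int = 90,
             scheme: ScoringScheme = DEFAULT_SCHEME) -> list[TaxAssignment]:
    """Classify validated prokaryotic candidates against the full database.

    The winner is the best-bit-score hit (ties broken by higher identity,
    then lexicographic subject id). Reads failing the identity or
    alignment-length threshold are discarded with a reason; non-prokaryotic
    candidates are discarded as ``non_prokaryotic``.
    """
    if len(full_db) == 0:
        raise ValueError("empty full database")
    index = _db_index(full_db)
    out: list[TaxAssignment] = []
    for cand in validated:
        call = cand.domain_call or "non_rrna"
        if call not in ("archaeal", "bacterial"):
            out.append(TaxAssignment(cand.read.id, call, None, discarded=True,
                                     reason="non_prokaryotic"))
            continue
        scores, t_ends, strands = best_scores(cand.read.sequence, index, scheme)
        top = int(scores.max())
        if top <= 0:
            out.append(TaxAssignment(cand.read.id, call, None, discarded=True,
                                     reason="low_identity"))
            continue
        tied = np.nonzero(scores == top)[0]
        hits = [align_to_subject(cand.read.sequence, index, int(i),
                                 str(strands[i]), int(t_ends[i]), top, scheme,
                                 query_id=cand.read.id, db_len=index.total_nt)
                for i in tied]
        hit = min(hits, key=lambda h: (-h.identity_pct, h.subject_id))
        if hit.identity_pct < min_identity:
            out.append(TaxAssignment(cand.read.id, call, None,
                                     identity_pct=hit.identity_pct,
                                     aln_length=hit.aln_length,
                                     best_subject_id=hit.subject_id,
                                     discarded=True, reason="low_identity"))
        elif hit.aln_length < min_aln:
            out.append(TaxAssignment(cand.read.id, call, None,
                                     identity_pct=hit.identity_pct,
                                     aln_length=hit.aln_length,
                                     best_subject_id=hit.subject_id,
                                     discarded=True, reason="short_alignment"))
        else:
            out.append(TaxAssignment(cand.read.id, call,
                                     full_db.by_id[hit.subject_id].lineage,
                                     identity_pct=hit.identity_pct,
                                     aln_length=hit.aln_length,
                                     best_subject_id=hit.subject_id))
    return out


def profile(assignments: list[TaxAssignment],
            focal_phylum: str) -> CommunityProfile:
    """Community profile over assigned prokaryotic reads.

    Percentages are per class label over the prokaryotic denominator; reads
    of the focal phylum are additionally split by best-hit sub-cluster label.
    A zero denominator yields an explicit empty profile.
    """
    prok = [a for a in assignments if a.assigned_taxon is not None
            and a.domain_call in ("archaeal", "bacterial")]
    denom = len(prok)
    if denom == 0:
        return CommunityProfile(taxa={}, denominator=0,
                                focal_phylum=focal_phylum)
    counts: dict[str, int] = {}
    subclusters: dict[str, int] = {}
    for a in prok:
        lin = a.assigned_taxon
        counts[lin.class_] = counts.get(lin.class_, 0) + 1
        if lin.phylum == focal_phylum:
            label = lin.cluster if lin.cluster is not None else lin.class_
            subclusters[label] = subclusters.get(label, 0) + 1
    taxa = {c: (n, 100.0 * n / denom) for c, n in counts.items()}
    return CommunityProfile(taxa=taxa, denominator=denom,
                            focal_phylum=focal_phylum, subclusters=subclusters)


@dataclass
class StageCounts:
    total_reads: int
    examined: int
    candidates: int
    by_domain: dict[str, int]
    assigned: int
    discarded: dict[str, int]


def classify_reads(reads: list[Read], reduced, full_db: ReferenceDB,
                   domain_references: dict[str, list[RefSequenceRecord]],
                   focal_phylum: str, *, evalue_cutoff: float = 1e-5,
                   min_identity: float = 80.0, min_aln: int = 90,
                   max_reads: int = 10_000_000,
                   scheme: ScoringScheme = DEFAULT_SCHEME):
    """Run screen -> validate -> classify -> profile end to end.

    Returns ``(assignments, profile, stage_counts)``.
    """
    cands = screen(reads, reduced, evalue_cutoff, max_reads, scheme)
    validate_domain(cands, domain_references, evalue_cutoff, scheme)
    passed = [c for c in cands if c.passed_screen]
    assignments = classify(passed, full_db, min_identity, min_aln, scheme)
    prof = profile(assignments, focal_phylum)
    discarded: dict[str, int] = {}
    for a in assignments:
        if a.discarded:
            discarded[a.reason] = discarded.get(a.reason, 0) + 1
    counts = StageCounts(
        total_reads=len(reads), examined=min(len(reads), max_reads),
        candidates=len(passed),
        by_domain={d: sum(1 for c in cands if c.domain_call == d)
                   for d in DOMAIN_CALLS},
        assigned=sum(1 for a in assignments if a.assigned_taxon is not None),
        discarded=discarded)
    return assignments, prof, counts


def assignments_to_frame(assignments: list[TaxAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        lin = a.assigned_taxon
        rows.append((a.read_id, a.domain_call,
                     lin.phylum if lin else "", lin.class_ if lin else "",
                     (lin.cluster or "") if lin else "",
                     a.identity_pct, a.aln_length, a.best_subject_id or "",
                     a.discarded, a.reason or ""))
    return pd.DataFrame(rows, columns=[
        "read_id", "domain_call", "phylum", "class", "cluster",
        "identity_pct", "aln_length", "best_subject_id", "discarded", "reason"])
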