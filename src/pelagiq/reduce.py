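"""Reduced screening database by greedy centroid clustering.

Mirrors the UCLUST-style reduction used to shrink a large 16S reference set
before read screening: sequences are processed in length-descending order
(ties by id); each joins the first existing centroid it matches at or above
the identity threshold, otherwise it founds a new centroid.

Identity between a sequence and a centroid is computed from the local
alignment engine as identical columns divided by the length of the shorter
sequence, so that a short spurious high-identity span cannot satisfy the
threshold — the alignment must also cover most of the shorter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import DEFAULT_SCHEME, ScoringScheme, local_align
from .synthetic import RefSequenceRecord, ReferenceDB


@dataclass
class ReducedDB:
    """Centroids plus the member -> centroid mapping of a greedy clustering."""

    centroids: list[RefSequenceRecord]
    membership: dict[str, str]
    threshold: float
    identities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        centroid_ids = {c.id for c in self.centroids}
        for member, centroid in self.membership.items():
            if centroid not in centroid_ids:
                raise ValueError(f"member {member} maps to unknown centroid")
        for cid in centroid_ids:
            if self.membership.get(cid) != cid:
                raise ValueError(f"centroid {cid} must map to itself")

    @property
    def total_nt(self) -> int:
        return sum(len(c.sequence) for c in self.centroids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m, c, self.identities.get(m, float("nan")))
             for m, c in self.membership.items()],
            columns=["member_id", "centroid_id", "identity"])


def cluster_identity(a: str, b: str,
                     scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """UCLUST-like identity: identical columns / length of the shorter
    sequence, from the best local alignment (both strands)."""
    hit = local_align(a, b, scheme)
    if hit is None:
        return 0.0
    return hit.n_identical / min(len(a), len(b))


def greedy_cluster(db: ReferenceDB, threshold: float = 0.85,
                   scheme: ScoringScheme = DEFAULT_SCHEME) -> ReducedDB:
    """Greedy centroid clustering at a nucleotide-identity threshold.

    Deterministic: input is sorted length-descending (ties by id) and each
    sequence joins the FIRST centroid, in creation order, whose identity is
    >= threshold. Every resulting member satisfies
    ``identity(member, centroid) >= threshold`` and every centroid has
    identity < threshold to all earlier centroids.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if len(db) == 0:
        raise ValueError("empty reference database")
    ordered = sorted(db.records, key=lambda r: (-len(r.sequence), r.id))
    centroids: list[RefSequenceRecord] = []
    membership: dict[str, str] = {}
    identities: dict[str, float] = {}
    for rec in ordered:
        placed = False
        for cen in centroids:
            ident = cluster_identity(rec.sequence, cen.sequence, scheme)
            if ident >= threshold:
                membership[rec.id] = cen.id
                identities[rec.id] = ident
                placed = True
                break
        if not placed:
            centroids.append(rec)
            membership[rec.id] = rec.id
            identities[rec.id] = 1.0
    return ReducedDB(centroids=centroids, membership=membership,
                     threshold=threshold, identities=identities)
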