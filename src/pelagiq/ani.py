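"""Fragment-based average nucleotide identity and species clustering.

ANI follows the classical fragment-based definition: one genome is cut into
consecutive 1020-nt fragments (the trailing short fragment is discarded),
each fragment is locally aligned to the other genome, and fragments are kept
when the alignment has >= 70% identity over >= 70% of the fragment length.
The directed ANI is the mean identity of kept fragments; the reported ANI is
the arithmetic mean of the two directions and is undefined when either
direction keeps no fragment. Genomes sharing > 95% ANI are grouped into one
species by single-linkage transitive closure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import DEFAULT_SCHEME, ScoringScheme, local_align


@dataclass
class ANIMatrix:
    """Symmetric pairwise ANI (%) with per-ordered-pair fragment counts.

    ``values.loc[i, j]`` is NaN when no fragment passed the filters in at
    least one direction.
    """

    genome_ids: list[str]
    values: pd.DataFrame
    n_fragments_used: dict[tuple[str, str], int] = field(default_factory=dict)


@dataclass
class SpeciesClusters:
    """A disjoint, exhaustive partition of genome ids at an ANI threshold."""

    clusters: list[list[str]]
    threshold: float

    def cluster_of(self, genome_id: str) -> list[str]:
        for c in self.clusters:
            if genome_id in c:
                return c
        raise KeyError(genome_id)


def directed_ani(genome_a: str, genome_b: str, frag_len: int = 1020,
                 min_id: float = 70.0, min_cov: float = 0.7,
                 scheme: ScoringScheme = DEFAULT_SCHEME) -> tuple[float | None, int]:
    """Mean identity of genome_a fragments aligned to genome_b.

    Returns ``(ani or None, n fragments kept)``.
    """
    if len(genome_a) < frag_len or len(genome_b) < frag_len:
        raise ValueError(f"genomes must be at least {frag_len} nt")
    identities = []
    for start in range(0, len(genome_a) - frag_len + 1, frag_len):
        frag = genome_a[start:start + frag_len]
        hit = local_align(frag, genome_b, scheme)
        if hit is None:
            continue
        if hit.identity_pct >= min_id and hit.aln_length >= min_cov * frag_len:
            identities.append(hit.identity_pct)
    if not identities:
        return None, 0
    return float(np.mean(identities)), len(identities)


def ani(genome_a: str, genome_b: str, frag_len: int = 1020,
        min_id: float = 70.0, min_cov: float = 0.7,
        scheme: ScoringScheme = DEFAULT_SCHEME) -> float | None:
    """Symmetric ANI: mean of the two directed values, or None if undefined."""
    fwd, n_fwd = directed_ani(genome_a, genome_b, frag_len, min_id, min_cov, scheme)
    rev, n_rev = directed_ani(genome_b, genome_a, frag_len, min_id, min_cov, scheme)
    if fwd is None or rev is None:
        return None
    return (fwd + rev) / 2.0


def ani_matrix(genomes: dict[str, str], frag_len: int = 1020,
               min_id: float = 70.0, min_cov: float = 0.7,
               scheme: ScoringScheme = DEFAULT_SCHEME) -> ANIMatrix:
    """All-vs-all symmetric ANI matrix; the diagonal is exactly 100."""
    ids = list(genomes)
    values = pd.DataFrame(np.full((len(ids), len(ids)), np.nan),
                          index=ids, columns=ids)
    n_frags: dict[tuple[str, str], int] = {}
    for gid in ids:
        values.loc[gid, gid] = 100.0
    for a, b in itertools.combinations(ids, 2):
        fwd, n_fwd = directed_ani(genomes[a], genomes[b], frag_len, min_id,
                                  min_cov, scheme)
        rev, n_rev = directed_ani(genomes[b], genomes[a], frag_len, min_id,
                                  min_cov, scheme)
        n_frags[(a, b)] = n_fwd
        n_frags[(b, a)] = n_rev
        if fwd is not None and rev is not None:
            values.loc[a, b] = values.loc[b, a] = (fwd + rev) / 2.0
    return ANIMatrix(genome_ids=ids, values=values, n_fragments_used=n_frags)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def species_clusters(matrix: ANIMatrix, threshold: float = 95.0) -> SpeciesClusters:
    """Single-linkage species grouping: transitive closure of ANI > threshold.

    Pairs with undefined ANI contribute no edge. Clusters and their members
    are returned in deterministic sorted order.
    """
    uf = _UnionFind(matrix.genome_ids)
    for a, b in itertools.combinations(matrix.genome_ids, 2):
        v = matrix.values.loc[a, b]
        if pd.notna(v) and v > threshold:
            uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for gid in matrix.genome_ids:
        groups.setdefault(uf.find(gid), []).append(gid)
    clusters = sorted((sorted(members) for members in groups.values()),
                      key=lambda c: c[0])
    return SpeciesClusters(clusters=clusters, threshold=threshold)


def clusters_to_frame(sc: SpeciesClusters) -> pd.DataFrame:
    rows = [(f"species_{i + 1:03d}", gid)
            for i, members in enumerate(sc.clusters) for gid in members]
    return pd.DataFrame(rows, columns=["species", "genome_id"])
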