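# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `pelagiq`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Alignment engine

Every stage (screening, domain validation, classification, recruitment,
ANI, clustering identity) uses one exact local-alignment engine:
Smith–Waterman with affine gaps, searching both strands and returning the
better one (forward wins ties).

* **Scoring**: match +1, mismatch −2, gap open 2, gap extend 1. A gap of
  length k costs `open + k·extend` (the BLAST convention — the opening
  penalty is charged on top of extension for the first gap position). These
  are fixed, documented stand-ins for BLASTN defaults; exact NCBI
  statistics are out of scope, and the constants exist to make e-values
  reproducible, not to reproduce BLAST output bit-for-bit.
* **Statistics**: e-value E = K·m·n·exp(−λS) with λ = 1.28, K = 0.46,
  m = query length, n = total nucleotides in the searched database;
  bit score = (λS − ln K)/ln 2.
* **Identity**: identical columns / all alignment columns, gap columns
  included (BLAST convention), so the published thresholds keep their
  original semantics.
* **N handling**: N matches nothing, including another N; masked regions
  therefore score as mismatch runs and cannot seed hits.
* **Implementation**: a numba-compiled score-only kernel (Gotoh recurrence,
  int32) finds the optimal score and its end cell; the full alignment is
  recovered by Biopython's `PairwiseAligner`, configured to the identical
  convention, on the subject window `[end − 2m − 8, end)`. With these
  penalties an optimal local alignment with positive score spans fewer than
  2m subject positions, so the window always contains it; the two scores
  are asserted equal on every call. Tests additionally check the kernel
  against an independent exhaustive DP oracle on ≤ 100-nt pairs.
* **Tie-breaking**: among co-optimal cells the kernel keeps the leftmost
  subject end (scan order); among co-optimal tracebacks Biopython's first
  path is used. This is deterministic engine order; enumerating all
  co-optimal paths to impose a leftmost-start rule can be exponential and
  is deliberately avoided.

## Synthetic community generator

The generator defines the study conditions for all end-to-end tests. It
emulates the *structure* of the real inputs — a taxonomically annotated 16S
reference database, shotgun read sets with known class composition, genome
pairs at controlled divergence, cell-size populations — not their biological
content.

* **Substitution process**: uniform replacement by one of the 3 alternative
  bases (Jukes–Cantor-like). Two sequences at divergences d₁, d₂ from a
  common ancestor agree per site with probability (1−d₁)(1−d₂) + d₁d₂/3,
  the analytic oracle used in tests.
* **Reference databases**: a star topology — one random root, class
  ancestors at `per_class_divergence` from it, leaves at
  `per_class_divergence × 0.2` from their ancestor. Defaults: 1500-nt roots
  (full-length 16S; end-to-end tests use 800–1200 nt for speed, still
  above the 500-nt minimum for the format), between-class branch
  divergence 0.16, which realizes ≈ 29% pairwise between-class divergence
  and ≈ 6% within-class — comfortably separated at the 85% clustering and
  80% classification thresholds, as real class-level 16S divergence is.
  Phyla are assigned to classes round-robin; phylum membership is a label
  hierarchy, not a similarity statement.
* **Reads**: uniform start positions on the forward strand (a flag enables
  50% reverse-complement), 100 nt (short-read regime consistent with the
  ≥ 90 bp alignment-length rule), per-base substitution errors at 0.005
  (typical modern short-read error scale), counts multinomial in the
  specified fractions, read order shuffled so position does not encode the
  taxon. Truth tables have fixed column order
  (read_id, source_id, domain, phylum, class, cluster).
* **Genomes**: uniform random sequence with 0-based half-open rRNA/gene
  intervals; `mutate_genome` preserves length and annotations exactly and
  records the realized substitution count.
* **Cells**: normal / lognormal / fixed dimension distributions (µm);
  rod/ovoid pairs with width > length are resampled (bounded retries).
  The demo population uses rods of mean length 0.92 µm and width 0.28 µm
  for the focal lineage against a background of smaller spheres
  (log-median ≈ 0.32 µm diameter), reflecting that the emulated lineage is
  distinctly larger than the ambient community.
* Not modelled: indels, chimeras, amplicon primer bias, quality-score
  error models, GC/coverage bias, real phylogenetic tree shapes. Passing
  tests therefore demonstrate correctness of the decision rules and
  arithmetic under clean substitution-only divergence, not robustness to
  every artefact of real sequencing.

## Stage conventions

* **Greedy clustering**: sequences processed length-descending (ties by
  id); a sequence joins the first centroid with identity ≥ threshold
  (default 0.85). Identity here is identical columns / length of the
  shorter sequence: a raw per-column identity over a short local span is
  near 100% for any pair and would collapse unrelated sequences, so
  coverage of the shorter sequence is built into the metric (UCLUST-like).
  On the substitution-only synthetic data this equals Hamming identity,
  which is what the brute-force oracle checks.
* **Screening**: e-value cutoff 1e−5 against the centroid set; at most the
  first 10 million reads examined (all reads when fewer).
* **Domain validation**: best hit among pooled per-domain representatives
  (first sequence of each class), called non-rRNA when the best hit fails
  the same 1e−5 cutoff. The published workflow used a covariance-model
  tool for this step; an alignment-based vote is a documented, testable
  approximation and fidelity to that tool is a non-goal. Exact
  archaeal/bacterial score ties are broken by pool order and flagged
  `domain_ambiguous`.
* **Classification**: winner = best bit score; ties by higher identity,
  then lexicographic subject id. Thresholds: identity ≥ 80%, alignment
  ≥ 90 bp; failures are discarded with reason (low_identity,
  short_alignment, non_prokaryotic). Profile percentages are over the
  prokaryotic denominator: archaeal + bacterial reads that received a
  taxon; eukaryotic and non-rRNA reads are excluded.
* **Contig votes**: "longer than 5 kb" is strict (> 5000 nt). The majority
  is computed over genes *with* hits; hitless genes leave the denominator
  (the alternative — counting them as votes against — is stricter than the
  stated rule); a tie is not a majority. No minimum gene count is imposed.
* **Recruitment**: filters aln_length ≥ 50 bp, identity > 95% (strict, per
  the printed ">"), e-value ≤ 1e−5 with n = genome length; one best hit
  per read. The RPKG genome length is the full genome including masked
  bases (masking suppresses spurious rRNA hits; the normalization is per
  genome kilobase), and metagenome size is total bases in the read set.
  Note an inherent property of local-alignment filtering: a read at, say,
  10% per-site divergence is overwhelmingly rejected, but can occasionally
  trim to a low-error ≥ 50 bp subspan above 95% identity and survive —
  BLASTN-based recruitment behaves identically. The deterministic guarantee
  (and the tested one) is that reads with no ≥ 50 bp window above 95%
  identity are always rejected.
* **ANI**: 1020-nt consecutive fragments (trailing remainder discarded),
  fragment kept at identity ≥ 70% over ≥ 70% of fragment length; directed
  ANI = mean identity of kept fragments; reported ANI = arithmetic mean of
  the two directions (the underlying definition is directional, single
  values are reported per pair), undefined if either direction keeps
  nothing. Species = single-linkage closure over pairs with ANI > 95%,
  matching the convention that any > 95% pair shares a species.
* **Morphometrics**: biovolume formulas as in the README; the rod formula
  degenerates continuously to the sphere at l = w. Percentiles (5th,
  median, 95th) use linear interpolation between order statistics. Biomass
  is proxied by biovolume (constant density); an allometric carbon
  conversion (C = 218·V^0.86 fg) is provided but off by default, since the
  partitioning statements are about biovolume shares. The external
  microscopy workflow that produced the real measurements does not print
  its exact volume formula; the cylinder-with-hemispherical-caps model is
  the standard in that literature and is the documented choice here.

## Orchestration and reproducibility

All randomness derives from one master seed via `numpy.random.SeedSequence`
spawn keys per stage (derived seeds < 2³¹), so re-running with the same
config is byte-identical (verified by manifest SHA-256 digests) and
toggling a stage off leaves other stages' outputs unchanged. Configuration
is a single YAML block with CLI flags overriding it; every output table can
carry its generating seed as a leading comment line.

## Problem sizes

End-to-end checks run on deliberately desk-scale inputs chosen as the
package's own defaults: reference databases of 15–30 sequences of
0.8–1.5 kb across 3–9 classes, read sets of 60–10,000 reads of 100 nt,
genomes of 10–100 kb, and 1000-cell measurement tables. The largest single
computation — classifying 10,000 reads through screen, validation, and
full-database assignment — recovers a 10% focal-cluster fraction within 3
binomial standard errors and runs in a few minutes on one CPU.

## Known limitations

* E-values use fixed λ, K rather than per-scheme Karlin–Altschul fits; they
  are internally consistent, not NCBI-comparable.
* No heuristic seeding: alignment cost is O(mn), so the engine is meant for
  the desk-scale databases above, not for screening real 10⁷-read datasets
  against SILVA-scale references.
* The greedy clustering does not reproduce USEARCH internals (k-mer
  acceleration, its exact identity definition); only the documented
  semantics above.
* Domain validation is a best-hit vote, not a covariance/HMM model.
* The cell-volume median of a real population depends on the (unpublished)
  measurement workflow's formula; only the documented formula is
  implemented.
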