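"""Reading and writing the standard formats used by the pipeline.

FASTA/FASTQ go through Biopython; tables are TSV via pandas. Reference
lineages are carried in FASTA description fields as
``domain=...;phylum=...;class=...;cluster=...`` and round-trip exactly.
Interval files are BED-like 3-column TSV with 0-based half-open coordinates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import Read, RefSequenceRecord, ReferenceDB, SimGenome, TaxonLineage

FASTQ_QUALITY = 40  # constant Sanger Phred+33 quality for simulated reads


def _lineage_description(lineage: TaxonLineage) -> str:
    parts = [f"domain={lineage.domain}", f"phylum={lineage.phylum}",
             f"class={lineage.class_}"]
    if lineage.cluster is not None:
        parts.append(f"cluster={lineage.cluster}")
    return ";".join(parts)


def _parse_lineage(description: str) -> TaxonLineage:
    fields = {}
    for token in description.split():
        if "=" in token and ";" in token:
            for part in token.split(";"):
                k, _, v = part.partition("=")
                fields[k] = v
    try:
        return TaxonLineage(domain=fields["domain"], phylum=fields["phylum"],
                            class_=fields["class"],
                            cluster=fields.get("cluster"))
    except KeyError as exc:
        raise ValueError(f"FASTA header lacks lineage field {exc}") from exc


def write_reference_fasta(db: ReferenceDB, path: str | Path,
                          seed: int | None = None) -> None:
    records = []
    for r in db:
        desc = _lineage_description(r.lineage)
        if seed is not None:
            desc += f" seed={seed}"
        records.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path: str | Path) -> ReferenceDB:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(RefSequenceRecord(
            id=rec.id, sequence=str(rec.seq).upper(),
            lineage=_parse_lineage(rec.description)))
    return ReferenceDB(records)


def write_reads_fastq(reads: list[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [FASTQ_QUALITY] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_reads_fasta(reads: list[Read], path: str | Path) -> None:
    SeqIO.write((SeqRecord(Seq(r.sequence), id=r.id, description="")
                 for r in reads), str(path), "fasta")


def read_reads(path: str | Path) -> list[Read]:
    """Read FASTA or FASTQ (sniffed from the first character)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [Read(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), fmt)]


def write_genome_fasta(genome: SimGenome, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(path), "fasta")


def read_genome_fasta(path: str | Path,
                      bed_path: str | Path | None = None) -> SimGenome:
    rec = next(SeqIO.parse(str(path), "fasta"))
    intervals = read_intervals_bed(bed_path) if bed_path else []
    return SimGenome(id=rec.id, sequence=str(rec.seq).upper(),
                     rrna_intervals=intervals)


def write_intervals_bed(genome_id: str, intervals: list[tuple[int, int]],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{genome_id}\t{s}\t{e}\n")


def read_intervals_bed(path: str | Path) -> list[tuple[int, int]]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            _, start, end = line.split("\t")[:3]
            intervals.append((int(start), int(end)))
    return intervals


def write_tsv(df: pd.DataFrame, path: str | Path,
              seed: int | None = None) -> None:
    """Write a TSV table, optionally recording the generating seed as a
    leading comment line."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
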