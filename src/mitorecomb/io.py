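"""Readers and writers for the pipeline's file formats.

Formats (exact column orders are documented in ``docs/formats.md``):

* genome: single-record FASTA (circular) + contig table TSV
  (``contig_id  start  end  depth``, 0-based half-open, depth optional);
* repeat annotations: TSV
  (``repeat_id  orientation  locus1_start  locus1_end  locus2_start
  locus2_end  composite``), optional BED6 export (two lines per repeat);
* assembly graph: GFA 1.0 (``S`` lines with ``DP``/``dp`` depth tags,
  ``L`` lines for links);
* alignments: PAF (minimap2 dialect, columns 1-12 + optional tags;
  ``tp:A:P`` marks primary records; target names ``<repeat>|<path>``);
* labels / counts / report: TSV.

FASTA/FASTQ go through Biopython and are transparently gzip-aware.
"""

from __future__ import annotations

import gzip
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .read_support import AlignmentRecord, SupportLabel
from .recomb_stats import SupportCounts
from .repeat_model import (
    CircularGenome,
    Contig,
    GenomeGraph,
    GraphLink,
    GraphNode,
    Locus,
    RepeatPair,
    revcomp,
)

__all__ = [
    "read_genome",
    "write_genome",
    "load_repeat_annotations",
    "write_repeat_annotations",
    "repeat_annotations_to_bed6",
    "read_gfa",
    "read_paf",
    "write_reads_fastq",
    "read_reads",
    "write_labels",
    "read_labels",
    "write_counts",
    "read_counts",
    "load_published_support",
]

REPEAT_COLUMNS = [
    "repeat_id",
    "orientation",
    "locus1_start",
    "locus1_end",
    "locus2_start",
    "locus2_end",
    "composite",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Genome + contig table
# ---------------------------------------------------------------------------


def read_genome(fasta_path: str | Path, contigs_path: str | Path) -> CircularGenome:
    with _open_text(fasta_path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single circular record, got {len(records)}")
    table = pd.read_csv(contigs_path, sep="\t")
    contigs = [
        Contig(
            id=str(row.contig_id),
            start=int(row.start),
            end=int(row.end),
            depth=float(row.depth) if "depth" in table.columns and pd.notna(row.depth) else None,
        )
        for row in table.itertuples()
    ]
    return CircularGenome(str(records[0].seq), contigs, name=records[0].id)


def write_genome(
    genome: CircularGenome, fasta_path: str | Path, contigs_path: str | Path
) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="circular")
    with open(fasta_path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    pd.DataFrame(
        [
            {"contig_id": c.id, "start": c.start, "end": c.end, "depth": c.depth}
            for c in genome.contigs
        ]
    ).to_csv(contigs_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Repeat annotations
# ---------------------------------------------------------------------------


def write_repeat_annotations(repeats: Sequence[RepeatPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "repeat_id": r.id,
                "orientation": r.orientation,
                "locus1_start": r.locus1.start,
                "locus1_end": r.locus1.end,
                "locus2_start": r.locus2.start,
                "locus2_end": r.locus2.end,
                "composite": int(r.composite),
            }
            for r in repeats
        ],
        columns=REPEAT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def load_repeat_annotations(
    path: str | Path, genome: CircularGenome | None = None
) -> list[RepeatPair]:
    """Load and validate repeat annotations.

    With a genome, each pair's locus sequences are checked for identity
    (reverse-complementing locus2 for inverted pairs); a violation names the
    repeat.  Malformed rows are reported with their line number.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(REPEAT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"repeat annotation file lacks columns {sorted(missing)}")
    repeats: list[RepeatPair] = []
    for i, row in enumerate(table.itertuples(), start=2):  # 1-based incl. header
        try:
            rp = RepeatPair(
                id=str(row.repeat_id),
                orientation=str(row.orientation),
                locus1=Locus(int(row.locus1_start), int(row.locus1_end)),
                locus2=Locus(int(row.locus2_start), int(row.locus2_end)),
                composite=bool(int(row.composite)),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
        repeats.append(rp)
    if genome is not None:
        for rp in repeats:
            s1 = genome.locus_sequence(rp.locus1)
            s2 = genome.locus_sequence(rp.locus2)
            if rp.orientation == "-":
                s2 = revcomp(s2)
            if s1 != s2:
                raise ValueError(
                    f"repeat {rp.id}: locus sequences are not identical on the genome"
                )
    return repeats


def repeat_annotations_to_bed6(repeats: Sequence[RepeatPair], chrom: str = "master") -> str:
    """BED6 text, two lines per repeat (name = repeat_id)."""
    lines = []
    for r in repeats:
        for locus, strand in ((r.locus1, "+"), (r.locus2, r.orientation if r.orientation in "+-" else "+")):
            lines.append(
                f"{chrom}\t{locus.start}\t{locus.end}\t{r.id}\t0\t{strand}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------


def read_gfa(path: str | Path) -> GenomeGraph:
    """Assembly graph from GFA 1.0 (S lines with DP/dp depth, L lines)."""
    nodes: list[GraphNode] = []
    links: list[GraphLink] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            kind = fields[0]
            if kind == "S":
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed S line")
                name, seq = fields[1], fields[2]
                depth = None
                length = None if seq == "*" else len(seq)
                for tag in fields[3:]:
                    parts = tag.split(":", 2)
                    if len(parts) != 3:
                        continue
                    key, _, value = parts
                    if key.upper() == "DP":
                        depth = float(value)
                    elif key.upper() == "LN":
                        length = int(value)
                nodes.append(
                    GraphNode(
                        id=name,
                        length=length or 0,
                        depth=depth,
                        sequence=None if seq == "*" else seq,
                    )
                )
            elif kind == "L":
                if len(fields) < 5:
                    raise ValueError(f"{path}:{lineno}: malformed L line")
                links.append(GraphLink(fields[1], fields[2], fields[3], fields[4]))
    return GenomeGraph(nodes, links)


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Alignment records from PAF; target names must be ``<repeat>|<path>``.

    Mapping quality is ignored; ``tp:A:P`` (or absence of a ``tp`` tag) marks
    a record primary.
    """
    records: list[AlignmentRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line with <12 columns")
            target = f[5]
            if "|" not in target:
                raise ValueError(
                    f"{path}:{lineno}: target {target!r} is not '<repeat>|<path>'"
                )
            repeat_id, path_id = target.rsplit("|", 1)
            primary = True
            for tag in f[12:]:
                if tag.startswith("tp:A:"):
                    primary = tag == "tp:A:P"
            records.append(
                AlignmentRecord(
                    read_id=f[0],
                    repeat_id=repeat_id,
                    path_id=path_id,
                    read_start=int(f[2]),
                    read_end=int(f[3]),
                    strand=f[4],
                    path_start=int(f[7]),
                    path_end=int(f[8]),
                    matches=int(f[9]),
                    block_len=int(f[10]),
                    is_primary=primary,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def write_reads_fastq(reads, path: str | Path, quality: int = 20) -> None:
    """Simulated reads as FASTQ with a constant placeholder quality."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{chr(33 + quality) * len(r.sequence)}\n")


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from FASTA or FASTQ (gz-transparent)."""
    p = Path(path)
    stem = p.name[:-3] if p.suffix == ".gz" else p.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt)]


# ---------------------------------------------------------------------------
# Labels, counts, published fixture
# ---------------------------------------------------------------------------


def write_labels(labels: Iterable[SupportLabel], path: str | Path) -> None:
    pd.DataFrame(
        [{"read_id": l.read_id, "repeat_id": l.repeat_id, "label": l.label} for l in labels]
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> list[SupportLabel]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SupportLabel(read_id=r.read_id, repeat_id=r.repeat_id, label=r.label)
        for r in table.itertuples()
    ]


def write_counts(counts: Iterable[SupportCounts], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"repeat_id": c.repeat_id, "m1": c.m1, "m2": c.m2, "s1": c.s1, "s2": c.s2}
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> list[SupportCounts]:
    table = pd.read_csv(path, sep="\t")
    return [
        SupportCounts(
            repeat_id=str(r.repeat_id), m1=int(r.m1), m2=int(r.m2), s1=int(r.s1), s2=int(r.s2)
        )
        for r in table.itertuples()
    ]


def load_published_support() -> pd.DataFrame:
    """The published repeat-support table for the floating-bamboo
    (*Hygroryza aristata*) mitogenome: 25 repeat pairs with junction path
    labels, spanning-read counts and printed rates; 23 repeats lie on the
    master circle and 2 complex repeats exist only in the alternative
    arrangement (``in_master`` = 0).
    """
    with resources.files("mitorecomb.data").joinpath(
        "hygroryza_repeat_support.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
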