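"""Sequence I/O, assembly statistics, N-run handling, pseudochromosomes.

Coordinates are 1-based inclusive throughout (GFF3 convention). Degenerate
IUB codes other than N are normalized to N when sequences are read, so the
working alphabet is {A, C, G, T, N}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DEGENERATE = re.compile(r"[^ACGTN]")

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def normalize_sequence(seq: str) -> str:
    """Uppercase and replace degenerate IUB codes (R, Y, W, S, ...) by N."""
    return _DEGENERATE.sub("N", seq.upper())


@dataclass
class Scaffold:
    """A named DNA sequence over {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyStats:
    n_scaffolds: int
    n10: int
    n50: int
    n90: int
    total_bp: int


@dataclass
class Pseudochromosome:
    """Scaffolds of one linkage group stitched with fixed-length N spacers.

    ``offsets`` maps scaffold_id -> (start, end, orientation), 1-based
    inclusive positions of that scaffold's sequence in ``sequence``.
    """

    lg_id: str
    sequence: str
    offsets: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    spacer: int = 100


def read_fasta(path) -> list[Scaffold]:
    return [Scaffold(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(scaffolds: Iterable[Scaffold], path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in scaffolds
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_gff3(path) -> pd.DataFrame:
    """Read GFF3 into a DataFrame with the nine standard columns.

    Attribute key=value pairs are additionally expanded into columns
    ``gene_id`` (from ID or Parent) where present.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)

    def _id(attrs: str) -> str:
        for part in attrs.split(";"):
            if part.startswith("ID="):
                return part[3:]
        return ""

    df["feature_id"] = df["attributes"].map(_id)
    return df


def write_gff3(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df.to_csv(fh, sep="\t", header=False, index=False, columns=GFF3_COLUMNS)


def assembly_stats(scaffolds: Sequence[Scaffold]) -> AssemblyStats:
    """Scaffold count, N10/N50/N90 and total bp.

    Nxx is the length of the scaffold at which the cumulative length, over
    scaffolds sorted by descending length, first reaches xx% of the total.
    Ties resolve by descending length then lexicographic id.
    """
    if not scaffolds:
        raise ValueError("assembly_stats requires a non-empty scaffold list")
    ordered = sorted(scaffolds, key=lambda s: (-s.length, s.id))
    lengths = [s.length for s in ordered]
    total = sum(lengths)

    def nxx(frac: float) -> int:
        cum = 0
        for length in lengths:
            cum += length
            if cum >= frac * total:
                return length
        return lengths[-1]

    return AssemblyStats(
        n_scaffolds=len(ordered),
        n10=nxx(0.10),
        n50=nxx(0.50),
        n90=nxx(0.90),
        total_bp=total,
    )


def stats_table(stats: AssemblyStats) -> pd.DataFrame:
    """Assembly statistics as a two-column table with conventional row labels."""
    rows = [
        ("No. scaffolds", stats.n_scaffolds),
        ("N10 (bp)", stats.n10),
        ("N50 (bp)", stats.n50),
        ("N90 (bp)", stats.n90),
        ("Total bp", stats.total_bp),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])


_N_RUN = re.compile(r"N+")


def find_n_runs(sequence: str, min_len: int = 20) -> list[tuple[int, int]]:
    """Maximal runs of >= min_len consecutive N, as 1-based inclusive intervals."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [
        (m.start() + 1, m.end())
        for m in _N_RUN.finditer(sequence)
        if m.end() - m.start() >= min_len
    ]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def build_pseudochromosome(
    ordered: Sequence[tuple[Scaffold, str]],
    lg_id: str = "pseudo",
    spacer: int = 100,
) -> Pseudochromosome:
    """Stitch oriented scaffolds into one sequence with N spacers.

    Scaffolds with orientation "-" contribute their reverse complement.
    Consecutive scaffold intervals are separated by exactly ``spacer`` N's.
    """
    if not ordered:
        raise ValueError("cannot build a pseudochromosome from zero scaffolds")
    parts: list[str] = []
    offsets: dict[str, tuple[int, int, str]] = {}
    pos = 0
    for i, (scaf, orient) in enumerate(ordered):
        if orient not in {"+", "-"}:
            raise ValueError(f"orientation must be + or -, got {orient!r}")
        if i > 0:
            parts.append("N" * spacer)
            pos += spacer
        seq = scaf.sequence if orient == "+" else reverse_complement(scaf.sequence)
        offsets[scaf.id] = (pos + 1, pos + len(seq), orient)
        parts.append(seq)
        pos += len(seq)
    return Pseudochromosome(lg_id=lg_id, sequence="".join(parts), offsets=offsets,
                            spacer=spacer)


def split_pseudochromosome(pseudo: Pseudochromosome) -> list[Scaffold]:
    """Recover the input scaffolds (forward strand) from a pseudochromosome."""
    out = []
    for sid, (start, end, orient) in sorted(pseudo.offsets.items(),
                                            key=lambda kv: kv[1][0]):
        seq = pseudo.sequence[start - 1:end]
        if orient == "-":
            seq = reverse_complement(seq)
        out.append(Scaffold(sid, seq))
    return out


def chromosome_size(lg_scaffolds: Sequence[Scaffold], include_n_runs: bool = True,
                    min_run: int = 20) -> int:
    """Total bp of a linkage group's scaffolds, optionally excluding long N-runs.

    With ``include_n_runs=False``, runs of >= ``min_run`` N's are subtracted;
    this mirrors estimating chromosome size without assembly gap padding.
    """
    total = sum(s.length for s in lg_scaffolds)
    if include_n_runs:
        return total
    gap = sum(
        end - start + 1
        for s in lg_scaffolds
        for start, end in find_n_runs(s.sequence, min_len=min_run)
    )
    return total - gap


def extract_pseudochromosome_cds(
    pseudo: Pseudochromosome, genes: pd.DataFrame
) -> pd.DataFrame:
    """Lift gene coordinates from scaffolds onto a pseudochromosome.

    ``genes`` needs columns gene_id, scaffold_id, start, end, strand
    (scaffold coordinates, 1-based inclusive). Genes on "-"-oriented
    scaffolds get mirrored coordinates (start' = L - end + 1 within the
    scaffold) and flipped strand. Output genes are sorted by lifted start
    and given consecutive ``order_index`` values (0-based).
    """
    rows = []
    for rec in genes.itertuples(index=False):
        if rec.scaffold_id not in pseudo.offsets:
            raise KeyError(
                f"gene {rec.gene_id}: scaffold {rec.scaffold_id} not in "
                f"pseudochromosome {pseudo.lg_id}"
            )
        off_start, off_end, orient = pseudo.offsets[rec.scaffold_id]
        scaf_len = off_end - off_start + 1
        if not (1 <= rec.start <= rec.end <= scaf_len):
            raise ValueError(
                f"gene {rec.gene_id} at {rec.start}-{rec.end} lies outside "
                f"scaffold {rec.scaffold_id} (length {scaf_len})"
            )
        if orient == "+":
            start, end, strand = rec.start, rec.end, rec.strand
        else:
            start = scaf_len - rec.end + 1
            end = scaf_len - rec.start + 1
            strand = "-" if rec.strand == "+" else "+"
        rows.append({
            "gene_id": rec.gene_id,
            "chrom": pseudo.lg_id,
            "start": off_start + start - 1,
            "end": off_start + end - 1,
            "strand": strand,
        })
    out = pd.DataFrame(rows).sort_values("start", kind="stable").reset_index(drop=True)
    out["order_index"] = range(len(out))
    return out
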