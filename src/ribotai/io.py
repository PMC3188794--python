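"""Readers and writers for the pipeline's plain-text formats.

All tabular files are tab-separated with ``#`` comment headers stating units
and conventions (codon coordinates are 1-based).  FASTA goes through
Biopython; the gene id is the first whitespace-delimited token of the
description line.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_model import (
    CODON_TO_AA,
    SENSE_CODONS,
    CodingSequence,
    CodonUsageProfile,
    CodonWeightTable,
    ExpressionLevelMap,
    InvalidSequenceError,
    TRNAPool,
    compute_weights,
)
from .genome_survey import GeneBottleneckTable
from .library_stats import LibraryRecord

__all__ = [
    "ParseError",
    "read_orf_fasta",
    "write_fasta",
    "read_trna_pool",
    "read_expression_levels",
    "read_library_table",
    "write_library_table",
    "write_codon_usage",
    "write_bottleneck_table",
    "default_trna_pool",
    "default_weights",
]


class ParseError(ValueError):
    """An input file failed to parse; message names file, record and reason."""


def read_orf_fasta(path: str | Path) -> list[CodingSequence]:
    """Read in-frame ORFs from FASTA (DNA or RNA alphabet)."""
    path = Path(path)
    orfs = []
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            orfs.append(CodingSequence.from_nucleotides(record.id, str(record.seq)))
        except InvalidSequenceError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if not orfs:
        raise ParseError(f"{path}: no FASTA records found")
    return orfs


def write_fasta(orfs: Iterable[CodingSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(orf.to_nucleotides()), id=orf.id, description="")
        for orf in orfs
    ]
    SeqIO.write(records, str(path), "fasta")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # malformed TSV
        raise ParseError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_trna_pool(
    pool_path: str | Path, s_values_path: str | Path | None = None
) -> TRNAPool:
    """Read a tRNA pool (columns: anticodon, copy_number) and optional
    s-values table (columns: pairing_class, s)."""
    df = _read_tsv(pool_path, ["anticodon", "copy_number"])
    entries = tuple(
        (str(row.anticodon), int(row.copy_number)) for row in df.itertuples()
    )
    if s_values_path is not None:
        sdf = _read_tsv(s_values_path, ["pairing_class", "s"])
        s_values = {str(row.pairing_class): float(row.s) for row in sdf.itertuples()}
        return TRNAPool(entries=entries, s_values=s_values)
    return TRNAPool(entries=entries)


def read_expression_levels(path: str | Path) -> ExpressionLevelMap:
    df = _read_tsv(path, ["gene_id", "mrna_level"])
    return ExpressionLevelMap(
        levels={str(r.gene_id): float(r.mrna_level) for r in df.itertuples()}
    )


def read_library_table(
    table_path: str | Path, fasta_path: str | Path
) -> list[LibraryRecord]:
    """Assemble library records from a measurement TSV plus variant FASTA.

    TSV columns: variant_id, protein_abundance, od, folding_energy (optional).
    Every table row must have a sequence in the FASTA, keyed by variant_id.
    """
    df = _read_tsv(table_path, ["variant_id", "protein_abundance", "od"])
    seqs = {orf.id: orf for orf in read_orf_fasta(fasta_path)}
    has_folding = "folding_energy" in df.columns
    records = []
    for row in df.itertuples():
        vid = str(row.variant_id)
        if vid not in seqs:
            raise ParseError(
                f"{table_path}: variant {vid!r} has no sequence in {fasta_path}"
            )
        folding = None
        if has_folding and pd.notna(row.folding_energy):
            folding = float(row.folding_energy)
        records.append(
            LibraryRecord(
                variant_id=vid,
                seq=seqs[vid],
                protein_abundance=float(row.protein_abundance),
                od=float(row.od),
                folding_energy=folding,
            )
        )
    return records


_HEADER = "# ribotai output; codon coordinates are 1-based; tab-separated\n"


def _write_df(df: pd.DataFrame, path: str | Path, extra_comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        if extra_comment:
            fh.write(f"# {extra_comment}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_library_table(records: Sequence[LibraryRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        dict(
            variant_id=[r.variant_id for r in records],
            protein_abundance=[r.protein_abundance for r in records],
            od=[r.od for r in records],
            folding_energy=[r.folding_energy for r in records],
        )
    )
    _write_df(df, path, "abundance: arbitrary units; od: optical density; folding_energy: kcal/mol")


def write_codon_usage(profile: CodonUsageProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        dict(
            codon=list(SENSE_CODONS),
            amino_acid=[CODON_TO_AA[c] for c in SENSE_CODONS],
            count=[profile.counts.get(c, float("nan")) for c in SENSE_CODONS],
            fraction=[profile.freq[c] for c in SENSE_CODONS],
        )
    )
    _write_df(df, path, f"codon usage, scope={profile.scope}")


def write_bottleneck_table(table: GeneBottleneckTable, path: str | Path) -> None:
    _write_df(
        table.table,
        path,
        f"bottleneck scan, window n={table.window_n}, min gene length {table.min_length} codons; "
        f"{len(table.skipped)} gene(s) skipped as too short",
    )


def default_trna_pool() -> TRNAPool:
    """The bundled E. coli-like anticodon table with default s-values."""
    data = importlib.resources.files("ribotai") / "data"
    return read_trna_pool(
        str(data / "ecoli_trna_gcn.tsv"), str(data / "s_values.tsv")
    )


def default_weights(cga_weight: float | None = 0.1333) -> CodonWeightTable:
    """Codon weight table computed from the bundled tRNA pool."""
    return compute_weights(
        default_trna_pool(), cga_weight=cga_weight, source="bundled E. coli-like tRNA pool"
    )
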