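"""Shared readers and writers for FASTA/FASTQ/GFF3/BED/VCF/TSV.

Coordinate contract: GFF3 is 1-based inclusive and BED 0-based half-open on
disk; everything in memory is 0-based half-open, converted exactly once at
these boundaries. Malformed records raise :class:`FileFormatError` carrying
``file:line`` context. TSV outputs may carry ``#``-prefixed comment headers
recording the parameters used; the readers skip them.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FileFormatError(ValueError):
    """A record violated its format's minimal well-formedness."""

    def __init__(self, path, line: int | None, message: str):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")


def _open_text(path) -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered ``{name: sequence}`` dict (uppercased)."""
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise FileFormatError(path, None, f"duplicate FASTA id {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(title, sequence, quality)`` from a (optionally gzipped) FASTQ.

    Uses Biopython's fast four-line iterator; a sequence/quality length
    mismatch surfaces as :class:`FileFormatError`.
    """
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title, seq, qual
        except ValueError as exc:
            raise FileFormatError(path, None, str(exc)) from exc


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3 / BED gene intervals

GENE_COLUMNS = ["gene_id", "seq", "start", "end"]


def read_gff3(path, feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Read gene intervals from GFF3 into a 0-based half-open frame.

    Returns a DataFrame with columns ``gene_id, seq, start, end`` (start/end
    0-based half-open). Only rows whose type is in *feature_types* are kept;
    the ``ID=`` attribute (or ``gene_id=``) names the gene.
    """
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FileFormatError(path, ln, f"expected 9 columns, got {len(parts)}")
            seq, _src, ftype, start, end, _score, _strand, _frame, attrs = parts
            if ftype not in feature_types:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FileFormatError(path, ln, "non-integer coordinates") from None
            if start_i < 1 or end_i < start_i:
                raise FileFormatError(path, ln, f"bad interval {start}-{end}")
            gene_id = None
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    if k in ("ID", "gene_id"):
                        gene_id = v
                        break
            if gene_id is None:
                raise FileFormatError(path, ln, "no ID= attribute")
            rows.append((gene_id, seq, start_i - 1, end_i))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_gff3(path, genes: pd.DataFrame, source: str = "hybridseer") -> None:
    """Write 0-based half-open gene intervals as 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.seq}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )


def read_bed(path) -> pd.DataFrame:
    """Read BED into ``gene_id, seq, start, end`` (+ optional extra columns)."""
    rows = []
    extra = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FileFormatError(path, ln, "BED needs >= 3 columns")
            seq, start, end = parts[0], parts[1], parts[2]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FileFormatError(path, ln, "non-integer coordinates") from None
            name = parts[3] if len(parts) > 3 else f"interval_{ln}"
            rows.append((name, seq, start_i, end_i))
            extra.append(parts[4] if len(parts) > 4 else None)
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if any(e is not None for e in extra):
        df["score"] = extra
    return df


def write_bed(path, intervals: pd.DataFrame, extra_cols: list[str] | None = None) -> None:
    """Write ``gene_id, seq, start, end`` (0-based half-open) as BED4+."""
    cols = ["seq", "start", "end", "gene_id"] + (extra_cols or [])
    with open(path, "w") as fh:
        for row in intervals[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# TSV with comment headers


def write_tsv(path, df: pd.DataFrame, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# Minimal VCF writing (reading goes through cyvcf2 in hybridseer.variome)


def write_vcf(
    path,
    samples: list[str],
    sites: pd.DataFrame,
    genotypes: np.ndarray,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write a minimal VCF 4.2 with GT fields.

    *sites* needs columns ``seq, pos (0-based), ref, alt`` where ``alt`` is a
    comma-joined string; *genotypes* is ``(n_samples, n_sites, 2)`` of allele
    indices with -1 for missing.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, row in enumerate(sites.itertuples(index=False)):
            gts = []
            for i in range(len(samples)):
                a, b = genotypes[i, j]
                gts.append("./." if a < 0 or b < 0 else f"{a}/{b}")
            fh.write(
                f"{row.seq}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick


def write_newick(path, newick: str) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip("\n") + "\n")
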