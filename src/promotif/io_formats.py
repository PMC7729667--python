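"""Readers and writers for the standard formats the pipeline touches.

Everything downstream operates on in-memory domain types; coordinate
conversion happens only here.  Internal coordinates are 0-based half-open;
GFF3 is converted from 1-based inclusive on read, BED is written 0-based
half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .pwm import PWM

logger = logging.getLogger(__name__)

_VALID_CHARS = set("ACGTN")


@dataclass
class SequenceSet:
    """Ordered map of sequence id -> uppercased DNA string."""

    records: dict[str, str]
    source_path: str = ""

    def __post_init__(self) -> None:
        for sid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for id {sid!r}")
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise ValueError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sid: str) -> str:
        return self.records[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.records

    def ids(self) -> list[str]:
        return list(self.records)


GENE_MODEL_COLUMNS = [
    "gene_id",
    "transcript_id",
    "seq_id",
    "start",
    "end",
    "strand",
    "feature_kind",
]


@dataclass
class GeneModelTable:
    """gene/CDS features with 1-based inclusive coordinates, as annotated."""

    df: pd.DataFrame
    n_skipped: int = 0

    def __post_init__(self) -> None:
        missing = set(GENE_MODEL_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"gene model table missing columns {sorted(missing)}")
        df = self.df
        if len(df):
            if (df["start"] > df["end"]).any():
                raise ValueError("gene model rows with start > end")
            if not df["strand"].isin(["+", "-"]).all():
                raise ValueError("strand must be '+' or '-'")
            key = df[["transcript_id", "feature_kind", "start", "end"]]
            if key.duplicated().any():
                raise ValueError("duplicate (transcript, kind, start, end) rows")

    def genes(self) -> pd.DataFrame:
        return self.df[self.df["feature_kind"] == "gene"]

    def cds(self) -> pd.DataFrame:
        return self.df[self.df["feature_kind"] == "CDS"]


ALIGNMENT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "query_coverage",
    "e_value",
    "bit_score",
    "rank",
]


@dataclass
class AlignmentTable:
    """Protein-alignment hits ranked per query by descending bit score."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(ALIGNMENT_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"alignment table missing columns {sorted(missing)}")
        df = self.df
        if len(df):
            if ((df["percent_identity"] < 0) | (df["percent_identity"] > 100)).any():
                raise ValueError("percent_identity outside [0, 100]")
            if ((df["query_coverage"] < 0) | (df["query_coverage"] > 100)).any():
                raise ValueError("query_coverage outside [0, 100]")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MotifLibraryEntry:
    motif_id: str
    tf_family: str
    pwm: PWM
    provenance: str = ""


@dataclass
class MotifLibrary:
    entries: list[MotifLibraryEntry]

    def __post_init__(self) -> None:
        ids = [e.motif_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate motif ids in library")
        for e in self.entries:
            if not e.tf_family:
                raise ValueError(f"motif {e.motif_id!r} lacks a family label")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.tf_family)
        return list(seen)


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file; ids are the first whitespace token of each header."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        records[rec.id] = seq
    return SequenceSet(records, source_path=str(path))


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.records.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def _parse_attributes(text: str) -> dict[str, str]:
    return {k.strip(): v.strip() for k, v in _ATTR_RE.findall(text)}


def read_gff3_genes(
    path: str | Path,
    id_attribute: str = "ID",
    parent_attribute: str = "Parent",
) -> GeneModelTable:
    """Read gene and CDS features from a GFF3 file.

    Records missing a strand or an id attribute are skipped with a logged
    warning and counted in ``n_skipped``.  The attribute key holding ids is
    configurable because annotation conventions vary between assemblies.
    """
    rows = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                logger.warning("%s:%d: malformed GFF3 line skipped", path, lineno)
                n_skipped += 1
                continue
            seq_id, _, kind, start, end, _, strand, _, attrs = fields
            if kind not in ("gene", "CDS"):
                continue
            if strand not in ("+", "-"):
                logger.warning("%s:%d: missing/invalid strand, skipped", path, lineno)
                n_skipped += 1
                continue
            attr = _parse_attributes(attrs)
            if kind == "gene":
                ident = attr.get(id_attribute)
                gene_id, transcript_id = ident, ident
            else:
                parent = attr.get(parent_attribute) or attr.get(id_attribute)
                gene_id, transcript_id = parent, parent
            if not gene_id:
                logger.warning("%s:%d: missing id attribute, skipped", path, lineno)
                n_skipped += 1
                continue
            try:
                s, e = int(start), int(end)
            except ValueError:
                logger.warning("%s:%d: non-numeric coordinates, skipped", path, lineno)
                n_skipped += 1
                continue
            rows.append((gene_id, transcript_id, seq_id, s, e, strand, kind))
    df = pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS)
    return GeneModelTable(df, n_skipped=n_skipped)


#: standard BLAST outfmt6 column names
OUTFMT6_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]


def read_blast_table(
    path: str | Path,
    query_lengths: dict[str, int] | None = None,
) -> AlignmentTable:
    """Read a BLAST outfmt6 table (optionally with a 13th query_coverage column).

    Rows are ranked per query by descending bit score; ties break by
    ascending e-value then subject id.  If no coverage column is present,
    coverage is computed from the aligned query span when ``query_lengths``
    is given, else set to 100.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=ALIGNMENT_COLUMNS)
        return AlignmentTable(df)
    if df.shape[1] == len(OUTFMT6_COLUMNS) + 1:
        df.columns = OUTFMT6_COLUMNS + ["query_coverage"]
    elif df.shape[1] == len(OUTFMT6_COLUMNS):
        df.columns = OUTFMT6_COLUMNS
    else:
        raise ValueError(
            f"{path}: expected 12 or 13 tab-separated columns, got {df.shape[1]}"
        )
    for col in ("percent_identity", "e_value", "bit_score"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: non-numeric {col} field at line {line}")
        df[col] = pd.to_numeric(df[col])
    if "query_coverage" not in df.columns:
        if query_lengths is not None:
            span = (df["q_end"] - df["q_start"]).abs() + 1
            qlen = df["query_id"].map(query_lengths)
            df["query_coverage"] = 100.0 * span / qlen
        else:
            df["query_coverage"] = 100.0
    df = df.sort_values(
        ["query_id", "bit_score", "e_value", "subject_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("query_id").cumcount() + 1
    return AlignmentTable(df[ALIGNMENT_COLUMNS].copy())


def read_motif_library(path: str | Path) -> MotifLibrary:
    """Read JASPAR-style or MEME-minimal motif records.

    JASPAR records look like::

        >MA0001.1 FAMILY
        A [ 4 19 0 ]
        C [16  0 20 ]
        G [ 0  1 0 ]
        T [ 0  0 0 ]

    MEME-minimal records use ``MOTIF id family`` followed by a
    ``letter-probability matrix`` block.  Count matrices are normalised per
    column; a column with non-positive total is a hard error.
    """
    text = Path(path).read_text()
    if ">" in text.lstrip()[:1] or text.lstrip().startswith(">"):
        return _read_jaspar(text, str(path))
    if "MOTIF" in text:
        return _read_meme(text, str(path))
    raise ValueError(f"{path}: unrecognised motif library format")


def _read_jaspar(text: str, provenance: str) -> MotifLibrary:
    entries = []
    blocks = re.split(r"(?m)^>", text)
    for block in blocks:
        block = block.strip()
        if not block:
            continue
        lines = block.splitlines()
        header = lines[0].split()
        motif_id = header[0]
        family = header[1] if len(header) > 1 else "unknown"
        rows: dict[str, list[float]] = {}
        for line in lines[1:]:
            m = re.match(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]+?)\s*\]?\s*$", line.strip())
            if not m:
                continue
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
        if set(rows) != set("ACGT"):
            raise ValueError(f"{provenance}: motif {motif_id} missing base rows")
        counts = np.array([rows["A"], rows["C"], rows["G"], rows["T"]]).T
        totals = counts.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError(
                f"{provenance}: motif {motif_id} has a column with non-positive total"
            )
        entries.append(
            MotifLibraryEntry(motif_id, family, PWM.from_counts(counts, motif_id=motif_id), provenance)
        )
    return MotifLibrary(entries)


def _read_meme(text: str, provenance: str) -> MotifLibrary:
    entries = []
    motif_blocks = re.split(r"(?m)^MOTIF\s+", text)[1:]
    for block in motif_blocks:
        lines = block.splitlines()
        header = lines[0].split()
        motif_id = header[0]
        family = header[1] if len(header) > 1 else "unknown"
        matrix_rows: list[list[float]] = []
        in_matrix = False
        for line in lines[1:]:
            if line.strip().startswith("letter-probability matrix"):
                in_matrix = True
                continue
            if in_matrix:
                parts = line.split()
                if len(parts) == 4:
                    matrix_rows.append([float(x) for x in parts])
                elif matrix_rows:
                    break
        if not matrix_rows:
            raise ValueError(f"{provenance}: motif {motif_id} has no matrix block")
        counts = np.array(matrix_rows)
        if np.any(counts.sum(axis=1) <= 0):
            raise ValueError(
                f"{provenance}: motif {motif_id} has a column with non-positive total"
            )
        entries.append(
            MotifLibraryEntry(motif_id, family, PWM.from_counts(counts, motif_id=motif_id), provenance)
        )
    return MotifLibrary(entries)


def write_motif_library(library: MotifLibrary, path: str | Path) -> None:
    """Write a library in JASPAR-style probability text, round-trip stable."""
    with open(path, "w") as fh:
        for e in library.entries:
            fh.write(f">{e.motif_id} {e.tf_family}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v:.12g}" for v in e.pwm.matrix[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


def write_hits_bed(hits: Sequence, path: str | Path) -> None:
    """Write motif hits as BED6 (0-based half-open, promoter id as chrom)."""
    rows = sorted(
        hits, key=lambda h: (h.promoter_id, h.interval[0], h.interval[1], h.motif_id)
    )
    with open(path, "w") as fh:
        for h in rows:
            score = getattr(h, "normalized_score", None)
            if score is None:
                p = getattr(h, "p_value", 1.0)
                score = min(1000, int(round(-10 * np.log10(max(p, 1e-300)))))
            else:
                score = int(round(1000 * score))
            fh.write(
                f"{h.promoter_id}\t{h.interval[0]}\t{h.interval[1]}\t"
                f"{h.motif_id}\t{score}\t{h.strand}\n"
            )


def read_hits_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["promoter_id", "start", "end", "motif_id", "score", "strand"],
    )
    return df


def write_enrichment_tsv(results: Sequence, path: str | Path) -> None:
    """Write per-family enrichment results with full contingency and p-values."""
    with open(path, "w") as fh:
        fh.write(
            "tf_family\tN\tK\tn\tk\tp_enrich\tp_deplete\tcritical\t"
            "significant\tdirection\n"
        )
        for r in results:
            fh.write(
                f"{r.tf_family}\t{r.N}\t{r.K}\t{r.n}\t{r.k}\t{r.p_value!r}\t"
                f"{r.p_deplete!r}\t{r.critical!r}\t{r.significant}\t{r.direction}\n"
            )


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_gene_list(path: str | Path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
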