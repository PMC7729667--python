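"""Promoter universe construction.

A promoter is the fixed-length region immediately upstream of a gene's
anchor (start codon or TSS), read 5'->3' relative to the gene.  Genes whose
putative promoter overlaps coding sequence of a *different* gene are
excluded, as are genes with less upstream sequence than the configured
minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModelTable, SequenceSet
from .pwm import reverse_complement


@dataclass
class PromoterRecord:
    gene_id: str
    transcript_id: str
    seq_id: str
    interval: tuple[int, int]  # 0-based half-open, genomic coordinates
    strand: str
    sequence: str  # 5'->3' relative to the gene

    def __post_init__(self) -> None:
        start, end = self.interval
        if not (0 <= start < end):
            raise ValueError("promoter interval must be non-empty and non-negative")
        if len(self.sequence) != end - start:
            raise ValueError("promoter sequence length must equal interval length")

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class PromoterUniverse:
    records: list[PromoterRecord]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = [r.transcript_id for r in self.records] + [g for g, _ in self.excluded]
        if len(set(seen)) != len(seen):
            raise ValueError("a transcript appears twice in the promoter universe")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.transcript_id for r in self.records]

    def sequences(self) -> SequenceSet:
        return SequenceSet({r.transcript_id: r.sequence for r in self.records})

    def subset(self, ids: set[str] | list[str]) -> "PromoterUniverse":
        wanted = set(ids)
        return PromoterUniverse(
            [r for r in self.records if r.transcript_id in wanted], []
        )


def _anchor_position(gene_rows: pd.DataFrame, strand: str, anchor: str) -> int:
    """0-based genomic position of the upstream reference point.

    For both the start-codon and TSS anchors the reference point is the
    5'-most annotated coordinate of the relevant feature set: the gene span
    for ``tss``, the CDS span for ``start_codon`` (falling back to the gene
    span when no CDS rows exist).
    """
    if anchor == "start_codon":
        rows = gene_rows[gene_rows["feature_kind"] == "CDS"]
        if rows.empty:
            rows = gene_rows[gene_rows["feature_kind"] == "gene"]
    elif anchor == "tss":
        rows = gene_rows[gene_rows["feature_kind"] == "gene"]
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    if strand == "+":
        return int(rows["start"].min()) - 1  # convert to 0-based
    return int(rows["end"].max())  # 0-based position one past the 3' gene end


def extract_promoters(
    genome: SequenceSet,
    genes: GeneModelTable,
    l_prom: int = 1500,
    min_length: int | None = None,
    anchor: str = "start_codon",
) -> PromoterUniverse:
    """Extract up-to-``l_prom``-bp upstream regions for every transcript.

    Exclusion reasons:

    * ``cds_overlap`` — the promoter interval intersects a CDS interval of a
      different gene by >= 1 bp;
    * ``truncated_below_min`` — less than ``min_length`` of upstream sequence
      is available (``min_length`` defaults to ``l_prom``, requiring the
      full-length region);
    * ``missing_sequence`` — the promoter interval is empty.
    """
    if min_length is None:
        min_length = l_prom
    df = genes.df
    # CDS intervals per seq_id in 0-based half-open coordinates
    cds = df[df["feature_kind"] == "CDS"]
    cds_by_seq: dict[str, np.ndarray] = {}
    cds_gene_by_seq: dict[str, np.ndarray] = {}
    for sid, grp in cds.groupby("seq_id"):
        cds_by_seq[sid] = np.column_stack([grp["start"].values - 1, grp["end"].values])
        cds_gene_by_seq[sid] = grp["gene_id"].values

    records: list[PromoterRecord] = []
    excluded: list[tuple[str, str]] = []
    gene_feats = df[df["feature_kind"] == "gene"]
    for transcript_id, grp_gene in gene_feats.groupby("transcript_id", sort=False):
        gene_id = grp_gene["gene_id"].iloc[0]
        seq_id = grp_gene["seq_id"].iloc[0]
        strand = grp_gene["strand"].iloc[0]
        if seq_id not in genome:
            raise KeyError(f"gene {gene_id!r} references unknown sequence {seq_id!r}")
        seq = genome[seq_id]
        rows = df[(df["transcript_id"] == transcript_id) | (df["gene_id"] == gene_id)]
        rows = rows[rows["gene_id"] == gene_id]
        pos = _anchor_position(rows, strand, anchor)
        if pos < 0 or pos > len(seq):
            raise ValueError(
                f"anchor of gene {gene_id!r} falls outside sequence {seq_id!r}"
            )
        if strand == "+":
            start, end = max(0, pos - l_prom), pos
        else:
            start, end = pos, min(len(seq), pos + l_prom)
        available = end - start
        if available == 0:
            excluded.append((transcript_id, "missing_sequence"))
            continue
        if available < min_length:
            excluded.append((transcript_id, "truncated_below_min"))
            continue
        # overlap with CDS of other genes
        overlap = False
        if seq_id in cds_by_seq:
            ivs = cds_by_seq[seq_id]
            owners = cds_gene_by_seq[seq_id]
            hit = (ivs[:, 0] < end) & (ivs[:, 1] > start) & (owners != gene_id)
            overlap = bool(hit.any())
        if overlap:
            excluded.append((transcript_id, "cds_overlap"))
            continue
        subseq = seq[start:end]
        if strand == "-":
            subseq = reverse_complement(subseq)
        records.append(
            PromoterRecord(gene_id, transcript_id, seq_id, (start, end), strand, subseq)
        )
    return PromoterUniverse(records, excluded)


def sample_random_promoters(
    universe: PromoterUniverse, n: int = 10000, seed: int | np.random.Generator = 0
) -> PromoterUniverse:
    """Uniform sample of promoters without replacement, reproducible by seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n >= len(universe.records):
        if n > len(universe.records):
            warnings.warn(
                f"requested {n} promoters but universe has {len(universe.records)}; "
                "sampling all",
                stacklevel=2,
            )
        return PromoterUniverse(list(universe.records), [])
    idx = rng.choice(len(universe.records), size=n, replace=False)
    return PromoterUniverse([universe.records[i] for i in sorted(idx)], [])


def write_promoter_bed(universe: PromoterUniverse, path: str) -> None:
    with open(path, "w") as fh:
        for r in universe.records:
            fh.write(
                f"{r.seq_id}\t{r.interval[0]}\t{r.interval[1]}\t"
                f"{r.transcript_id}\t0\t{r.strand}\n"
            )


def write_exclusion_report(universe: PromoterUniverse, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\treason\n")
        for tid, reason in universe.excluded:
            fh.write(f"{tid}\t{reason}\n")
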