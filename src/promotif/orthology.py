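"""Ortholog chaining and TF-family target propagation.

Sugarcane transcripts are linked to Arabidopsis genes either directly
(filtered protein-alignment top hits) or, with higher confidence, through
sorghum: filtered sugarcane->sorghum hits joined to a curated
sorghum->Arabidopsis ortholog relation table.  Per-TF-family Arabidopsis
target sets are then propagated back through the map to sugarcane
transcript ids with valid regulatory regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import AlignmentTable

ORTHOLOG_COLUMNS = [
    "sugarcane_transcript_id",
    "sorghum_gene_id",
    "arabidopsis_gene_id",
    "route",
    "percent_identity",
    "query_coverage",
]


@dataclass
class OrthologMap:
    df: pd.DataFrame
    min_identity: float = 30.0
    min_coverage: float = 50.0

    def __post_init__(self) -> None:
        missing = set(ORTHOLOG_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"ortholog map missing columns {sorted(missing)}")
        if len(self.df):
            if (self.df["percent_identity"] < self.min_identity).any():
                raise ValueError("ortholog map rows below the identity filter")
            if (self.df["query_coverage"] < self.min_coverage).any():
                raise ValueError("ortholog map rows below the coverage filter")

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# min_identity={self.min_identity} min_coverage={self.min_coverage}\n"
            )
            self.df.to_csv(fh, sep="\t", index=False)


@dataclass
class TargetSet:
    tf_family: str
    member_transcript_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.member_transcript_ids)


def top_hits(
    aln: AlignmentTable,
    n_top: int,
    e_max: float = 1e-3,
    min_identity: float = 30.0,
    min_coverage: float = 50.0,
) -> AlignmentTable:
    """Keep, per query: e-value <= e_max, rank <= n_top, and the identity and
    coverage floors.  The rank was assigned at read time (bit-score order),
    so the filters compose order-independently."""
    df = aln.df
    keep = (
        (df["e_value"] <= e_max)
        & (df["rank"] <= n_top)
        & (df["percent_identity"] >= min_identity)
        & (df["query_coverage"] >= min_coverage)
    )
    return AlignmentTable(df[keep].reset_index(drop=True))


def _check_id_overlap(left: pd.Series, right: pd.Series, what: str) -> None:
    l, r = set(left), set(right)
    if l and r and not (l & r):
        examples = f"left={sorted(l)[:3]} right={sorted(r)[:3]}"
        raise ValueError(f"id-format mismatch joining {what}: no shared ids ({examples})")


def chain_orthologs(
    sc_sb: AlignmentTable | None,
    sc_at: AlignmentTable | None,
    sb_at_relations: pd.DataFrame | None,
    mode: str = "high_confidence",
    min_identity: float = 30.0,
    min_coverage: float = 50.0,
) -> OrthologMap:
    """Build the sugarcane->Arabidopsis ortholog map.

    ``high_confidence`` joins filtered sugarcane->sorghum hits with the
    sorghum->Arabidopsis relation table (columns ``sorghum_gene_id``,
    ``arabidopsis_gene_id``); ``direct`` uses filtered
    sugarcane->Arabidopsis hits.  Many-to-many relations are retained; the
    result is deduplicated on (sugarcane transcript, Arabidopsis gene).
    """
    if mode == "high_confidence":
        if sc_sb is None or sb_at_relations is None:
            raise ValueError("high_confidence mode needs sc->sb hits and relations")
        hits = sc_sb.df
        _check_id_overlap(
            hits["subject_id"], sb_at_relations["sorghum_gene_id"], "sorghum ids"
        )
        merged = hits.merge(
            sb_at_relations[["sorghum_gene_id", "arabidopsis_gene_id"]],
            left_on="subject_id",
            right_on="sorghum_gene_id",
            how="inner",
        )
        out = pd.DataFrame(
            {
                "sugarcane_transcript_id": merged["query_id"],
                "sorghum_gene_id": merged["sorghum_gene_id"],
                "arabidopsis_gene_id": merged["arabidopsis_gene_id"],
                "route": "via_sorghum",
                "percent_identity": merged["percent_identity"],
                "query_coverage": merged["query_coverage"],
            }
        )
    elif mode == "direct":
        if sc_at is None:
            raise ValueError("direct mode needs sc->at hits")
        hits = sc_at.df
        out = pd.DataFrame(
            {
                "sugarcane_transcript_id": hits["query_id"],
                "sorghum_gene_id": None,
                "arabidopsis_gene_id": hits["subject_id"],
                "route": "direct",
                "percent_identity": hits["percent_identity"],
                "query_coverage": hits["query_coverage"],
            }
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = (
        out.drop_duplicates(["sugarcane_transcript_id", "arabidopsis_gene_id"])
        .sort_values(["sugarcane_transcript_id", "arabidopsis_gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return OrthologMap(out, min_identity=min_identity, min_coverage=min_coverage)


def propagate_targets(
    ortho: OrthologMap,
    at_targets_per_tf: pd.DataFrame,
    family_of_tf: pd.DataFrame,
    promoter_universe_ids: set[str] | list[str],
) -> list[TargetSet]:
    """Union each family's Arabidopsis TF targets and map them back to
    sugarcane transcripts with valid regulatory regions.

    ``at_targets_per_tf`` has columns (tf_id, target_gene_id);
    ``family_of_tf`` has columns (tf_id, tf_family).
    """
    import warnings

    universe = set(promoter_universe_ids)
    at_to_sc: dict[str, set[str]] = {}
    for sc, at in zip(
        ortho.df["sugarcane_transcript_id"], ortho.df["arabidopsis_gene_id"]
    ):
        at_to_sc.setdefault(at, set()).add(sc)
    out: list[TargetSet] = []
    for family, tf_rows in family_of_tf.groupby("tf_family", sort=True):
        tf_ids = set(tf_rows["tf_id"])
        targets = set(
            at_targets_per_tf[at_targets_per_tf["tf_id"].isin(tf_ids)]["target_gene_id"]
        )
        if not tf_ids or at_targets_per_tf["tf_id"].isin(tf_ids).sum() == 0:
            warnings.warn(f"TF family {family!r} has no TFs with targets", stacklevel=2)
        members: set[str] = set()
        for at in targets:
            members |= at_to_sc.get(at, set())
        out.append(TargetSet(family, frozenset(members & universe)))
    return out
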