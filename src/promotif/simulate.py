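"""Synthetic study generator with known ground truth.

Emulates every input the pipeline consumes: promoters drawn from a k-th
order Markov background with motif occurrences planted from chosen PWMs, a
toy genome + gene models laid out so promoter extraction recovers exactly
the generated promoters, DEG labels whose association with planted motifs
has a controllable odds ratio, and self-consistent toy ortholog/alignment
tables with decoy hits.

Planted sites are forced non-overlapping and at least 2 bp from promoter
edges so ground truth stays unambiguous for recovery scoring.  DEG labels
are assigned first and planting is conditioned on the label, making the
per-family association a direct input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .background import BackgroundModel
from .io_formats import (
    GeneModelTable,
    GENE_MODEL_COLUMNS,
    MotifLibrary,
    MotifLibraryEntry,
    SequenceSet,
)
from .pwm import PWM, reverse_complement

SPACER = 60
GENE_BODY = 300


@dataclass
class PlantedMotif:
    pwm: PWM
    tf_family: str
    p_deg: float  # occurrence probability in DEG promoters
    p_nondeg: float  # occurrence probability in non-DEG promoters

    def __post_init__(self) -> None:
        for p in (self.p_deg, self.p_nondeg):
            if not 0.0 <= p <= 1.0:
                raise ValueError("occurrence probabilities must lie in [0, 1]")


@dataclass
class SyntheticSpec:
    seed: int
    n_genes: int = 500
    promoter_length: int = 1500
    background: BackgroundModel | None = None
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    deg_fraction: float = 0.2
    minus_strand_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.deg_fraction < 1.0:
            raise ValueError("deg_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    # transcript_id -> list of (tf_family, offset on the promoter, strand)
    planted_sites: dict[str, list[tuple[str, int, str]]]
    deg_labels: dict[str, bool]
    # transcript_id -> set of families planted in its promoter
    family_indicator: dict[str, set[str]]
    ortholog_triples: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for tid, sites in self.planted_sites.items():
            fams = {f for f, _, _ in sites}
            if fams != self.family_indicator.get(tid, set()):
                raise ValueError(f"indicator inconsistent with sites for {tid}")


def at_rich_background(order: int = 0) -> BackgroundModel:
    """An AT-rich order-0 composition typical of plant intergenic sequence."""
    stat = np.array([0.31, 0.19, 0.19, 0.31])
    return BackgroundModel(order=order, transition={}, stationary=stat, pseudocount=1.0)


def uniform_background() -> BackgroundModel:
    return BackgroundModel(
        order=0, transition={}, stationary=np.full(4, 0.25), pseudocount=1.0
    )


def block_pwm(consensus: str, major: float = 0.94, motif_id: str = "") -> PWM:
    """A PWM concentrated on a consensus word; ``major`` sets the probability
    of the consensus base at each position (the rest split evenly)."""
    from .pwm import BASE_INDEX

    w = len(consensus)
    mat = np.full((w, 4), (1 - major) / 3)
    for i, b in enumerate(consensus):
        mat[i, BASE_INDEX[b]] = major
    return PWM(mat, motif_id=motif_id or f"planted_{consensus}")


def generate_promoter_set(
    spec: SyntheticSpec,
) -> tuple[SequenceSet, GeneModelTable, GroundTruth]:
    """Generate a toy genome, gene models and ground truth.

    Each gene occupies its own contig laid out so that
    ``extract_promoters(genome, genes, l_prom=spec.promoter_length)`` with
    the start-codon anchor returns exactly the generated promoter sequences.
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background or at_rich_background()
    L = spec.promoter_length
    for pm in spec.planted_motifs:
        if pm.pwm.width >= L - 4:
            raise ValueError("planted motif is wider than the promoter allows")

    n = spec.n_genes
    ids = [f"sc_{i:05d}" for i in range(n)]
    n_deg = max(1, int(round(spec.deg_fraction * n)))
    deg_idx = set(rng.choice(n, size=n_deg, replace=False).tolist())

    genome: dict[str, str] = {}
    rows = []
    planted_sites: dict[str, list[tuple[str, int, str]]] = {}
    deg_labels: dict[str, bool] = {}
    family_indicator: dict[str, set[str]] = {}

    for i, tid in enumerate(ids):
        is_deg = i in deg_idx
        deg_labels[tid] = is_deg
        promoter = list(bg.sample(L, rng))
        occupied: list[tuple[int, int]] = []
        sites: list[tuple[str, int, str]] = []
        fams: set[str] = set()
        for pm in spec.planted_motifs:
            p = pm.p_deg if is_deg else pm.p_nondeg
            if rng.random() >= p:
                continue
            w = pm.pwm.width
            for _attempt in range(200):
                off = int(rng.integers(2, L - w - 1))
                if all(off + w <= s or off >= e for s, e in occupied):
                    break
            else:
                continue
            site = pm.pwm.sample_site(rng)
            promoter[off : off + w] = list(site)
            occupied.append((off, off + w))
            sites.append((pm.tf_family, off, "+"))
            fams.add(pm.tf_family)
        prom_seq = "".join(promoter)
        planted_sites[tid] = sorted(sites, key=lambda s: s[1])
        family_indicator[tid] = fams

        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        body = bg.sample(GENE_BODY, rng)
        spacer_l = bg.sample(SPACER, rng)
        spacer_r = bg.sample(SPACER, rng)
        contig_id = f"contig_{tid}"
        if strand == "+":
            contig = spacer_l + prom_seq + body + spacer_r
            cds_start = SPACER + L + 1  # 1-based
            cds_end = SPACER + L + GENE_BODY
        else:
            contig = spacer_l + reverse_complement(body) + reverse_complement(prom_seq) + spacer_r
            cds_start = SPACER + 1
            cds_end = SPACER + GENE_BODY
        genome[contig_id] = contig
        rows.append((tid, tid, contig_id, cds_start, cds_end, strand, "gene"))
        rows.append((tid, tid, contig_id, cds_start, cds_end, strand, "CDS"))

    genes = GeneModelTable(pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS))
    truth = GroundTruth(planted_sites, deg_labels, family_indicator)
    return SequenceSet(genome, source_path="synthetic"), genes, truth


def generate_ortholog_fixture(
    transcript_ids: list[str],
    seed: int,
    sc_per_sb: int = 2,
    dropout: float = 0.0,
    n_decoys: int = 0,
    families_targets: dict[str, set[str]] | None = None,
):
    """Self-consistent toy ortholog tables over sc_*/sb_*/at_* id spaces.

    Returns (sc->sb AlignmentTable, sc->at AlignmentTable, sorghum->At
    relation DataFrame, targets DataFrame, family_of_tf DataFrame,
    ground-truth triples).  Decoy hits fall below the default quality
    filters (identity 15%, coverage 20%); dropout removes sc->sb rows.
    """
    from .io_formats import AlignmentTable, ALIGNMENT_COLUMNS

    rng = np.random.default_rng(seed)
    triples = []
    sc_sb_rows = []
    sc_at_rows = []
    rel_rows = []
    seen_sb = set()
    for i, tid in enumerate(transcript_ids):
        sb = f"sb_{i // sc_per_sb:05d}"
        at = f"at_{i // sc_per_sb:05d}"
        dropped = rng.random() < dropout
        if not dropped:
            ident = float(rng.uniform(60, 95))
            cov = float(rng.uniform(70, 100))
            sc_sb_rows.append((tid, sb, ident, cov, 1e-50, 200.0, 1))
            sc_at_rows.append((tid, at, ident - 10, cov - 5, 1e-30, 150.0, 1))
            triples.append((tid, sb, at))
        if sb not in seen_sb:
            rel_rows.append((sb, at))
            seen_sb.add(sb)
    for d in range(n_decoys):
        tid = transcript_ids[int(rng.integers(len(transcript_ids)))]
        sc_sb_rows.append((tid, f"sb_decoy_{d:03d}", 15.0, 20.0, 5e-4, 40.0, 99))
        rel_rows.append((f"sb_decoy_{d:03d}", f"at_decoy_{d:03d}"))
    sc_sb = AlignmentTable(pd.DataFrame(sc_sb_rows, columns=ALIGNMENT_COLUMNS))
    sc_at = AlignmentTable(pd.DataFrame(sc_at_rows, columns=ALIGNMENT_COLUMNS))
    relations = pd.DataFrame(rel_rows, columns=["sorghum_gene_id", "arabidopsis_gene_id"])

    target_rows = []
    family_rows = []
    if families_targets:
        sc_to_at = {sc: at for sc, _, at in triples}
        for family, sc_targets in sorted(families_targets.items()):
            tf_id = f"at_tf_{family}"
            family_rows.append((tf_id, family))
            at_targets = sorted({sc_to_at[sc] for sc in sc_targets if sc in sc_to_at})
            for at in at_targets:
                target_rows.append((tf_id, at))
    targets = pd.DataFrame(target_rows, columns=["tf_id", "target_gene_id"])
    family_of_tf = pd.DataFrame(family_rows, columns=["tf_id", "tf_family"])
    return sc_sb, sc_at, relations, targets, family_of_tf, triples


def conditional_plant_probs(
    N: int, K: int, n_target: int, odds_ratio: float
) -> tuple[float, float]:
    """Solve for (p_deg, p_nondeg) giving the requested odds ratio with an
    expected ``n_target`` TFBS-carrying genes out of N (K of them DEGs)."""
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")

    def expected(p0: float) -> float:
        odds0 = p0 / (1 - p0)
        p1 = odds_ratio * odds0 / (1 + odds_ratio * odds0)
        return K * p1 + (N - K) * p0 - n_target

    p0 = brentq(expected, 1e-9, 1 - 1e-9)
    odds0 = p0 / (1 - p0)
    p1 = odds_ratio * odds0 / (1 + odds_ratio * odds0)
    return float(p1), float(p0)


def simulate_association(
    N: int, K: int, n_target: int, odds_ratio: float, rng: np.random.Generator
) -> tuple[set[str], set[str], set[str]]:
    """Draw one synthetic universe of gene labels with a controlled DEG/TFBS
    odds ratio; returns (universe_ids, deg_ids, tfbs_ids)."""
    p1, p0 = conditional_plant_probs(N, K, n_target, odds_ratio)
    ids = [f"g{i:06d}" for i in range(N)]
    deg = set(rng.choice(N, size=K, replace=False).tolist())
    u = rng.random(N)
    tfbs = {ids[i] for i in range(N) if u[i] < (p1 if i in deg else p0)}
    return set(ids), {ids[i] for i in deg}, tfbs


def write_motif_library_for(
    planted: list[PlantedMotif], path: str | Path
) -> MotifLibrary:
    from .io_formats import write_motif_library

    entries = [
        MotifLibraryEntry(pm.pwm.motif_id or f"planted_{i}", pm.tf_family, pm.pwm, "synthetic")
        for i, pm in enumerate(planted)
    ]
    lib = MotifLibrary(entries)
    write_motif_library(lib, path)
    return lib


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tdeg\tfamilies\tsites\n")
        for tid in truth.deg_labels:
            fams = ",".join(sorted(truth.family_indicator.get(tid, set()))) or "."
            sites = (
                ";".join(f"{f}:{o}:{s}" for f, o, s in truth.planted_sites.get(tid, []))
                or "."
            )
            fh.write(f"{tid}\t{int(truth.deg_labels[tid])}\t{fams}\t{sites}\n")
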