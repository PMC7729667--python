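"""Stage implementations behind the command-line pipeline.

Each stage reads standard-format files, calls the library, writes its
outputs plus a machine-readable run manifest (input checksums, config,
seed), and is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .background import BackgroundModel, build_background
from .comparison import annotate_against_library, write_annotation_tsv
from .discovery import (
    dedupe_across_widths,
    filter_valid,
    rank_and_group,
    replicate_runs,
    write_groups_tsv,
)
from .enrichment import bonferroni, test_family
from .io_formats import (
    MotifLibrary,
    MotifLibraryEntry,
    read_blast_table,
    read_fasta,
    read_gene_list,
    read_gff3_genes,
    read_motif_library,
    write_enrichment_tsv,
    write_fasta,
    write_gene_list,
    write_hits_bed,
    write_motif_library,
)
from .orthology import chain_orthologs, propagate_targets, top_hits
from .promoters import (
    PromoterUniverse,
    extract_promoters,
    sample_random_promoters,
    write_exclusion_report,
    write_promoter_bed,
)
from .scanning import build_consensus, mapping_rate, mark_genes, scan_normalized, scan_pvalue
from .simulate import (
    PlantedMotif,
    SyntheticSpec,
    at_rich_background,
    block_pwm,
    generate_ortholog_fixture,
    generate_promoter_set,
    write_ground_truth,
)

logger = logging.getLogger("promotif")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "l_prom": 1500,
    "min_length": 1500,
    "anchor": "start_codon",
    "background_order": 3,
    "background_pseudocount": 1.0,
    "widths": [6, 8, 10, 12],
    "n_motifs_per_run": 6,
    "max_sites_per_seq": 3,
    "n_iterations": 200,
    "n_runs": 100,
    "min_runs": 10,
    "distance_threshold": 0.3,
    "min_overlap": 4,
    "annotation_cutoff": 0.3,
    "locator_threshold": 0.9,
    "p_threshold": 1e-4,
    "n_random_promoters": 10000,
    "mapping_fold": 1.5,
    "mapping_rule": "fold",
    "colocate": "identical",
    "n_top_sorghum": 10,
    "n_top_arabidopsis": 5,
    "e_max": 1e-3,
    "min_identity": 30.0,
    "min_coverage": 50.0,
    "ortholog_mode": "high_confidence",
    "alpha": 0.05,
    # simulate-only knobs
    "sim_n_genes": 500,
    "sim_promoter_length": 1500,
    "sim_deg_fraction": 0.2,
    "sim_module_size": 50,
}


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    import yaml

    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(user)
    if overrides:
        config.update(overrides)
    return config


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(stage: str, outdir: Path, inputs: list[Path], config: dict) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.get("seed"),
        "config": {k: v for k, v in sorted(config.items())},
        "inputs": {str(p): _checksum(Path(p)) for p in inputs if Path(p).exists()},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def stage_simulate(outdir: Path, config: dict) -> None:
    """Write a complete toy study directory with known ground truth."""
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    bg = at_rich_background()
    planted = [
        PlantedMotif(block_pwm("TTGACC", motif_id="planted_WRKY"), "WRKY", 0.7, 0.25),
        PlantedMotif(block_pwm("CACGTGTC", motif_id="planted_bHLH"), "bHLH", 0.6, 0.2),
        PlantedMotif(block_pwm("GCCGCCTCTA", motif_id="planted_AP2-ERF"), "AP2-ERF", 0.5, 0.2),
    ]
    spec = SyntheticSpec(
        seed=seed,
        n_genes=int(config["sim_n_genes"]),
        promoter_length=int(config["sim_promoter_length"]),
        background=bg,
        planted_motifs=planted,
        deg_fraction=float(config["sim_deg_fraction"]),
    )
    genome, genes, truth = generate_promoter_set(spec)
    write_fasta(genome, outdir / "genome.fasta")
    _write_gff3(genes, outdir / "genes.gff3")
    # intergenic sequence for background estimation: fresh background draws
    intergenic = {
        f"intergenic_{i}": bg.sample(2000, rng) for i in range(30)
    }
    from .io_formats import SequenceSet

    write_fasta(SequenceSet(intergenic), outdir / "intergenic.fasta")
    lib = MotifLibrary(
        [
            MotifLibraryEntry(pm.pwm.motif_id, pm.tf_family, pm.pwm, "synthetic")
            for pm in planted
        ]
    )
    write_motif_library(lib, outdir / "motif_library.txt")
    degs = [tid for tid, d in truth.deg_labels.items() if d]
    write_gene_list(degs, outdir / "deg_ids.txt")
    # co-expression module stand-in: genes carrying the first planted family,
    # topped up with random others
    first_family = planted[0].tf_family
    module = [t for t, fams in truth.family_indicator.items() if first_family in fams]
    rest = [t for t in truth.deg_labels if t not in set(module)]
    size = int(config["sim_module_size"])
    module = module[:size]
    if len(module) < size:
        extra = rng.permutation(len(rest))[: size - len(module)]
        module += [rest[i] for i in extra]
    write_gene_list(sorted(module), outdir / "module_genes.txt")
    sc_sb, sc_at, relations, targets, family_of_tf, triples = generate_ortholog_fixture(
        list(truth.deg_labels),
        seed=seed + 1,
        families_targets={
            pm.tf_family: {
                t for t, fams in truth.family_indicator.items() if pm.tf_family in fams
            }
            for pm in planted
        },
    )
    _write_outfmt6(sc_sb, outdir / "sc_sb.blast.tsv", rng)
    _write_outfmt6(sc_at, outdir / "sc_at.blast.tsv", rng)
    relations.to_csv(outdir / "sb_at_relations.tsv", sep="\t", index=False)
    targets.to_csv(outdir / "at_targets.tsv", sep="\t", index=False)
    family_of_tf.to_csv(outdir / "family_of_tf.tsv", sep="\t", index=False)
    write_ground_truth(truth, outdir / "ground_truth.tsv")
    write_manifest("simulate", outdir, [], config)
    logger.info("simulate: %d genes, %d DEGs, %d module genes", spec.n_genes, len(degs), len(module))


def _write_gff3(genes, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in genes.df.iterrows():
            if row.feature_kind == "gene":
                attrs = f"ID={row.gene_id}"
            else:
                attrs = f"ID={row.gene_id}.cds;Parent={row.gene_id}"
            fh.write(
                f"{row.seq_id}\tsynthetic\t{row.feature_kind}\t{row.start}\t"
                f"{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def _write_outfmt6(aln, path: Path, rng) -> None:
    df = aln.df
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.percent_identity:.2f}\t100\t0\t0\t"
                f"1\t100\t1\t100\t{r.e_value:g}\t{r.bit_score:.1f}\t{r.query_coverage:.2f}\n"
            )


def _load_promoters(outdir: Path, subset: list[str] | None = None) -> PromoterUniverse:
    from .promoters import PromoterRecord

    seqs = read_fasta(outdir / "promoters.fasta")
    records = []
    for tid, seq in seqs.records.items():
        if subset is not None and tid not in subset:
            continue
        records.append(PromoterRecord(tid, tid, tid, (0, len(seq)), "+", seq))
    return PromoterUniverse(records, [])


def stage_promoters(outdir: Path, config: dict) -> None:
    genome = read_fasta(outdir / "genome.fasta")
    genes = read_gff3_genes(outdir / "genes.gff3")
    universe = extract_promoters(
        genome,
        genes,
        l_prom=int(config["l_prom"]),
        min_length=int(config["min_length"]),
        anchor=str(config["anchor"]),
    )
    write_fasta(universe.sequences(), outdir / "promoters.fasta")
    write_promoter_bed(universe, str(outdir / "promoters.bed"))
    write_exclusion_report(universe, str(outdir / "exclusions.tsv"))
    write_manifest(
        "promoters", outdir, [outdir / "genome.fasta", outdir / "genes.gff3"], config
    )
    logger.info("promoters: %d kept, %d excluded", len(universe), len(universe.excluded))


def stage_background(outdir: Path, config: dict) -> None:
    intergenic = read_fasta(outdir / "intergenic.fasta")
    model = build_background(
        intergenic,
        order=int(config["background_order"]),
        pseudocount=float(config["background_pseudocount"]),
    )
    model.save(outdir / "background.tsv")
    write_manifest("background", outdir, [outdir / "intergenic.fasta"], config)
    logger.info("background: order %d estimated", model.order)


def stage_discover(outdir: Path, config: dict) -> None:
    module_ids = read_gene_list(outdir / "module_genes.txt")
    promoters = _load_promoters(outdir, subset=module_ids)
    background = BackgroundModel.load(outdir / "background.tsv")
    candidates = replicate_runs(
        promoters,
        background,
        n_runs=int(config["n_runs"]),
        seed=int(config["seed"]),
        widths=tuple(config["widths"]),
        n_motifs_per_run=int(config["n_motifs_per_run"]),
        max_sites_per_seq=int(config["max_sites_per_seq"]),
        n_iterations=int(config["n_iterations"]),
    )
    groups = rank_and_group(
        candidates,
        distance_threshold=float(config["distance_threshold"]),
        min_overlap=int(config["min_overlap"]),
    )
    valid = filter_valid(
        groups, min_runs=int(config["min_runs"]), total_runs=int(config["n_runs"])
    )
    deduped = dedupe_across_widths(
        valid,
        distance_threshold=float(config["distance_threshold"]),
        min_overlap=int(config["min_overlap"]),
    )
    lib = MotifLibrary(
        [
            MotifLibraryEntry(g.group_id, "de_novo", g.representative, "discovery")
            for g in deduped
        ]
    )
    write_motif_library(lib, outdir / "valid_motifs.txt")
    write_groups_tsv(deduped, str(outdir / "valid_groups.tsv"))
    write_manifest(
        "discover",
        outdir,
        [outdir / "promoters.fasta", outdir / "background.tsv", outdir / "module_genes.txt"],
        config,
    )
    logger.info(
        "discover: %d candidates -> %d groups -> %d valid",
        len(candidates),
        len(groups),
        len(deduped),
    )


def stage_annotate(outdir: Path, config: dict) -> None:
    valid = read_motif_library(outdir / "valid_motifs.txt")
    library = read_motif_library(outdir / "motif_library.txt")
    queries = [e.pwm for e in valid]
    annotated, unannotated = annotate_against_library(
        queries,
        library,
        distance_cutoff=float(config["annotation_cutoff"]),
        min_overlap=int(config["min_overlap"]),
    )
    write_annotation_tsv(annotated, library, str(outdir / "annotation.tsv"))
    write_gene_list(unannotated, outdir / "unannotated_groups.txt")
    write_manifest(
        "annotate", outdir, [outdir / "valid_motifs.txt", outdir / "motif_library.txt"], config
    )
    logger.info("annotate: %d annotated, %d novel", len(annotated), len(unannotated))


def stage_scan(outdir: Path, config: dict) -> None:
    """Family-PWM p-value scan over all promoters, plus locator mapping
    rates of the de novo valid motifs against a random promoter sample."""
    promoters = _load_promoters(outdir)
    background = BackgroundModel.load(outdir / "background.tsv")
    library = read_motif_library(outdir / "motif_library.txt")
    hits = []
    for entry in library:
        hits.extend(
            scan_pvalue(
                promoters,
                entry.pwm,
                background,
                p_threshold=float(config["p_threshold"]),
                tf_family=entry.tf_family,
            )
        )
    write_hits_bed(hits, outdir / "hits.bed")
    _write_hits_tsv(hits, outdir / "hits.tsv")
    # locator mapping-rate enrichment of de novo motifs
    valid_path = outdir / "valid_motifs.txt"
    rows = []
    if valid_path.exists():
        valid = read_motif_library(valid_path)
        module_ids = read_gene_list(outdir / "module_genes.txt")
        target = _load_promoters(outdir, subset=module_ids)
        random_set = sample_random_promoters(
            promoters, n=int(config["n_random_promoters"]), seed=int(config["seed"])
        )
        for entry in valid:
            t_hits = scan_normalized(
                target, entry.pwm, background, t=float(config["locator_threshold"])
            )
            r_hits = scan_normalized(
                random_set, entry.pwm, background, t=float(config["locator_threshold"])
            )
            res = mapping_rate(
                t_hits,
                target,
                random_set,
                r_hits,
                fold=float(config["mapping_fold"]),
                rule=str(config["mapping_rule"]),
            )
            rows.append(
                (entry.motif_id, res.rate_target, res.rate_random, res.enriched)
            )
    with open(outdir / "mapping_rates.tsv", "w") as fh:
        fh.write("motif_id\trate_target\trate_random\tenriched\n")
        for mid, rt, rr, e in rows:
            fh.write(f"{mid}\t{rt:.6g}\t{rr:.6g}\t{e}\n")
    write_manifest(
        "scan", outdir, [outdir / "promoters.fasta", outdir / "motif_library.txt"], config
    )
    logger.info("scan: %d hits", len(hits))


def _write_hits_tsv(hits, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("promoter_id\tmotif_id\ttf_family\tstart\tend\tstrand\traw_score\tp_value\n")
        for h in sorted(hits, key=lambda h: (h.promoter_id, h.interval, h.motif_id)):
            fh.write(
                f"{h.promoter_id}\t{h.motif_id}\t{h.tf_family}\t{h.interval[0]}\t"
                f"{h.interval[1]}\t{h.strand}\t{h.raw_score:.6g}\t{h.p_value!r}\n"
            )


def _read_hits_tsv(path: Path):
    from .scanning import MotifHit

    df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(
            promoter_id=r.promoter_id,
            motif_id=r.motif_id,
            tf_family=r.tf_family,
            interval=(int(r.start), int(r.end)),
            strand=r.strand,
            raw_score=float(r.raw_score),
            p_value=float(r.p_value),
        )
        for r in df.itertuples()
    ]


def stage_consensus(outdir: Path, config: dict) -> None:
    hits = _read_hits_tsv(outdir / "hits.tsv")
    consensus = build_consensus(hits, colocate=str(config["colocate"]))
    with open(outdir / "consensus.tsv", "w") as fh:
        fh.write("promoter_id\tstart\tend\tfamilies\tn_hits\n")
        for c in consensus:
            fh.write(
                f"{c.promoter_id}\t{c.interval[0]}\t{c.interval[1]}\t"
                f"{','.join(sorted(c.families))}\t{len(c.supporting_hits)}\n"
            )
    promoter_to_gene = {h.promoter_id: h.promoter_id for h in hits}
    # include all promoters so unmarked genes are reported too
    seqs = read_fasta(outdir / "promoters.fasta")
    for tid in seqs.records:
        promoter_to_gene.setdefault(tid, tid)
    statuses = mark_genes(hits, consensus, promoter_to_gene)
    with open(outdir / "gene_status.tsv", "w") as fh:
        fh.write("gene_id\ttotal_hits\thas_consensus\tmarked\n")
        for s in statuses:
            fh.write(f"{s.gene_id}\t{s.total_hits}\t{s.has_consensus}\t{s.marked}\n")
    write_manifest("consensus", outdir, [outdir / "hits.tsv"], config)
    logger.info("consensus: %d sites", len(consensus))


def stage_orthomap(outdir: Path, config: dict) -> None:
    sc_sb = read_blast_table(outdir / "sc_sb.blast.tsv")
    sc_at = read_blast_table(outdir / "sc_at.blast.tsv")
    relations = pd.read_csv(outdir / "sb_at_relations.tsv", sep="\t")
    sc_sb_f = top_hits(
        sc_sb,
        n_top=int(config["n_top_sorghum"]),
        e_max=float(config["e_max"]),
        min_identity=float(config["min_identity"]),
        min_coverage=float(config["min_coverage"]),
    )
    sc_at_f = top_hits(
        sc_at,
        n_top=int(config["n_top_arabidopsis"]),
        e_max=float(config["e_max"]),
        min_identity=float(config["min_identity"]),
        min_coverage=float(config["min_coverage"]),
    )
    ortho = chain_orthologs(
        sc_sb_f,
        sc_at_f,
        relations,
        mode=str(config["ortholog_mode"]),
        min_identity=float(config["min_identity"]),
        min_coverage=float(config["min_coverage"]),
    )
    ortho.to_tsv(str(outdir / "orthomap.tsv"))
    write_manifest(
        "orthomap",
        outdir,
        [outdir / "sc_sb.blast.tsv", outdir / "sc_at.blast.tsv", outdir / "sb_at_relations.tsv"],
        config,
    )
    logger.info("orthomap: %d rows", len(ortho))


def stage_enrich(outdir: Path, config: dict) -> None:
    from .orthology import OrthologMap

    df = pd.read_csv(outdir / "orthomap.tsv", sep="\t", comment="#")
    ortho = OrthologMap(
        df,
        min_identity=float(config["min_identity"]),
        min_coverage=float(config["min_coverage"]),
    )
    targets = pd.read_csv(outdir / "at_targets.tsv", sep="\t")
    family_of_tf = pd.read_csv(outdir / "family_of_tf.tsv", sep="\t")
    seqs = read_fasta(outdir / "promoters.fasta")
    universe_ids = set(seqs.records)
    target_sets = propagate_targets(ortho, targets, family_of_tf, universe_ids)
    hits = _read_hits_tsv(outdir / "hits.tsv")
    degs = set(read_gene_list(outdir / "deg_ids.txt"))
    tfbs_by_family: dict[str, set[str]] = {}
    for h in hits:
        tfbs_by_family.setdefault(h.tf_family, set()).add(h.promoter_id)
    results = []
    for ts in target_sets:
        if not ts.member_transcript_ids:
            continue
        universe = set(ts.member_transcript_ids)
        results.append(
            test_family(
                ts.tf_family,
                universe,
                degs & universe,
                tfbs_by_family.get(ts.tf_family, set()),
                alpha=float(config["alpha"]),
            )
        )
    if results:
        bonferroni(results, alpha=float(config["alpha"]))
    write_enrichment_tsv(results, str(outdir / "enrichment.tsv"))
    write_manifest(
        "enrich",
        outdir,
        [outdir / "orthomap.tsv", outdir / "hits.tsv", outdir / "deg_ids.txt"],
        config,
    )
    logger.info("enrich: %d families tested", len(results))


STAGES = {
    "simulate": stage_simulate,
    "promoters": stage_promoters,
    "background": stage_background,
    "discover": stage_discover,
    "annotate": stage_annotate,
    "scan": stage_scan,
    "consensus": stage_consensus,
    "orthomap": stage_orthomap,
    "enrich": stage_enrich,
}

#: stage order for `all`: discovery track first, then the enrichment track
ALL_ORDER = [
    "promoters",
    "background",
    "discover",
    "annotate",
    "scan",
    "consensus",
    "orthomap",
    "enrich",
]


def run_all(outdir: Path, config: dict) -> None:
    for name in ALL_ORDER:
        STAGES[name](outdir, config)
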