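#!/usr/bin/env python
"""Step 1: generate the synthetic drought-transcriptome study.

Writes a complete study directory under results/study/: a toy genome with
gene models, intergenic sequence for the background model, a reference motif
library with the three planted TF-family motifs (WRKY, bHLH, AP2-ERF), DEG
and co-expression-module gene lists, toy ortholog/alignment tables, and the
ground-truth table used by later steps for evaluation.
"""

from pathlib import Path

from promotif.pipeline import STAGES, load_config

CONFIG_OVERRIDES = {
    "seed": 1,
    "sim_n_genes": 500,
    "sim_promoter_length": 1500,
    "sim_module_size": 50,
    # scaled discovery settings shared by all steps (see docs/methods.md)
    "widths": [6, 8],
    "n_motifs_per_run": 2,
    "n_iterations": 100,
    "n_runs": 25,
    "min_runs": 5,
    "n_random_promoters": 500,
}

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    STUDY.mkdir(parents=True, exist_ok=True)
    config = load_config(None, CONFIG_OVERRIDES)
    import yaml

    (STUDY / "config.yaml").write_text(yaml.safe_dump(CONFIG_OVERRIDES))
    STAGES["simulate"](STUDY, config)
    print(f"study written to {STUDY}")
    print("key files: genome.fasta genes.gff3 intergenic.fasta deg_ids.txt "
          "module_genes.txt motif_library.txt ground_truth.tsv")


if __name__ == "__main__":
    main()
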