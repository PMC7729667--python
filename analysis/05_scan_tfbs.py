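#!/usr/bin/env python
"""Step 5: scan promoters for TFBSs and build consensus sites.

Scans every promoter with the family PWMs (exact p-value scanner), computes
locator-style mapping-rate enrichment of the de novo motifs against a
random promoter sample, then derives consensus sites (co-located hits of
two or more TF families) and per-gene TFBS status.
"""

from pathlib import Path

from promotif.pipeline import STAGES, load_config

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    config = load_config(STUDY / "config.yaml")
    STAGES["scan"](STUDY, config)
    STAGES["consensus"](STUDY, config)
    n_hits = len((STUDY / "hits.tsv").read_text().splitlines()) - 1
    n_cons = len((STUDY / "consensus.tsv").read_text().splitlines()) - 1
    marked = sum(
        line.split("\t")[-1] == "True"
        for line in (STUDY / "gene_status.tsv").read_text().splitlines()[1:]
    )
    print(f"{n_hits} TFBS hits; {n_cons} consensus sites; {marked} genes marked")
    print((STUDY / "mapping_rates.tsv").read_text().rstrip())


if __name__ == "__main__":
    main()
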