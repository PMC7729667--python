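#!/usr/bin/env python
"""Step 6: chain orthologs sugarcane -> sorghum -> Arabidopsis.

Filters the protein-alignment tables (top hits below the e-value cutoff
with identity/coverage floors) and joins them through the curated
sorghum-Arabidopsis relation table into the high-confidence ortholog map
used for TF-target propagation.
"""

from pathlib import Path

from promotif.pipeline import STAGES, load_config

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    config = load_config(STUDY / "config.yaml")
    STAGES["orthomap"](STUDY, config)
    lines = (STUDY / "orthomap.tsv").read_text().splitlines()
    print(f"{len(lines) - 2} ortholog rows -> {STUDY / 'orthomap.tsv'}")
    for line in lines[:5]:
        print("  " + line)


if __name__ == "__main__":
    main()
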