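#!/usr/bin/env python
"""Step 7: hypergeometric DEG enrichment per TF family.

Propagates each family's Arabidopsis TF targets back to sugarcane
transcripts through the ortholog map, builds the 2x2 DEG x TFBS
contingency per family, and applies the upper-tail hypergeometric test
with Bonferroni control across families.
"""

from pathlib import Path

from promotif.pipeline import STAGES, load_config

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    config = load_config(STUDY / "config.yaml")
    STAGES["enrich"](STUDY, config)
    print((STUDY / "enrichment.tsv").read_text().rstrip())


if __name__ == "__main__":
    main()
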