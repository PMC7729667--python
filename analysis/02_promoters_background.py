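#!/usr/bin/env python
"""Step 2: extract promoters and estimate the intergenic background model.

Extracts the 1,500-bp region upstream of each start codon (dropping
promoters that overlap a neighbouring CDS or are truncated by a contig
edge) and fits the k-th-order Markov background from intergenic sequence.
"""

from pathlib import Path

from promotif.pipeline import STAGES, load_config

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    config = load_config(STUDY / "config.yaml")
    STAGES["promoters"](STUDY, config)
    STAGES["background"](STUDY, config)
    n = sum(1 for l in (STUDY / "promoters.fasta").read_text().splitlines()
            if l.startswith(">"))
    print(f"{n} promoters extracted; background model: {STUDY / 'background.tsv'}")


if __name__ == "__main__":
    main()
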