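#!/usr/bin/env python
"""Step 4: annotate discovered motifs against the reference motif library.

Each valid de novo motif is assigned to its nearest reference PWM by
symmetrised KL distance over the best ungapped alignment; motifs with no
neighbour inside the cutoff are reported as novel.
"""

from pathlib import Path

from promotif.pipeline import STAGES, load_config

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    config = load_config(STUDY / "config.yaml")
    STAGES["annotate"](STUDY, config)
    print((STUDY / "annotation.tsv").read_text().rstrip())
    novel = (STUDY / "unannotated_groups.txt").read_text().split()
    print(f"novel (unannotated) motifs: {len(novel)}")


if __name__ == "__main__":
    main()
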