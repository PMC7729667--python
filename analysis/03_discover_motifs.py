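#!/usr/bin/env python
"""Step 3: de novo motif discovery on the co-expression module promoters.

Runs the replicated Gibbs site sampler over the module promoters, groups
candidate PWMs by KL distance, keeps groups found in enough independent
runs (the validity rule), and removes cross-width redundancy.
"""

from pathlib import Path

from promotif.pipeline import STAGES, load_config

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    config = load_config(STUDY / "config.yaml")
    STAGES["discover"](STUDY, config)
    lines = (STUDY / "valid_groups.tsv").read_text().splitlines()
    print(f"{len(lines) - 1} valid motif groups -> {STUDY / 'valid_motifs.txt'}")
    for line in lines[:6]:
        print("  " + line)


if __name__ == "__main__":
    main()
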