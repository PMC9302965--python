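"""Generate the synthetic two-cell-type, two-platform ATAC-seq study.

Writes per-sample fragment BEDs and narrowPeak calls, TSS/feature/blacklist
annotation, expression and motif tables, and the ground truth under
results/sim/.  All downstream drivers read from that directory.
"""

import argparse

from atacpeaks.cli import main as cli


def run(seed: int) -> None:
    cli.main(
        ["simulate", "--out-dir", "results/sim", "--seed", str(seed)],
        standalone_mode=False,
    )
    print(f"synthetic study written to results/sim (seed {seed})")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    run(parser.parse_args().seed)
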