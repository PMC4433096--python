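#!/usr/bin/env python
"""Build the seven-taxon 80-run mixture design and write it to results/.

The special cubic model in seven components has 7 + C(7,2) + C(7,3) = 63
coefficients, so the D-optimal support holds 63 runs; two interior
lack-of-fit runs and 15 replicate runs bring the design to 80 runs over 65
unique treatment combinations, with run order randomized.
"""

from pathlib import Path

import mockbias as mb

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    taxa = mb.vaginal_panel()
    names = [t.name for t in taxa]
    print(f"panel: {len(taxa)} taxa -> minimum runs {mb.special_cubic_size(7)}")
    design = mb.build_design(7, seed=SEED, taxa=names)
    design.to_csv(RESULTS / "design.csv")
    print(
        f"assembled {design.n_runs} runs ({design.n_unique_treatments} unique "
        f"treatments, {(design.role == 'replicate').sum()} replicates, "
        f"{(design.role == 'lack_of_fit').sum()} lack-of-fit) -> results/design.csv"
    )


if __name__ == "__main__":
    main()
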