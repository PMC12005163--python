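#!/usr/bin/env python
"""Run the stepwise nested-LRT ladders on the working dataset.

Three ladders over the full dataset (species x context, divergence x
gene class, polymorphism x gene class) and one over the divergence-only
mel/ana subset (piRNA compartments).  Writes one JSON report per ladder
under results/selection/ and prints the selected model of each.
"""

import argparse
import json
from pathlib import Path

import mknest as mk


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/selection"))
    parser.add_argument("--threshold", type=float, default=0.05)
    args = parser.parse_args()
    counts = args.data_dir / "counts.tsv"
    if not counts.exists():
        raise SystemExit(f"{counts} missing; run analysis/01_simulate.py first")
    ds = mk.read_variant_table(str(counts), str(args.data_dir / "classes.tsv"))
    args.out_dir.mkdir(parents=True, exist_ok=True)

    runs = [
        ("species-context", ds),
        ("divergence-class", ds),
        ("polymorphism-class", ds),
        ("compartment", ds.subset(species=["mel", "ana"],
                                  contexts=["divergence"])),
    ]
    for name, data in runs:
        report = mk.run_ladder(data, mk.preset_ladder(name),
                               threshold=args.threshold)
        (args.out_dir / f"ladder_{name}.json").write_text(
            json.dumps(report.to_dict(), indent=2, default=float)
        )
        sel = report.selected
        print(f"{name}: selected {sel.model.name} "
              f"(K = {sel.K}, loglik = {sel.loglik:.1f}) after "
              f"{len(report.steps)} tiers")


if __name__ == "__main__":
    main()
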