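#!/usr/bin/env python
"""Generate the default synthetic study bundle.

Writes the five input files (annotation table, curated regulator list,
expression matrix, interaction edge list, knockdown-evidence table), the
ground-truth JSON, and a ready-to-run pipeline config under
results/bundle/. The bundle plants three shared candidate regulators
(CAND1-3), one breast-only candidate, and three decoys that each violate
one selection criterion.
"""

from pathlib import Path

from golgiscreen.synth import default_config, simulate_bundle, write_bundle

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "bundle"


def main() -> None:
    cfg = default_config(SEED)
    bundle = simulate_bundle(cfg)
    paths = write_bundle(bundle, OUT)
    truth = bundle.ground_truth
    print(f"wrote bundle (seed {SEED}) to {OUT}")
    print(f"  genes: {cfg.n_genes}, universe: {cfg.n_universe}, planted: {len(cfg.planted)}")
    for ct, genes in truth.expected_selected.items():
        print(f"  expected selected [{ct}]: {sorted(genes)}")
    print(f"  expected common: {sorted(truth.common_genes)}")
    print(f"  files: {', '.join(sorted(Path(p).name for p in paths.values()))}")


if __name__ == "__main__":
    main()
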