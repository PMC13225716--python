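#!/usr/bin/env python
"""Fold-change screening of both cell-line pairs on the simulated bundle.

Reads results/bundle/ (run 01_simulate.py first), screens the
Golgi-associated universe genes for each cancer-type pair (breast:
MDAMB231 vs MCF7 at threshold >=10; lung: A549 vs CALU1 at >=5, both with
the adaptive top-50 cap) and writes per-pair DEG tables under results/.
"""

from pathlib import Path

from golgiscreen.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"
OUT = ROOT / "results"


def main() -> None:
    cfg = PipelineConfig.from_yaml(BUNDLE / "run_config.yaml")
    result = run_pipeline(cfg, write=False)
    OUT.mkdir(parents=True, exist_ok=True)
    for ct, table in result.deg_tables.items():
        path = OUT / f"degs_{ct}.tsv"
        table.to_frame().to_csv(path, sep="\t", index=False)
        passed = table.passed
        print(
            f"{ct}: screened {len(table.records)} universe genes, "
            f"{len(passed)} DEGs passed at effective threshold {table.effective_threshold:g}"
        )
        print(f"  DEGs: {[r.gene for r in passed]}")
        print(f"  wrote {path}")


if __name__ == "__main__":
    main()
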