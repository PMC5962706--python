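"""Run the full pipeline on the simulated cohort and summarize detections.

Reads the fixture tables written by 01_simulate_cohort.py, runs
normalization -> per-type detection -> aggregation -> clustering ->
outcome (scratch/pipeline/), then copies the compact summary tables
(per-type signatures, Venn partition, manifest) into results/ and prints
how the detected signatures compare with the planted ground truth.
"""

import json
import shutil
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import PLANTED, cohort_config

from pathosig.config import parse_config
from pathosig.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
PIPELINE_OUT = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    if not (COHORT / "signals.tsv").exists():
        sys.exit("run analysis/01_simulate_cohort.py first")
    config = parse_config(
        {
            "seed": cohort_config().seed,
            "inputs": {
                "signals": str(COHORT / "signals.tsv"),
                "annotations": str(COHORT / "annotations.tsv"),
                "metadata": str(COHORT / "metadata.tsv"),
            },
        }
    )
    manifest = run_pipeline(config, PIPELINE_OUT)

    RESULTS.mkdir(exist_ok=True)
    for cancer_type in manifest["cancer_types"]:
        shutil.copy(PIPELINE_OUT / f"signatures_{cancer_type}.tsv", RESULTS)
    shutil.copy(PIPELINE_OUT / "venn_partition.json", RESULTS)
    shutil.copy(PIPELINE_OUT / "venn_partition.tsv", RESULTS)
    shutil.copy(PIPELINE_OUT / "manifest.json", RESULTS)

    truth = {s.organism: set(s.target_groups) for s in PLANTED}
    print("reported signatures per cancer type (planted organisms marked *):")
    for cancer_type in manifest["cancer_types"]:
        table = pd.read_csv(RESULTS / f"signatures_{cancer_type}.tsv", sep="\t")
        marked = [
            f"{org}*" if cancer_type in truth.get(org, set()) else org
            for org in table["organism"]
        ]
        print(f"  {cancer_type} ({len(marked)}): {', '.join(marked) or '-'}")
    venn = json.loads((RESULTS / "venn_partition.json").read_text())
    print("Venn partition (unique/shared across types):")
    for cell, organisms in venn.items():
        print(f"  {cell}: {', '.join(organisms)}")


if __name__ == "__main__":
    main()
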