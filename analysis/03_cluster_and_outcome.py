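"""Summarize sample clustering and outcome association on the cohort run.

Reads the pipeline outputs from scratch/pipeline/ (run 02 first), copies
the compact cluster and outcome tables into results/ and prints, per
cancer type: the Calinski-Harabasz-selected cluster count, the deceased
proportion per cluster, and organisms whose signature signal associates
with outcome at nominal p < 0.05.
"""

import json
import shutil
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
PIPELINE_OUT = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    manifest_path = PIPELINE_OUT / "manifest.json"
    if not manifest_path.exists():
        sys.exit("run analysis/02_detect_signatures.py first")
    manifest = json.loads(manifest_path.read_text())
    RESULTS.mkdir(exist_ok=True)

    print("clustering (Euclidean, complete linkage, CH-index selection):")
    for tag, block in manifest["clustering"].items():
        if block.get("skipped"):
            print(f"  {tag}: skipped ({block['n_organisms']} organisms, {block['n_samples']} samples)")
            continue
        for name in (f"ch_curve_{tag}.tsv", f"cluster_outcomes_{tag}.tsv", f"dendrogram_{tag}.nwk"):
            shutil.copy(PIPELINE_OUT / name, RESULTS)
        outcomes = pd.read_csv(RESULTS / f"cluster_outcomes_{tag}.tsv", sep="\t")
        parts = [
            f"cluster {int(row.cluster)}: {row.n_deceased}/{row.n_alive + row.n_deceased} deceased"
            for row in outcomes.itertuples()
            if row.n_alive + row.n_deceased > 0
        ]
        print(f"  {tag}: selected k = {block['selected_k']}; " + "; ".join(parts))

    print("outcome associations (one-sided Welch t on signature signals):")
    for cancer_type, block in manifest["outcome"].items():
        if block.get("skipped"):
            print(f"  {cancer_type}: skipped")
            continue
        shutil.copy(PIPELINE_OUT / f"outcome_{cancer_type}.tsv", RESULTS)
        table = pd.read_csv(RESULTS / f"outcome_{cancer_type}.tsv", sep="\t")
        sig = table[table["flag"] == "significant"]
        desc = [
            f"{row.organism} ({row.direction}, p={row.p:.3g})" for row in sig.itertuples()
        ] or ["none (outcomes are assigned independently of signals in this cohort)"]
        print(f"  {cancer_type}: {len(sig)} significant: " + "; ".join(desc))


if __name__ == "__main__":
    main()
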