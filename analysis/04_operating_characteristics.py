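"""Measure the pipeline's operating characteristics on replicate simulations.

Runs the null-calibration, planted-recovery, cluster-count-recovery and
outcome power/size studies (see pathosig.evaluation) and writes a one-row
summary table to results/operating_characteristics.tsv.
"""

from pathlib import Path

import pandas as pd

from pathosig.evaluation import (
    cluster_count_recovery,
    null_signature_rate,
    outcome_power_and_size,
    planted_recovery,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260927


def main() -> None:
    null_df = null_signature_rate(n_seeds=100, seed=SEED)
    rec = planted_recovery(n_seeds=50, seed=SEED + 1)
    blobs = cluster_count_recovery(n_seeds=100, seed=SEED + 2)
    power = outcome_power_and_size(n_seeds=100, seed=SEED + 3)

    summary = pd.DataFrame(
        [
            ("null clean-run rate (%)", 100 * (null_df["n_reported"] == 0).mean(), len(null_df)),
            ("planted sensitivity (%)", 100 * rec["n_recovered"].sum() / rec["n_planted"].sum(), len(rec)),
            ("decoy false positives per run", rec["n_decoys_reported"].mean(), len(rec)),
            ("cluster-count recovery (%)", 100 * (blobs["selected_k"] == blobs["planted_k"]).mean(), len(blobs)),
            ("outcome power (%)", 100 * power["planted_detected"].mean(), len(power)),
            (
                "outcome false-positive rate (%)",
                100 * power["n_null_positive"].sum() / power["n_null_tests"].sum(),
                int(power["n_null_tests"].sum()),
            ),
        ],
        columns=["metric", "value", "n"],
    )
    out = ROOT / "results" / "operating_characteristics.tsv"
    out.parent.mkdir(exist_ok=True)
    summary.to_csv(out, sep="\t", index=False, float_format="%.4g")
    print(summary.to_string(index=False))
    print(f"written to {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
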