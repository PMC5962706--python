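"""Simulate the demonstration cohort and write its input tables.

Writes the signal, annotation, metadata and ground-truth tables for a
synthetic 168-case / 20-control two-channel array experiment with six
planted organism signatures.  The raw tables are large, so they go to
scratch/cohort/ (regenerate any time by re-running this script).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort import cohort_config

from pathosig.simulate import simulate_experiment, write_fixture

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "cohort"


def main() -> None:
    config = cohort_config()
    experiment = simulate_experiment(config)
    paths = write_fixture(experiment, OUT)
    n_carriers = int(experiment.truth["carrier"].sum())
    print(f"simulated {experiment.arrays.n_probes} probes x {experiment.arrays.n_samples} samples")
    print(f"planted {len(config.signatures)} signatures; {n_carriers} carrier (organism, sample) pairs")
    for name, path in paths.items():
        print(f"  {name}: {path.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
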