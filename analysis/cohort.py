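"""Shared definition of the demonstration cohort used by the analysis scripts.

A synthetic case/control cohort shaped like the emulated screen: four
breast-cancer groups (50 endocrine-receptor-positive, 34 HER2-positive,
24 triple-positive, 40 triple-negative) plus 20 healthy-control breast
samples, with a mix of planted organism signatures — some shared by all
cancer types, some restricted to a subset — on top of 20 decoy organisms.
"""

from pathosig.simulate import PlantedSignature, SimulationConfig

ALL_TYPES = ("BRER", "BRHR", "BRTP", "BRTN")

PLANTED = (
    PlantedSignature("Papillomaviridae", "virus", ALL_TYPES, 2.5, 0.7),
    PlantedSignature("Anelloviridae", "virus", ("BRER", "BRHR"), 2.0, 0.6),
    PlantedSignature("Brevundimonas", "bacterium", ALL_TYPES, 2.5, 0.8, 0.1),
    PlantedSignature("Mobiluncus", "bacterium", ("BRTN",), 2.2, 0.6),
    PlantedSignature("Candida", "fungus", ("BRTP", "BRTN"), 2.0, 0.55),
    PlantedSignature("Plasmodium", "parasite", ("BRHR",), 2.2, 0.6),
)


def cohort_config(seed: int = 20260927) -> SimulationConfig:
    return SimulationConfig(signatures=PLANTED, seed=seed)
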