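"""Shared paths and study conditions for the numbered analysis drivers.

The canonical simulated study: a 1200-gene ancestral genome on 5 chromosomes,
30% focal class, subjected to an old hexaploidy (gamma, Ks 1.6) and two
tetraploidies (beta 0.8, alpha 0.2) with class-biased retention 0.9 vs 0.3,
light single-gene duplication, and mild collinearity erosion.
"""

from __future__ import annotations

from pathlib import Path

from polyretain.collinearity import CollinearityParams
from polyretain.pipeline import StudyConfig
from polyretain.simulate import SimParams, default_events

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"
STUDY = RESULTS / "study"


def study_config(seed: int = 1) -> StudyConfig:
    return StudyConfig(
        sim=SimParams(
            n_genes=1200,
            n_chroms=5,
            focal_fraction=0.3,
            inversion_count=10,
            seed=seed,
        ),
        events=default_events(retention_focal=0.9, retention_background=0.3),
        collinearity=CollinearityParams(n_permutations=200, seed=seed),
    )
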