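"""Shared configuration for the numbered analysis scripts.

Every script regenerates the same synthetic study deterministically from
one seed (the run takes a couple of seconds), so each stage can be read,
rerun, and inspected on its own.
"""

import warnings
from pathlib import Path

from wheatsel.pipeline import StudyConfig, run_study

SEED = 2025
RESULTS = Path(__file__).resolve().parent.parent / "results"


def get_study():
    RESULTS.mkdir(exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(StudyConfig(seed=SEED))
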