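"""Shared defaults for the analysis drivers: one cohort, cached on disk."""

from pathlib import Path

import pandas as pd

from bmimed.cohort import PrepConfig, prepare_cohort
from bmimed.simulate import GeneratorParams, generate_cohort

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

#: The study conditions every driver analyses.
PARAMS = GeneratorParams(n=3840, seed=20160301)


def raw_cohort() -> pd.DataFrame:
    SCRATCH.mkdir(exist_ok=True)
    path = SCRATCH / "cohort_raw.csv"
    if path.exists():
        return pd.read_csv(path)
    df = generate_cohort(PARAMS)
    df.to_csv(path, index=False)
    return df


def analysis_cohort():
    data, log = prepare_cohort(raw_cohort(), PrepConfig())
    return data, log
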