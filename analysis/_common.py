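"""Shared paths and constants for the numbered analysis scripts.

The scripts form a file-based chain: each reads what the previous one wrote
under ``results/`` and writes its own tables there.  Everything is
deterministic given SEED.
"""

from pathlib import Path

SEED = 1
NOISE_SD = 0.3
N_PER_PATTERN = 5
CONDITIONS = ("control", "treated", "withdrawn")

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"
SE_CALLS = RESULTS / "se_calls"


def sample_sheet_path() -> Path:
    return DATA / "sample_sheet.tsv"


def read_sample_sheet():
    import pandas as pd

    return pd.read_csv(sample_sheet_path(), sep="\t", index_col=0)
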