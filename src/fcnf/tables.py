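"""Tab-separated table reading and writing.

All tables are UTF-8, tab-separated, single header row; floats are
serialized with 12 significant digits so that written tables round-trip
through the readers bit-stably for regression testing.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def digest(path: str | Path) -> str:
    """Short content digest used in log lines for reproducibility."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
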