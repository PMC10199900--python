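"""Small shared helpers."""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd


def read_tsv(source, **kwargs) -> pd.DataFrame:
    """Read a TSV whose metadata lines *start* with '#'.

    pandas' ``comment`` option would also truncate data fields that
    contain '#' (device tags like "Device #3" do), so full-line comments
    are stripped here instead.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [ln for ln in text.splitlines() if not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError("no data lines")
    return pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", **kwargs)
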