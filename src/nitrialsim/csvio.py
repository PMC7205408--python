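"""CSV output with embedded run metadata.

Every CSV written by the tool starts with ``#``-prefixed comment lines that
record the effective configuration (including the master seed), so any output
file is reproducible from its own header. Floats are printed with 6 decimals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.6f"


def write_csv(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write ``df`` with ``# key=value`` metadata comment lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv`, skipping metadata comments."""
    return pd.read_csv(path, comment="#")


__all__ = ["FLOAT_FORMAT", "write_csv", "read_csv"]
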