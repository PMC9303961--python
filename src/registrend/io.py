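"""CSV persistence with a seed-carrying header comment."""

from __future__ import annotations

import pandas as pd


def write_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_seed(path) -> int | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# seed="):
        return int(first.strip().split("=", 1)[1])
    return None
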