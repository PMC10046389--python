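"""Tab-separated output with provenance headers.

Every table starts with ``#`` comment lines recording the tool version, a
short hash of the generating parameters, and the parameters themselves, so
reruns with an identical configuration are byte-identical.
"""

from __future__ import annotations

import hashlib

import pandas as pd

from . import __version__


def _config_hash(params: dict) -> str:
    text = ";".join(f"{k}={params[k]}" for k in sorted(params))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, params: dict | None = None,
              float_format: str = "%.6g") -> None:
    params = params or {}
    with open(path, "w") as fh:
        fh.write(f"# pbtraj {__version__}\n")
        fh.write(f"# config_hash {_config_hash(params)}\n")
        for k in sorted(params):
            fh.write(f"# {k} = {params[k]}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
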