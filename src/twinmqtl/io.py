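"""TSV/JSON/YAML I/O with provenance headers.

Every pipeline output is plain text: TSV with an ``NA`` missing sentinel and
``#``-prefixed provenance header lines (stage, master seed, parameter hash)
so a run can be audited and reproduced byte-for-byte.  Timestamps are
deliberately excluded from payloads so identical configurations produce
identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def params_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(stage: str, seed: int, params: dict) -> list[str]:
    return [
        f"# stage: {stage}",
        f"# seed: {seed}",
        f"# params_hash: {params_hash(params)}",
    ]


def write_tsv(df: pd.DataFrame, path: str | Path, stage: str, seed: int,
              params: dict | None = None, index: bool = True,
              index_label: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(stage, seed, params or {}):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index=index,
                  index_label=index_label)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values="NA",
                       index_col=index_col)


def read_meta(path: str | Path) -> pd.DataFrame:
    """Read a cohort metadata table; the singleton zygosity level shares
    its spelling with the missing sentinel, so restore it after parsing."""
    meta = read_tsv(path)
    meta["zygosity"] = meta["zygosity"].fillna("NA")
    return meta


def write_json(obj: dict, path: str | Path, stage: str, seed: int,
               params: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": {"stage": stage, "seed": seed,
                              "params_hash": params_hash(params or {})},
               **obj}
    path.write_text(json.dumps(payload, indent=2, default=_json_default)
                    + "\n")


def _json_default(o):
    import numpy as np
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def derive_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed stream: SHA-256 of (master seed, stage name), folded
    below 2^31.  Documented splitting rule for full-run determinism."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)
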