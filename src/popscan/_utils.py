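"""Small shared helpers: seeding policy, TSV output with metadata headers."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 from a global seed and a stage name.

    Hash-based so adding a stage never perturbs another stage's random draws.
    """
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a TSV with ``#key=value`` metadata lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"#{key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_tsv`; returns (frame, metadata)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            meta[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    return df, meta


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
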