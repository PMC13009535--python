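"""Plain-text serialization with seed-carrying provenance sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
    "write_runs",
    "write_provenance",
    "sha256_of",
]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(values: np.ndarray, path: str | Path, labels=None) -> Path:
    """Square matrix as headered TSV (labels default to the row index)."""
    values = np.asarray(values)
    labels = list(labels) if labels is not None else list(range(values.shape[0]))
    pd.DataFrame(values, index=labels, columns=labels).to_csv(Path(path), sep="\t")
    return Path(path)


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)


def write_runs(runs, subject_id: str, outdir: str | Path) -> list[Path]:
    """One compressed array per run plus a TSV motion trace."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for run in runs:
        base = outdir / run.run_id
        np.savez_compressed(base.with_suffix(".npz"), data=run.data)
        pd.DataFrame({"rms": run.rms, "censored": run.censored.astype(int)}).to_csv(
            base.with_suffix(".rms.tsv"), sep="\t", index=False
        )
        written += [base.with_suffix(".npz"), base.with_suffix(".rms.tsv")]
    return written


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(path: str | Path, seed: int, **extra) -> Path:
    path = Path(path)
    payload = {"seed": int(seed), **extra}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
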