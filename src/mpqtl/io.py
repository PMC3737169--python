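"""TSV interchange formats and run manifests.

All pipeline artefacts are tab-separated text with documented headers so
they diff cleanly and load anywhere; probability matrices use a long format
(ril_id, arm, pos_bp, f1..f8) with the founder names in the header.  Every
pipeline run writes a manifest (JSON) recording the seed, a hash of the
configuration and a sha256 checksum per output file: identical manifests
imply identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import HaplotypeProbSet

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_prob_set",
    "read_prob_set",
    "write_manifest",
    "sha256_of",
]


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_prob_set(probs: HaplotypeProbSet, path: str | Path) -> Path:
    """Long-format TSV: one row per (RIL, grid position) with 8 founder columns."""
    R, P, _ = probs.probs.shape
    grid = probs.grid
    df = pd.DataFrame(
        {
            "ril_id": np.repeat(probs.ril_ids, P),
            "subpop": np.repeat([probs.subpops[r] for r in probs.ril_ids], P),
            "arm": np.tile(grid["arm"].to_numpy(), R),
            "pos_bp": np.tile(grid["pos_bp"].to_numpy(), R),
            "pos_cM": np.tile(grid["pos_cM"].to_numpy(), R),
        }
    )
    flat = probs.probs.reshape(R * P, -1)
    for k, f in enumerate(probs.founders):
        df[f] = flat[:, k]
    return write_tsv(df, path)


def read_prob_set(path: str | Path, population: str) -> HaplotypeProbSet:
    df = read_tsv(path)
    founders = [c for c in df.columns if c not in
                ("ril_id", "subpop", "arm", "pos_bp", "pos_cM")]
    ril_ids = list(pd.unique(df["ril_id"]))
    first = df[df["ril_id"] == ril_ids[0]]
    grid = first[["arm", "pos_bp", "pos_cM"]].reset_index(drop=True)
    P = len(grid)
    probs = df[founders].to_numpy(dtype=float).reshape(len(ril_ids), P, len(founders))
    subpops = dict(df.groupby("ril_id", sort=False)["subpop"].first())
    return HaplotypeProbSet(
        population=population, ril_ids=ril_ids, subpops=subpops, grid=grid, probs=probs,
        founders=founders,
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir: str | Path, config: dict, seed: int, files: list[Path]) -> Path:
    outdir = Path(outdir)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "files": {p.name: sha256_of(p) for p in sorted(files)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
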