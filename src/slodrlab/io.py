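"""CSV and JSON round-tripping for cohorts and response matrices."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohorts import Cohort, ResponseMatrix

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_responses_csv",
    "read_responses_csv",
]


def _manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".manifest.json")


def write_cohort_csv(cohort: Cohort, path) -> Path:
    """Write scores as CSV (12 significant digits) plus a sidecar
    JSON manifest carrying generator, seed and transform history."""
    path = Path(path)
    df = pd.DataFrame(cohort.scores, columns=list(cohort.variable_names))
    df.to_csv(path, index=False, float_format="%.12g")
    with open(_manifest_path(path), "w") as fh:
        json.dump(cohort.provenance, fh, indent=2, default=str)
    return path


def read_cohort_csv(path) -> Cohort:
    path = Path(path)
    df = pd.read_csv(path)
    manifest = {}
    mp = _manifest_path(path)
    if mp.exists():
        with open(mp) as fh:
            manifest = json.load(fh)
    if not manifest:
        manifest = {"generator": "external", "source": str(path)}
    return Cohort(
        scores=df.to_numpy(dtype=float),
        variable_names=tuple(df.columns),
        provenance=manifest,
    )


def write_responses_csv(matrix: ResponseMatrix, path) -> Path:
    """Respondent-id column plus one 0/1 column per item; the
    item-to-scale map goes to a sidecar JSON."""
    path = Path(path)
    cols = {f"item{j+1}": matrix.responses[:, j] for j in range(matrix.n_items)}
    df = pd.DataFrame({"respondent": list(matrix.respondent_ids), **cols})
    df.to_csv(path, index=False)
    with open(_manifest_path(path), "w") as fh:
        json.dump(
            {f"item{j+1}": s for j, s in enumerate(matrix.item_scales)},
            fh,
            indent=2,
        )
    return path


def read_responses_csv(path) -> ResponseMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    ids = tuple(df["respondent"])
    items = [c for c in df.columns if c != "respondent"]
    with open(_manifest_path(path)) as fh:
        scale_map = json.load(fh)
    return ResponseMatrix(
        responses=df[items].to_numpy(dtype=np.int8),
        item_scales=tuple(scale_map[c] for c in items),
        respondent_ids=ids,
    )
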