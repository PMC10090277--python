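"""Compound/activity ingestion and the pIC50 activity transform.

Activities are modelled on the transformed scale ``offset − log10(IC50[µM])``
with a default offset of 6, so that an IC50 of 1 µM maps to 6.0 (the
µM→M conversion is absorbed by the offset).  The bundled fixture carries
the 22 dipeptide-alkylated nitrogen-mustard derivatives with their
IC50 values against osteosarcoma cells; the four held-out compounds of
the 2D study are marked ``split=test``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_OFFSET = 6.0

_FIXTURE = "nitrogen_mustard_ic50.csv"


def pic50_transform(ic50_uM: float | np.ndarray, offset: float = DEFAULT_OFFSET):
    """Transform IC50 in µM to the modelling scale ``offset − log10(IC50)``.

    Strictly decreasing in IC50: more potent compounds (lower IC50) get
    higher activity.  Raises ``ValueError`` on non-positive input.
    """
    arr = np.asarray(ic50_uM, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"IC50 must be positive and finite, got {ic50_uM!r}")
    out = offset - np.log10(arr)
    return float(out) if np.isscalar(ic50_uM) or arr.ndim == 0 else out


def inverse_pic50(activity: float | np.ndarray, offset: float = DEFAULT_OFFSET):
    """Invert :func:`pic50_transform`: activity → IC50 in µM (always > 0)."""
    arr = np.asarray(activity, dtype=float)
    out = np.power(10.0, offset - arr)
    return float(out) if np.isscalar(activity) or arr.ndim == 0 else out


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: id, optional structure, IC50 (µM), transformed activity."""

    compound_id: str
    ic50_uM: float
    activity: float
    split: str = "train"
    structure: Optional[str] = None  # SMILES or a 3D-molecule handle

    def __post_init__(self):
        if self.ic50_uM <= 0:
            raise ValueError(
                f"compound {self.compound_id!r}: IC50 must be > 0, got {self.ic50_uM}"
            )
        if not math.isfinite(self.activity):
            raise ValueError(f"compound {self.compound_id!r}: activity not finite")
        if self.split not in ("train", "test"):
            raise ValueError(
                f"compound {self.compound_id!r}: split must be train|test, got {self.split!r}"
            )


@dataclass(frozen=True)
class Dataset:
    """Ordered collection of compound records with disjoint train/test splits."""

    records: tuple[CompoundRecord, ...]

    def __post_init__(self):
        ids = [r.compound_id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate compound id(s): {sorted(dup)}")

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    @property
    def n_train(self) -> int:
        return sum(r.split == "train" for r in self.records)

    @property
    def n_test(self) -> int:
        return sum(r.split == "test" for r in self.records)

    def activities(self, split: str | None = None) -> np.ndarray:
        recs = self.records if split is None else [r for r in self.records if r.split == split]
        return np.array([r.activity for r in recs], dtype=float)

    def subset(self, split: str) -> "Dataset":
        return Dataset(tuple(r for r in self.records if r.split == split))

    def with_random_split(self, n_test: int, seed: int) -> "Dataset":
        """Redraw the train/test split with an explicit seed.

        Replaces the original study's system-time randomisation so runs
        are reproducible.
        """
        rng = np.random.default_rng(seed)
        test_idx = set(rng.choice(len(self.records), size=n_test, replace=False).tolist())
        recs = tuple(
            replace(r, split="test" if i in test_idx else "train")
            for i, r in enumerate(self.records)
        )
        return Dataset(recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "ic50_uM": [r.ic50_uM for r in self.records],
                "activity": [r.activity for r in self.records],
                "split": [r.split for r in self.records],
            }
        )


def read_compound_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    offset: float = DEFAULT_OFFSET,
) -> Dataset:
    """Read a compound-activity CSV into a :class:`Dataset`.

    Expected columns (renameable through ``schema``, a map from the
    canonical name to the column name in the file): ``id``, ``ic50_uM``,
    optional ``smiles`` and ``split``.  Row order is preserved; absent
    split column → all compounds are training compounds.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path)
    colmap = {schema.get(k, k): k for k in ("id", "ic50_uM", "smiles", "split")}
    df = df.rename(columns=colmap)
    for required in ("id", "ic50_uM"):
        if required not in df.columns:
            raise ValueError(f"missing required column {required!r} in {path}")
    if "split" in df.columns:
        df["split"] = df["split"].fillna("train")

    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        cid = str(row.id)
        try:
            ic50 = float(row.ic50_uM)
        except (TypeError, ValueError):
            raise ValueError(
                f"row {row_no} (id {cid!r}): IC50 {row.ic50_uM!r} is not numeric"
            ) from None
        if not math.isfinite(ic50) or ic50 <= 0:
            raise ValueError(f"row {row_no} (id {cid!r}): IC50 must be positive, got {ic50}")
        split = str(getattr(row, "split", "train") or "train")
        smiles = getattr(row, "smiles", None)
        if smiles is not None and (not isinstance(smiles, str) or not smiles):
            smiles = None
        records.append(
            CompoundRecord(
                compound_id=cid,
                ic50_uM=ic50,
                activity=pic50_transform(ic50, offset),
                split=split,
                structure=smiles,
            )
        )
    return Dataset(tuple(records))


def write_compound_table(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to the CSV dialect `read_compound_table` accepts."""
    df = pd.DataFrame(
        {
            "id": dataset.ids,
            "ic50_uM": [r.ic50_uM for r in dataset.records],
            "split": [r.split for r in dataset.records],
        }
    )
    smiles = [r.structure for r in dataset.records]
    if any(s is not None for s in smiles):
        df.insert(1, "smiles", smiles)
    df.to_csv(path, index=False)


def load_fixture(offset: float = DEFAULT_OFFSET) -> Dataset:
    """Load the bundled 22-compound nitrogen-mustard IC50 table."""
    with resources.as_file(resources.files("nmqsar.data") / _FIXTURE) as p:
        return read_compound_table(p, offset=offset)
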