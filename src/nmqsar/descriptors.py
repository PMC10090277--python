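"""Descriptor-matrix assembly: imported tables, graph descriptors, screening.

Quantum-chemical descriptors (minimum electrophilic reactivity index for a
carbon atom, minimum C–C exchange energy, minimum C–H total interaction,
total dipole moment) require a semi-empirical wavefunction and are
import-only: they enter through CSV tables computed elsewhere.  The small
graph-derivable subset (nitrogen count, average carbon valency) is computed
here from SMILES/SDF via RDKit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from nmqsar.chem_data import Dataset

DESCRIPTOR_CLASSES = (
    "constitutional",
    "topological",
    "geometrical",
    "electrostatic",
    "quantum-chemical",
    "imported",
)

DEFAULT_VARIANCE_FLOOR = 1e-8


@dataclass(frozen=True)
class DescriptorMatrix:
    """Compounds × named descriptors, with per-descriptor class tags."""

    compound_ids: tuple[str, ...]
    names: tuple[str, ...]
    values: np.ndarray  # shape (n_compounds, n_descriptors)
    classes: tuple[str, ...] = ()

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.compound_ids), len(self.names)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.compound_ids)} compounds × {len(self.names)} descriptors"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")
        classes = self.classes or tuple("imported" for _ in self.names)
        if len(classes) != len(self.names):
            raise ValueError("classes length must match names length")
        object.__setattr__(self, "classes", tuple(classes))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.compound_ids), columns=list(self.names))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def select(self, names: Sequence[str]) -> "DescriptorMatrix":
        idx = [self.names.index(n) for n in names]
        return DescriptorMatrix(
            self.compound_ids,
            tuple(names),
            self.values[:, idx],
            tuple(self.classes[i] for i in idx),
        )

    def rows(self, compound_ids: Sequence[str]) -> "DescriptorMatrix":
        idx = [self.compound_ids.index(c) for c in compound_ids]
        return DescriptorMatrix(
            tuple(compound_ids), self.names, self.values[idx, :], self.classes
        )


def compute_graph_descriptors(structure) -> dict[str, float | None]:
    """Graph-derivable descriptors from a molecule: NN and AVC.

    ``NN``: number of nitrogen atoms.  ``AVC``: average total valency
    (bond orders + implicit/explicit hydrogens) over carbon atoms;
    ``None`` when the molecule has no carbon (undefined, not zero).

    ``structure`` may be a SMILES string or an RDKit ``Mol``.
    """
    from rdkit import Chem

    if isinstance(structure, str):
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {structure!r}")
    else:
        mol = structure

    nn = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "N")
    carbon_valencies = [a.GetTotalValence() for a in mol.GetAtoms() if a.GetSymbol() == "C"]
    avc = float(np.mean(carbon_valencies)) if carbon_valencies else None
    return {"NN": float(nn), "AVC": avc}


def read_descriptor_csv(path: str | Path) -> pd.DataFrame:
    """Descriptor CSV: first column compound_id, remaining columns numeric."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df.apply(pd.to_numeric, errors="coerce")


def read_class_sidecar(path: str | Path) -> dict[str, str]:
    """Optional JSON sidecar mapping descriptor names → class tags."""
    with open(path) as fh:
        return {str(k): str(v) for k, v in json.load(fh).items()}


def assemble_matrix(
    dataset: Dataset,
    imported: Iterable[str | Path | pd.DataFrame] = (),
    computed: Mapping[str, Mapping[str, float | None]] | None = None,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    classes: Mapping[str, str] | None = None,
) -> tuple[DescriptorMatrix, list[str]]:
    """Merge imported tables and computed maps into a screened matrix.

    Screening: columns with any missing value are dropped, then columns
    with variance below ``variance_floor``.  Returns the matrix (rows in
    dataset order) and a drop log naming each removed column and why.
    Raises if a dataset compound is covered by no source.
    """
    frames = []
    for src in imported:
        frames.append(src if isinstance(src, pd.DataFrame) else read_descriptor_csv(src))
    if computed:
        frames.append(pd.DataFrame.from_dict(dict(computed), orient="index"))

    if not frames:
        raise ValueError("no descriptor sources given")
    merged = pd.concat(frames, axis=1)
    missing_compounds = [cid for cid in dataset.ids if cid not in merged.index]
    if missing_compounds:
        raise ValueError(f"compound(s) absent from all descriptor sources: {missing_compounds}")
    merged = merged.loc[dataset.ids]

    drop_log: list[str] = []
    keep = []
    for name in merged.columns:
        col = merged[name].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            drop_log.append(f"{name}: missing value(s)")
            continue
        if float(np.var(col)) < variance_floor:
            drop_log.append(f"{name}: variance below {variance_floor:g}")
            continue
        keep.append(name)

    class_map = dict(classes or {})
    matrix = DescriptorMatrix(
        compound_ids=tuple(dataset.ids),
        names=tuple(keep),
        values=merged[keep].to_numpy(dtype=float),
        classes=tuple(class_map.get(n, "imported") for n in keep),
    )
    return matrix, drop_log
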