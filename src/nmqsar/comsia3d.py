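"""3D-QSAR: rigid alignment, CoMSIA-style similarity-index fields, PLS.

Similarity-index fields follow the Klebe convention: at lattice point q the
field value for property type F is

    A_F(q) = − Σ_atoms  w_probe · w_atom,F · exp(−α · r_aq²)

with probe weight +1, attenuation factor α (default 0.3) and r_aq the
atom–point distance in Å.  Five property types are supported: steric (S),
electrostatic (E), hydrophobic (H), hydrogen-bond donor (D) and acceptor
(A).  The Gaussian distance dependence needs no cutoff and is smooth at the
molecular surface, which is the point of similarity indices over
Lennard-Jones/Coulomb potentials.

The stacked per-point field columns across molecules form the X block of a
PLS model (NIPALS, hand-rolled so the column pretreatment and metadata stay
explicit): columns with stdev below a floor are dropped, the rest centred,
and each field block scaled to unit total variance.  The number of
components is picked by maximising leave-one-out Q².
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

FIELD_TYPES = ("S", "E", "H", "D", "A")

_FIELD_ATTR = {
    "S": "steric",
    "E": "charge",
    "H": "hydrophobic",
    "D": "donor",
    "A": "acceptor",
}

DEFAULT_ALPHA = 0.3
DEFAULT_SPACING = 2.0
DEFAULT_MARGIN = 4.0
MIN_COLUMN_SIGMA = 1e-6


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------


@dataclass
class Molecule3D:
    """Rigid 3D molecule with per-atom field properties.

    ``coords`` in Å; ``charge`` in e; ``steric`` is the cubed van der Waals
    radius by convention; donor/acceptor are 0/1 flags stored as floats.
    Any property array may be None when unknown — asking for that field
    then raises.
    """

    molecule_id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3)
    charge: Optional[np.ndarray] = None
    steric: Optional[np.ndarray] = None
    hydrophobic: Optional[np.ndarray] = None
    donor: Optional[np.ndarray] = None
    acceptor: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, float))
        if self.coords.shape[0] < 1 or self.coords.shape[1] != 3:
            raise ValueError("molecule needs ≥ 1 atom with xyz coordinates")
        if np.any(~np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for name in _FIELD_ATTR.values():
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, float)
                if arr.shape != (self.n_atoms,):
                    raise ValueError(f"{name} must have one value per atom")
                setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def property_for(self, field_type: str) -> np.ndarray:
        if field_type not in FIELD_TYPES:
            raise ValueError(f"unknown field type {field_type!r}; expected one of {FIELD_TYPES}")
        arr = getattr(self, _FIELD_ATTR[field_type])
        if arr is None:
            raise ValueError(
                f"molecule {self.molecule_id!r} carries no per-atom property for field {field_type!r}"
            )
        return arr

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule3D":
        return Molecule3D(
            molecule_id=self.molecule_id,
            elements=self.elements,
            coords=self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float),
            charge=self.charge,
            steric=self.steric,
            hydrophobic=self.hydrophobic,
            donor=self.donor,
            acceptor=self.acceptor,
        )

    def to_json_dict(self) -> dict:
        d = {
            "molecule_id": self.molecule_id,
            "elements": list(self.elements),
            "coords": self.coords.tolist(),
        }
        for name in _FIELD_ATTR.values():
            arr = getattr(self, name)
            if arr is not None:
                d[name] = arr.tolist()
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "Molecule3D":
        kwargs = {k: np.asarray(d[k], float) for k in _FIELD_ATTR.values() if k in d}
        return cls(
            molecule_id=str(d["molecule_id"]),
            elements=tuple(d["elements"]),
            coords=np.asarray(d["coords"], float),
            **kwargs,
        )


def write_molecules_json(molecules: Sequence[Molecule3D], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_json_dict() for m in molecules], fh, indent=1)


def read_molecules_json(path: str | Path) -> list[Molecule3D]:
    with open(path) as fh:
        return [Molecule3D.from_json_dict(d) for d in json.load(fh)]


def read_molecules_sdf(path: str | Path) -> list[Molecule3D]:
    """Read a 3D SDF; derive per-atom CoMSIA properties with RDKit.

    Steric = (van der Waals radius)³; electrostatic = Gasteiger partial
    charge; hydrophobic = Crippen atomic logP contribution; donor = N/O
    bearing an H; acceptor = N/O.  Per-atom property tags
    ``COMSIA_W_<S|E|H|D|A>`` (one whitespace-separated value per atom)
    override the derived values.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem, Crippen, rdMolDescriptors

    ptable = Chem.GetPeriodicTable()
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False)):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        conf = mol.GetConformer()
        coords = np.array(
            [[conf.GetAtomPosition(a).x, conf.GetAtomPosition(a).y, conf.GetAtomPosition(a).z]
             for a in range(mol.GetNumAtoms())]
        )
        AllChem.ComputeGasteigerCharges(mol)
        charge = np.array([float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()])
        steric = np.array(
            [ptable.GetRvdw(a.GetAtomicNum()) ** 3 for a in mol.GetAtoms()]
        )
        crippen = rdMolDescriptors._CalcCrippenContribs(mol)
        hydrophobic = np.array([c[0] for c in crippen])
        donor = np.array(
            [
                1.0 if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs(includeNeighbors=True) > 0 else 0.0
                for a in mol.GetAtoms()
            ]
        )
        acceptor = np.array(
            [1.0 if a.GetSymbol() in ("N", "O") else 0.0 for a in mol.GetAtoms()]
        )
        props = {
            "charge": charge,
            "steric": steric,
            "hydrophobic": hydrophobic,
            "donor": donor,
            "acceptor": acceptor,
        }
        for ftype, attr in _FIELD_ATTR.items():
            tag = f"COMSIA_W_{ftype}"
            if mol.HasProp(tag):
                vals = np.array([float(v) for v in mol.GetProp(tag).split()])
                if len(vals) != mol.GetNumAtoms():
                    raise ValueError(f"{name}: {tag} must list one value per atom")
                props[attr] = vals
        out.append(
            Molecule3D(
                molecule_id=name,
                elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
                coords=coords,
                **props,
            )
        )
    if not out:
        raise ValueError(f"no molecules read from {path}")
    return out


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def kabsch_align(
    template: Molecule3D, target: Molecule3D, atom_pairs: Sequence[tuple[int, int]]
) -> tuple[Molecule3D, float, np.ndarray, np.ndarray]:
    """Rigidly superpose ``target`` onto ``template`` over paired atoms.

    Kabsch: SVD of the cross-covariance of the centred paired coordinates,
    with the determinant correction that guarantees a proper rotation.
    Returns (aligned copy, RMSD over the pairs, rotation, translation),
    where ``aligned.coords = target.coords @ R.T + t``.
    """
    pairs = list(atom_pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 atom pairs for rigid alignment")
    P = template.coords[[i for i, _ in pairs]]  # reference
    Q = target.coords[[j for _, j in pairs]]  # moving

    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    # collinearity check: centred points must span a plane
    if np.linalg.matrix_rank(Qc, tol=1e-9) < 2 or np.linalg.matrix_rank(Pc, tol=1e-9) < 2:
        raise ValueError("paired atoms are collinear; rotation is underdetermined")

    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - R @ Q.mean(axis=0)

    aligned = target.transformed(R, t)
    diff = aligned.coords[[j for _, j in pairs]] - P
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return aligned, rmsd, R, t


# ---------------------------------------------------------------------------
# grid and fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned lattice: origin + integer multiples of the spacing."""

    origin: tuple[float, float, float]
    spacing: float
    counts: tuple[int, int, int]
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.alpha <= 0:
            raise ValueError("attenuation factor must be positive")
        if any(c < 1 for c in self.counts):
            raise ValueError("grid counts must be ≥ 1")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.counts))

    def points(self) -> np.ndarray:
        """Lattice points, x fastest-varying last (C order over (i,j,k))."""
        axes = [
            np.asarray(self.origin[d]) + self.spacing * np.arange(self.counts[d])
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def build_grid(
    molecules: Sequence[Molecule3D],
    spacing: float = DEFAULT_SPACING,
    margin: float = DEFAULT_MARGIN,
    alpha: float = DEFAULT_ALPHA,
) -> GridSpec:
    """Lattice covering the joint bounding box expanded by ``margin`` per side."""
    if not molecules:
        raise ValueError("empty molecule set")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    all_coords = np.vstack([m.coords for m in molecules])
    lo = all_coords.min(axis=0) - margin
    hi = all_coords.max(axis=0) + margin
    counts = tuple(int(math.ceil((hi[d] - lo[d]) / spacing - 1e-9)) + 1 for d in range(3))
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=float(spacing), counts=counts, alpha=float(alpha))


def field_values(
    molecule: Molecule3D, points: np.ndarray, field_type: str, alpha: float = DEFAULT_ALPHA
) -> np.ndarray:
    """Similarity-index values at arbitrary probe points (see module docs)."""
    w = molecule.property_for(field_type)
    points = np.atleast_2d(np.asarray(points, float))
    d2 = np.sum((points[:, None, :] - molecule.coords[None, :, :]) ** 2, axis=2)
    return -np.exp(-alpha * d2) @ w


def comsia_field(molecule: Molecule3D, grid: GridSpec, field_type: str) -> np.ndarray:
    """Field block on the lattice, shaped ``grid.counts``."""
    vals = field_values(molecule, grid.points(), field_type, grid.alpha)
    return vals.reshape(grid.counts)


def stack_fields(
    molecules: Sequence[Molecule3D],
    grid: GridSpec,
    fields: Sequence[str] = FIELD_TYPES,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-point field columns for all molecules.

    Returns (X, field_labels): X is (n_molecules, n_points·n_fields); the
    labels name the field of each column, in field-major order.
    """
    pts = grid.points()
    blocks, labels = [], []
    for f in fields:
        block = np.vstack([field_values(m, pts, f, grid.alpha) for m in molecules])
        blocks.append(block)
        labels.extend([f] * pts.shape[0])
    return np.hstack(blocks), np.asarray(labels)


def export_field_csv(grid: GridSpec, molecule: Molecule3D, path: str | Path,
                     fields: Sequence[str] = FIELD_TYPES) -> None:
    """Flat CSV export: x,y,z,field,value."""
    import pandas as pd

    pts = grid.points()
    rows = []
    for f in fields:
        vals = field_values(molecule, pts, f, grid.alpha)
        for (x, y, z), v in zip(pts, vals):
            rows.append((x, y, z, f, v))
    pd.DataFrame(rows, columns=["x", "y", "z", "field", "value"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """NIPALS PLS1 fit with pretreatment metadata and quality statistics."""

    n_components: int
    kept_columns: np.ndarray  # indices into the raw X
    column_means: np.ndarray
    column_scales: np.ndarray  # per-column divisor (block scaling)
    coefficients: np.ndarray  # on the pretreated scale
    y_mean: float
    field_labels: Optional[np.ndarray] = None  # per kept column
    r2: float = np.nan
    q2: float = np.nan
    see: float = np.nan
    f_stat: float = np.nan
    field_fractions: Optional[dict[str, float]] = None
    column_stdevs: Optional[np.ndarray] = None  # of the pretreated columns

    def pretreat(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return (X[:, self.kept_columns] - self.column_means) / self.column_scales

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.y_mean + self.pretreat(X) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "q2": None if np.isnan(self.q2) else self.q2,
            "r2": self.r2,
            "see": self.see,
            "f_stat": self.f_stat,
            "field_fractions": self.field_fractions,
        }


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """NIPALS for a single response; X, y already centred. Returns coefs."""
    n, m = X.shape
    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    q = np.zeros(n_components)
    Xd, yd = X.copy(), y.copy()
    for c in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # residual X carries no covariance with y; stop early
            W, P, q = W[:, :c], P[:, :c], q[:c]
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, P, q = W[:, :c], P[:, :c], q[:c]
            break
        p = Xd.T @ t / tt
        qc = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - qc * t
        W[:, c], P[:, c], q[c] = w, p, qc
    if W.shape[1] == 0:
        return np.zeros(m)
    return W @ np.linalg.solve(P.T @ W, q)


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    field_labels: Sequence[str] | None = None,
    pretreat: bool = True,
) -> PLSModel:
    """Fit PLS1 with CoMFA-standard-style pretreatment.

    Pretreatment: drop columns with stdev < 1e-6, centre the rest, and
    scale each field block to unit total variance (identity scaling when
    no field labels are given).  Reports r², SEE = sqrt(RSS/(n−c−1)) and
    F = [r²/c]/[(1−r²)/(n−c−1)] with c = ``n_components``.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, m_all = X.shape
    labels_all = np.asarray(field_labels) if field_labels is not None else None

    sd = X.std(axis=0)
    kept = np.flatnonzero(sd >= MIN_COLUMN_SIGMA) if pretreat else np.arange(m_all)
    if kept.size == 0:
        raise ValueError("no informative columns (all below the sigma floor)")
    Xk = X[:, kept]
    means = Xk.mean(axis=0)  # NIPALS assumes centred blocks
    Xc = Xk - means

    labels = labels_all[kept] if labels_all is not None else None
    scales = np.ones(kept.size)
    if pretreat and labels is not None:
        for f in np.unique(labels):
            mask = labels == f
            total_var = float(np.sum(Xc[:, mask] ** 2)) / max(n - 1, 1)
            if total_var > 0:
                scales[mask] = math.sqrt(total_var)
    Xs = Xc / scales

    max_c = min(n - 1, kept.size)
    if not 1 <= n_components <= max_c:
        raise ValueError(f"n_components must be in [1, {max_c}], got {n_components}")

    ymean = float(y.mean())
    coefs = _nipals_pls1(Xs, y - ymean, n_components)

    yhat = ymean + Xs @ coefs
    rss = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - ymean) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    dof = n - n_components - 1
    see = math.sqrt(rss / dof) if dof > 0 else math.nan
    f_stat = (r2 / n_components) / ((1.0 - r2) / dof) if dof > 0 and r2 < 1.0 else math.inf

    return PLSModel(
        n_components=n_components,
        kept_columns=kept,
        column_means=means,
        column_scales=scales,
        coefficients=coefs,
        y_mean=ymean,
        field_labels=labels,
        r2=r2,
        see=see,
        f_stat=f_stat,
        column_stdevs=Xs.std(axis=0),
    )


def pls_loo_onc(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    field_labels: Sequence[str] | None = None,
) -> PLSModel:
    """Pick the number of components by leave-one-out Q², then refit.

    Q²(c) = 1 − PRESS(c)/Σ(y−ȳ)² from exact LOO refits (pretreatment
    recomputed inside every fold).  ONC maximises Q², smallest on ties.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 rows for component selection")
    cmax = min(max_components, n - 2)

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2s = []
    for c in range(1, cmax + 1):
        press = 0.0
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            m = pls_fit(X[mask], y[mask], c, field_labels=field_labels)
            press += float((y[i] - m.predict(X[i : i + 1])[0]) ** 2)
        q2s.append(1.0 - press / ss_tot)

    onc = int(np.argmax(q2s)) + 1  # argmax returns the first (smallest) max
    model = pls_fit(X, y, onc, field_labels=field_labels)
    model.q2 = q2s[onc - 1]
    return model


# ---------------------------------------------------------------------------
# contours and field contributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContourSet:
    """Per-field favorable/unfavorable levels and lattice masks."""

    levels: dict[str, tuple[float, float]]  # field → (favorable, unfavorable)
    favorable_masks: dict[str, np.ndarray]
    unfavorable_masks: dict[str, np.ndarray]


def contour_and_contrib(
    model: PLSModel,
    grid: GridSpec | None = None,
    fav_pct: float = 80.0,
    unfav_pct: float = 20.0,
) -> tuple[ContourSet, dict[str, float]]:
    """StDev·Coeff contour analysis and per-field contribution fractions.

    Per-column score = coefficient × column stdev (both on the pretreated
    scale).  ``field_fractions[f] = Σ_f |score| / Σ_all |score|``.  Contour
    levels: favorable at the ``fav_pct`` percentile of the field's scores,
    unfavorable at ``unfav_pct``; masks flag the columns beyond each level.
    """
    if model.field_labels is None or model.column_stdevs is None:
        raise ValueError("model carries no field labels / column metadata")
    scores = model.coefficients * model.column_stdevs
    labels = model.field_labels

    totals = {f: float(np.sum(np.abs(scores[labels == f]))) for f in FIELD_TYPES}
    grand = sum(totals.values())
    if grand == 0:
        fractions = {f: 0.0 for f in FIELD_TYPES}
    else:
        fractions = {f: totals[f] / grand for f in FIELD_TYPES}
    model.field_fractions = fractions

    levels, fav_masks, unfav_masks = {}, {}, {}
    for f in FIELD_TYPES:
        s = scores[labels == f]
        if s.size == 0 or np.all(s == 0):
            levels[f] = (0.0, 0.0)
            fav_masks[f] = np.zeros(s.shape, bool)
            unfav_masks[f] = np.zeros(s.shape, bool)
            continue
        fav_level = float(np.percentile(s, fav_pct))
        unfav_level = float(np.percentile(s, unfav_pct))
        levels[f] = (fav_level, unfav_level)
        fav_masks[f] = s >= fav_level
        unfav_masks[f] = s <= unfav_level
    return ContourSet(levels, fav_masks, unfav_masks), fractions
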