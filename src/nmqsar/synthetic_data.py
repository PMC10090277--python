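"""Seeded generators emulating the statistical structure of each QSAR stage.

The real study's inputs (quantum-chemical descriptor values, field grids,
3D conformers) are not published, so every model in the package is
exercised by parameter recovery on synthetic data instead: a descriptor
table with a planted sparse linear signal for the stepwise-MLR stage,
symbolic-regression targets built only from the {+,−,*,/,Ln,sin} operator
set for the GEP stage, and pre-aligned pseudo-atom molecule sets with a
planted single-field activity effect for the CoMSIA stage.  Each generator
is a pure function of its spec (seed included) and returns the planted
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from nmqsar.comsia3d import FIELD_TYPES, Molecule3D
from nmqsar.descriptors import DescriptorMatrix

SYMBOLIC_CATALOG: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "f1": lambda X: np.sin(X[:, 0]) + X[:, 1],
    "f2": lambda X: X[:, 0] * X[:, 1] + np.sin(X[:, 2]),
    "f3": lambda X: X[:, 0] / X[:, 1] + np.log(X[:, 2]),
}

# per-target sampling domains keep divisors and Ln arguments away from 0
_SYMBOLIC_DOMAIN = {
    "f1": lambda rng, n, p: rng.uniform(-2.0, 2.0, size=(n, p)),
    "f2": lambda rng, n, p: rng.uniform(-2.0, 2.0, size=(n, p)),
    "f3": lambda rng, n, p: rng.uniform(0.5, 3.0, size=(n, p)),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset; same spec ⇒ identical output."""

    seed: int = 0
    n: int = 60
    p: int = 30
    planted_subset: tuple[int, ...] = (0, 3, 7)
    beta: tuple[float, ...] = (3.0, -2.0, 1.5)
    noise_sd: float = 0.1  # as a fraction of the noise-free signal sd
    expression_id: str = "f1"
    field_effect: tuple[int, str, float] = (0, "E", 2.0)  # (site, field, effect size)
    correlated_block: int = 0  # optional count of mutually correlated columns

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if len(self.planted_subset) != len(self.beta):
            raise ValueError("planted_subset and beta must have equal length")


def gen_descriptor_table(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, np.ndarray, dict]:
    """Standard-normal descriptor table with a planted sparse linear signal.

    ``y = Σ beta_k · x_{planted_k} + ε`` with ε ~ N(0, (noise_sd·sd(signal))²).
    An optional block of the first ``correlated_block`` non-planted columns
    shares a common latent factor (pairwise r ≈ 0.7) so collinearity
    handling can be exercised.  Returns (matrix, activities, truth dict).
    """
    if any(j >= spec.p for j in spec.planted_subset):
        raise ValueError("planted descriptor index out of range")
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p))

    if spec.correlated_block > 1:
        free = [j for j in range(spec.p) if j not in spec.planted_subset]
        block = free[: spec.correlated_block]
        z = rng.standard_normal(spec.n)
        for j in block:
            X[:, j] = 0.84 * z + 0.55 * rng.standard_normal(spec.n)

    signal = X[:, list(spec.planted_subset)] @ np.asarray(spec.beta)
    sd_sig = float(signal.std())
    noise = rng.standard_normal(spec.n) * spec.noise_sd * (sd_sig if sd_sig > 0 else 1.0)
    y = signal + noise

    names = tuple(f"D{j:03d}" for j in range(spec.p))
    matrix = DescriptorMatrix(
        compound_ids=tuple(f"C{i + 1}" for i in range(spec.n)),
        names=names,
        values=X,
        classes=tuple("imported" for _ in names),
    )
    truth = {
        "planted_names": [names[j] for j in spec.planted_subset],
        "planted_subset": list(spec.planted_subset),
        "beta": list(spec.beta),
        "noise_sd_abs": spec.noise_sd * sd_sig,
    }
    return matrix, y, truth


def gen_symbolic_dataset(
    spec: SyntheticSpec, p: int | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Sample a symbolic-regression target from the catalog.

    Targets use only the GEP operator alphabet {+,−,*,/,Ln,sin}; sampling
    domains exclude singularities (f3 keeps all columns in [0.5, 3] so
    divisors and Ln arguments stay positive).  Returns (X, y, truth).
    """
    if spec.expression_id not in SYMBOLIC_CATALOG:
        raise ValueError(
            f"unknown expression_id {spec.expression_id!r}; "
            f"catalog: {sorted(SYMBOLIC_CATALOG)}"
        )
    p = p if p is not None else max(3, min(spec.p, 6))
    rng = np.random.default_rng(spec.seed)
    X = _SYMBOLIC_DOMAIN[spec.expression_id](rng, spec.n, p)
    f = SYMBOLIC_CATALOG[spec.expression_id]
    signal = f(X)
    sd_sig = float(signal.std())
    y = signal + rng.standard_normal(spec.n) * spec.noise_sd * (sd_sig if sd_sig > 0 else 1.0)
    return X, y, {"expression_id": spec.expression_id, "noise_sd_abs": spec.noise_sd * sd_sig}


# rigid 8-atom scaffold shared by every generated molecule (Å)
_SCAFFOLD = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.5, 0.0, 0.0],
        [3.0, 0.0, 0.0],
        [3.8, 1.3, 0.0],
        [3.0, 2.6, 0.0],
        [1.5, 2.6, 0.0],
        [0.7, 1.3, 0.0],
        [1.5, 1.3, 1.4],
    ]
)
_SITE_COORDS = np.array([[5.3, 1.3, 0.0], [3.8, 3.9, 0.0]])  # substituent sites


def gen_aligned_molecules(
    spec: SyntheticSpec,
) -> tuple[list[Molecule3D], np.ndarray, dict]:
    """Pre-aligned pseudo-atom series with a planted single-field effect.

    All molecules share the rigid scaffold (identical coordinates — the
    series is already superposed, as after template alignment).  One
    substituent site's per-field properties vary across molecules; the
    activity is ``effect_size × property(site, field) + ε``.  Scaffold
    properties are fixed; non-effect properties at the sites vary randomly
    so all five fields have variance but only one carries signal.
    """
    if spec.n < 6:
        raise ValueError("need at least 6 molecules")
    site_idx, eff_field, eff_size = spec.field_effect
    if eff_field not in FIELD_TYPES:
        raise ValueError(f"effect field {eff_field!r} not one of {FIELD_TYPES}")
    if site_idx >= len(_SITE_COORDS):
        raise ValueError(f"site index {site_idx} out of range")

    rng = np.random.default_rng(spec.seed)
    coords = np.vstack([_SCAFFOLD, _SITE_COORDS])
    n_atoms = coords.shape[0]
    n_scaffold = _SCAFFOLD.shape[0]
    eff_atom = n_scaffold + site_idx

    base = {
        "charge": rng.uniform(-0.3, 0.3, n_atoms),
        "steric": rng.uniform(1.0, 8.0, n_atoms),
        "hydrophobic": rng.uniform(-0.5, 0.5, n_atoms),
        "donor": (rng.random(n_atoms) < 0.3).astype(float),
        "acceptor": (rng.random(n_atoms) < 0.3).astype(float),
    }
    attr_of = {"S": "steric", "E": "charge", "H": "hydrophobic", "D": "donor", "A": "acceptor"}
    ranges = {
        "charge": (-0.5, 0.5),
        "steric": (1.0, 8.0),
        "hydrophobic": (-1.0, 1.0),
        "donor": (0.0, 1.0),
        "acceptor": (0.0, 1.0),
    }

    molecules, effect_props = [], np.empty(spec.n)
    for i in range(spec.n):
        props = {k: v.copy() for k, v in base.items()}
        # all site properties vary molecule to molecule
        for attr, (lo, hi) in ranges.items():
            for s in range(len(_SITE_COORDS)):
                props[attr][n_scaffold + s] = rng.uniform(lo, hi)
        effect_props[i] = props[attr_of[eff_field]][eff_atom]
        molecules.append(
            Molecule3D(
                molecule_id=f"M{i + 1}",
                elements=tuple("X" * n_atoms),
                coords=coords.copy(),
                **props,
            )
        )

    signal = eff_size * effect_props
    sd_sig = float(signal.std())
    y = signal + rng.standard_normal(spec.n) * spec.noise_sd * (sd_sig if sd_sig > 0 else 1.0)
    truth = {
        "effect_atom": int(eff_atom),
        "effect_field": eff_field,
        "effect_size": eff_size,
        "site_property": effect_props.tolist(),
        "noise_sd_abs": spec.noise_sd * sd_sig,
    }
    return molecules, y, truth
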