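"""Atom-based 3D QSAR: class-typed occupancy grids + PLS regression.

Aligned conformers are described as overlapping van der Waals spheres.
Each heavy atom is assigned one of six classes — D (hydrogen-bond donor),
N (negative ionic), P (positive ionic), W (electron-withdrawing /
acceptor), H (hydrophobic carbon), X (miscellaneous) — with first-match
priority D, N, P, W, H, X so multi-rule atoms classify deterministically.
A cubic grid (default spacing 1.0 Å) covers the aligned set; the bit for
(cube, class) is set iff the cube *center* lies within the van der Waals
radius of at least one atom of that class.  The binary matrix feeds a
partial-least-squares (NIPALS) regression on pIC50 with at most four
factors; per-cube regression coefficients are exportable as volumetric
field maps (Gaussian cube format) showing favorable/unfavorable regions.

The "stability" statistic is a resampling surrogate (mean Pearson
correlation between full-model predictions and predictions of models
refit on random 80% subsets); it is labelled as such in all reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from scipy import stats as sps

logger = logging.getLogger(__name__)

ATOM_CLASSES = ("D", "N", "P", "W", "H", "X")

#: first-match atom-typing rules, applied in ATOM_CLASSES order.  The
#: negative/positive rules also catch groups drawn neutral but ionized at
#: physiological pH (carboxylic acids); no pKa engine is involved.
DEFAULT_ATOM_RULES: tuple[tuple[str, str], ...] = (
    ("D", "[$([N;!H0;!+]),$([O;H1;!$([OH]C=O)]),$([n;H1])]"),
    ("N", "[$([O-]),$([S-]),$([OH]C=O),$([OX1]=C[OH])]"),
    ("P", "[$([N+]),$([n+])]"),
    ("W", "[#7,#8]"),
    ("H", "[#6;!$([#6]~[!#6;!#1])]"),
)

#: Bondi van der Waals radii (Å) for the elements expected in drug-like sets.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98, "B": 1.92, "Si": 2.10,
}
_DEFAULT_VDW = 1.70
_BOHR_PER_ANGSTROM = 1.8897259886


def assign_atom_classes(mol: Chem.Mol, rules: Sequence[tuple[str, str]] = DEFAULT_ATOM_RULES) -> list[str]:
    """One class label per heavy atom, first-match priority D,N,P,W,H,X."""
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    labels = {idx: "X" for idx in heavy}
    claimed: set[int] = set()
    for cls, smarts in rules:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid atom-class SMARTS for {cls!r}: {smarts!r}")
        for match in mol.GetSubstructMatches(patt):
            idx = match[0]
            if idx in labels and idx not in claimed:
                labels[idx] = cls
                claimed.add(idx)
    return [labels[idx] for idx in heavy]


@dataclass(frozen=True)
class GridSpec:
    """Cubic grid; cube (i,j,k) has its center at origin + (i,j,k)*spacing."""

    origin: tuple[float, float, float]
    dims: tuple[int, int, int]
    spacing: float = 1.0

    @property
    def n_cubes(self) -> int:
        return self.dims[0] * self.dims[1] * self.dims[2]


def _heavy_coords(mol: Chem.Mol, conf_id: int = -1) -> tuple[np.ndarray, list[int]]:
    conf = mol.GetConformer(conf_id)
    idxs = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z] for i in idxs])
    return coords, idxs


def auto_grid(mols: Sequence[Chem.Mol], spacing: float = 1.0) -> GridSpec:
    """Smallest grid covering every atom plus the largest vdW radius."""
    mins = np.full(3, np.inf)
    maxs = np.full(3, -np.inf)
    for mol in mols:
        coords, _ = _heavy_coords(mol)
        mins = np.minimum(mins, coords.min(axis=0))
        maxs = np.maximum(maxs, coords.max(axis=0))
    margin = max(VDW_RADII.values()) + spacing
    origin = np.floor((mins - margin) / spacing) * spacing
    dims = np.ceil((maxs + margin - origin) / spacing).astype(int) + 1
    return GridSpec(origin=tuple(float(x) for x in origin), dims=tuple(int(d) for d in dims), spacing=spacing)


def encode_occupancy(
    mols: Sequence[Chem.Mol],
    grid: GridSpec | None = None,
    rules: Sequence[tuple[str, str]] = DEFAULT_ATOM_RULES,
) -> tuple[np.ndarray, GridSpec]:
    """Binary occupancy matrix, one row per aligned conformer.

    Column layout: ``cube_index * 6 + class_index`` with cubes flattened in
    (x, y, z) C order and classes in ATOM_CLASSES order.  A bit is set iff
    the cube center lies within the vdW sphere of >= 1 atom of that class.
    With an explicit grid, an atom whose sphere extends outside it raises
    an error naming the atom.
    """
    if len(mols) == 0:
        raise ValueError("empty molecule list")
    explicit = grid is not None
    if grid is None:
        grid = auto_grid(mols)
    nx, ny, nz = grid.dims
    origin = np.asarray(grid.origin)
    X = np.zeros((len(mols), grid.n_cubes * len(ATOM_CLASSES)), dtype=np.uint8)
    for m, mol in enumerate(mols):
        classes = assign_atom_classes(mol, rules)
        coords, idxs = _heavy_coords(mol)
        for (x, y, z), atom_idx, cls in zip(coords, idxs, classes):
            sym = mol.GetAtomWithIdx(atom_idx).GetSymbol()
            r = VDW_RADII.get(sym, _DEFAULT_VDW)
            lo = np.ceil((np.array([x, y, z]) - r - origin) / grid.spacing).astype(int)
            hi = np.floor((np.array([x, y, z]) + r - origin) / grid.spacing).astype(int)
            if explicit and ((lo < 0).any() or (hi >= np.array(grid.dims)).any()):
                raise ValueError(
                    f"molecule {m}, atom {atom_idx} ({sym}) at ({x:.2f}, {y:.2f}, {z:.2f}) "
                    f"extends outside the grid"
                )
            lo = np.maximum(lo, 0)
            hi = np.minimum(hi, np.array(grid.dims) - 1)
            ci = ATOM_CLASSES.index(cls)
            r2 = r * r
            for i in range(lo[0], hi[0] + 1):
                dx2 = (origin[0] + i * grid.spacing - x) ** 2
                for j in range(lo[1], hi[1] + 1):
                    dy2 = (origin[1] + j * grid.spacing - y) ** 2
                    if dx2 + dy2 > r2:
                        continue
                    for k in range(lo[2], hi[2] + 1):
                        dz2 = (origin[2] + k * grid.spacing - z) ** 2
                        if dx2 + dy2 + dz2 <= r2:
                            cube = (i * ny + j) * nz + k
                            X[m, cube * len(ATOM_CLASSES) + ci] = 1
    return X, grid


def drop_constant_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove dataset-constant columns; returns (reduced X, kept indices)."""
    keep = np.flatnonzero(X.min(axis=0) != X.max(axis=0))
    return X[:, keep], keep


@dataclass
class FactorStats:
    n_factors: int
    r2: float
    sd: float
    f: float
    p: float
    stability: float | None = None


@dataclass
class GridQSARModel:
    """Occupancy-grid PLS model: affine in the occupancy bits."""

    coefficients: np.ndarray  # per retained column
    intercept: float
    x_mean: np.ndarray
    n_factors: int
    factor_stats: list[FactorStats]
    grid: GridSpec | None = None  # None for abstract (non-molecular) grids
    kept_columns: np.ndarray | None = None  # None when no columns were dropped
    n_input_columns: int | None = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if self.kept_columns is not None and X_new.shape[1] == self.n_input_columns:
            X_new = X_new[:, self.kept_columns]
        if X_new.shape[1] != self.coefficients.size:
            raise ValueError(
                f"X has {X_new.shape[1]} columns, model expects {self.coefficients.size}"
                + (f" (or {self.n_input_columns} before constant-column drop)" if self.kept_columns is not None else "")
            )
        return X_new @ self.coefficients + self.intercept


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_factors: int) -> list[np.ndarray]:
    """NIPALS PLS1: returns the coefficient vector after each factor."""
    X = Xc.copy()
    y = yc.copy()
    W, P, Q = [], [], []
    coefs = []
    for _ in range(n_factors):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = (X.T @ t) / tt
        q = float(y @ t) / tt
        X = X - np.outer(t, p)
        y = y - t * q
        W.append(w)
        P.append(p)
        Q.append(q)
        Wm = np.column_stack(W)
        Pm = np.column_stack(P)
        # B = W (P^T W)^{-1} q
        coefs.append(Wm @ np.linalg.solve(Pm.T @ Wm, np.array(Q)))
    return coefs


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int = 4,
    grid: GridSpec | None = None,
    drop_constant: bool = True,
    stability_subsets: int = 10,
    stability_seed: int = 0,
) -> GridQSARModel:
    """Fit the occupancy-grid PLS model and its per-factor statistics.

    For each factor count k <= ``n_factors`` the model reports training
    r², SD = sqrt(SS_res / (n - k - 1)), F = (r²/k) / ((1-r²)/(n-k-1)),
    its p-value from the F(k, n-k-1) distribution, and the resampling
    stability surrogate.  Requesting more factors than the data support
    truncates with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X rows must match y length")
    if n < n_factors + 2:
        raise ValueError(f"need at least n_factors + 2 = {n_factors + 2} samples, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("constant y: nothing to regress")

    n_input = X.shape[1]
    kept = None
    if drop_constant:
        Xr, kept_idx = drop_constant_columns(X)
        if kept_idx.size < n_input:
            kept = kept_idx
            X = Xr

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    coefs = _nipals_pls1(Xc, yc, n_factors)
    if len(coefs) < n_factors:
        logger.warning("PLS truncated at %d factors (requested %d): X rank exhausted", len(coefs), n_factors)
    if not coefs:
        raise ValueError("PLS could not extract any factor")

    tss = float(yc @ yc)
    factor_stats = []
    rng = np.random.default_rng(stability_seed)
    for k, b in enumerate(coefs, start=1):
        fitted = Xc @ b + y_mean
        ss_res = float(np.sum((y - fitted) ** 2))
        r2 = 1.0 - ss_res / tss
        dof = n - k - 1
        sd = math.sqrt(ss_res / dof) if dof > 0 else float("nan")
        if r2 < 1.0 and dof > 0:
            f_val = (r2 / k) / ((1.0 - r2) / dof)
            p_val = float(sps.f.sf(f_val, k, dof))
        else:
            f_val, p_val = float("inf"), 0.0
        stability = None
        if stability_subsets > 0:
            full_pred = fitted
            cors = []
            for _ in range(stability_subsets):
                sub = rng.choice(n, size=max(int(round(0.8 * n)), k + 2), replace=False)
                sub_coefs = _nipals_pls1(
                    X[sub] - X[sub].mean(axis=0), y[sub] - y[sub].mean(), k
                )
                if not sub_coefs:
                    continue
                pred = (X - X[sub].mean(axis=0)) @ sub_coefs[-1] + y[sub].mean()
                if np.std(pred) > 0 and np.std(full_pred) > 0:
                    cors.append(np.corrcoef(full_pred, pred)[0, 1])
            stability = float(np.mean(cors)) if cors else None
        factor_stats.append(FactorStats(n_factors=k, r2=r2, sd=sd, f=f_val, p=p_val, stability=stability))

    b_final = coefs[-1]
    return GridQSARModel(
        coefficients=b_final,
        intercept=y_mean - float(x_mean @ b_final),
        x_mean=x_mean,
        n_factors=len(coefs),
        factor_stats=factor_stats,
        grid=grid,
        kept_columns=kept,
        n_input_columns=n_input if kept is not None else None,
    )


def predict(model: GridQSARModel, X_new: np.ndarray) -> np.ndarray:
    return model.predict(X_new)


def _full_coefficient_field(model: GridQSARModel) -> np.ndarray:
    """Coefficient per original (cube, class) column, zeros where dropped."""
    if model.kept_columns is None:
        return model.coefficients
    full = np.zeros(model.n_input_columns)
    full[model.kept_columns] = model.coefficients
    return full


def export_field_maps(model: GridQSARModel, atom_class: str, path: str | Path, sign: str | None = None) -> None:
    """Write the per-cube coefficients of one atom class as a Gaussian cube.

    ``sign='positive'``/``'negative'`` masks the other sign to zero
    (favorable vs unfavorable regions).  Values are written with full
    float64 precision so a re-read reproduces them bit-exactly.
    """
    if model.grid is None:
        raise ValueError("model has no molecular grid; field maps are undefined")
    if atom_class not in ATOM_CLASSES:
        raise ValueError(f"unknown atom class {atom_class!r}; expected one of {ATOM_CLASSES}")
    if sign not in (None, "positive", "negative"):
        raise ValueError("sign must be None, 'positive' or 'negative'")
    full = _full_coefficient_field(model)
    ci = ATOM_CLASSES.index(atom_class)
    values = full[ci :: len(ATOM_CLASSES)].reshape(model.grid.dims)
    if sign == "positive":
        values = np.where(values > 0, values, 0.0)
    elif sign == "negative":
        values = np.where(values < 0, values, 0.0)

    nx, ny, nz = model.grid.dims
    ox, oy, oz = (c * _BOHR_PER_ANGSTROM for c in model.grid.origin)
    step = model.grid.spacing * _BOHR_PER_ANGSTROM
    with open(path, "w") as fh:
        fh.write(f"occupancy-grid PLS coefficient field, class {atom_class}\n")
        fh.write(f"sign={sign or 'both'} spacing={model.grid.spacing} A\n")
        fh.write(f"{0:5d} {ox:.10f} {oy:.10f} {oz:.10f}\n")
        fh.write(f"{nx:5d} {step:.10f} {0.0:.10f} {0.0:.10f}\n")
        fh.write(f"{ny:5d} {0.0:.10f} {step:.10f} {0.0:.10f}\n")
        fh.write(f"{nz:5d} {0.0:.10f} {0.0:.10f} {step:.10f}\n")
        flat = values.ravel(order="C")
        for start in range(0, flat.size, 6):
            fh.write(" ".join(f"{v:.17E}" for v in flat[start : start + 6]) + "\n")


def read_field_map(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a cube file written by :func:`export_field_maps`."""
    with open(path) as fh:
        fh.readline()
        fh.readline()
        natoms_line = fh.readline().split()
        origin = tuple(float(x) / _BOHR_PER_ANGSTROM for x in natoms_line[1:4])
        dims = []
        spacing = None
        for axis in range(3):
            parts = fh.readline().split()
            dims.append(int(parts[0]))
            step = float(parts[1 + axis]) / _BOHR_PER_ANGSTROM
            if spacing is None:
                spacing = step
        values = np.array([float(tok) for line in fh for tok in line.split()])
    grid = GridSpec(origin=origin, dims=tuple(dims), spacing=float(spacing))
    return values.reshape(grid.dims), grid


def factor_stats_frame(model: GridQSARModel):
    """Per-factor statistics table (columns laid out factor-wise)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "n_factors": [s.n_factors for s in model.factor_stats],
            "r2": [s.r2 for s in model.factor_stats],
            "sd": [s.sd for s in model.factor_stats],
            "f_value": [s.f for s in model.factor_stats],
            "p_value": [s.p for s in model.factor_stats],
            "stability_surrogate": [s.stability for s in model.factor_stats],
        }
    )
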