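"""Pharmacophore feature perception, hypothesis matching, rigid alignment.

A pharmacophore hypothesis is a small set of typed feature points —
hydrogen-bond acceptor (A), donor (D), hydrophobic (H), negative (N) or
positive (P) ionic, aromatic ring (R) — with fixed inter-feature
distances.  Matching a conformer to a hypothesis enumerates type-
compatible assignments of perceived features to hypothesis slots, prunes
them by pairwise-distance compatibility, and scores the survivors by the
RMSD of a least-squares rigid (Kabsch) superposition; mirror-image
matches are rejected (proper rotations only).

Feature perception uses editable substructure rules; the defaults are
deliberately simple and documented next to :data:`DEFAULT_FEATURE_RULES`.
Ring features sit at the aromatic-ring centroid.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("A", "D", "H", "N", "P", "R")

#: default perception rules (SMARTS per feature type, ring type handled
#: separately from ring info):
#:   A — N/O with an available lone pair, not positively charged
#:   D — N-H or O-H
#:   H — carbons with only carbon/hydrogen neighbours (aliphatic)
#:   N/P — groups carrying formal charge (ionized at physiological pH)
DEFAULT_FEATURE_RULES: dict[str, str] = {
    "A": "[$([O;X2;H0]),$([O;X1]),$([OH]),$([N;!+;H0;!X4;!$(N=O)]),$([n;H0;+0])]",
    "D": "[$([N;!H0;!+]),$([O;H1]),$([n;H1])]",
    "H": "[C;!$([C]~[!#6;!#1])]",
    "N": "[$([O-]),$([S-]),$([N-])]",
    "P": "[$([N+]),$([n+])]",
}


@dataclass(frozen=True)
class PharmacophoreFeature:
    type: str
    position: np.ndarray  # (3,) Å
    atoms: tuple[int, ...]  # source atom indices

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")


@dataclass(frozen=True)
class LigandPrepConfig:
    """Ligand preparation limits applied before conformer analysis."""

    ph_center: float = 7.2
    ph_window: float = 0.2
    max_conformers_per_rotatable_bond: int = 100
    max_conformers_per_compound: int = 1000
    energy_window_kj: float = 50.0
    dedup_rmsd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("ph_center", "ph_window", "max_conformers_per_rotatable_bond",
                     "max_conformers_per_compound", "energy_window_kj", "dedup_rmsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PharmacophoreHypothesis:
    """k typed feature slots with a symmetric inter-feature distance matrix."""

    feature_types: tuple[str, ...]
    distances: np.ndarray  # (k, k) Å
    tolerance: float = 2.0
    reference_coords: np.ndarray | None = None  # (k, 3) if built from a conformer

    def __post_init__(self) -> None:
        D = np.asarray(self.distances, dtype=float)
        k = len(self.feature_types)
        if D.shape != (k, k):
            raise ValueError("distance matrix shape must match feature count")
        if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        for i, j, l in itertools.permutations(range(k), 3):
            if D[i, j] > D[i, l] + D[l, j] + 1e-9:
                raise ValueError("distance matrix violates the triangle inequality")
        self.distances = D

    def coordinates(self) -> np.ndarray:
        """Reference 3D coordinates; embedded from distances if needed."""
        if self.reference_coords is not None:
            return np.asarray(self.reference_coords, dtype=float)
        # classical MDS on the distance matrix
        D2 = self.distances**2
        J = np.eye(len(self.feature_types)) - 1.0 / len(self.feature_types)
        G = -0.5 * J @ D2 @ J
        w, V = np.linalg.eigh(G)
        idx = np.argsort(w)[::-1][:3]
        coords = V[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))
        out = np.zeros((len(self.feature_types), 3))
        out[:, : coords.shape[1]] = coords
        return out


@dataclass
class MatchResult:
    mapping: tuple[int, ...]  # conformer feature index per hypothesis slot
    rmsd: float
    fit: float  # max(0, 1 - rmsd/tolerance)
    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,)


def embed_conformer(mol: Chem.Mol, seed: int = 0, optimize: bool = True) -> Chem.Mol:
    """Distance-geometry (ETKDG) 3D embedding, deterministic for a seed."""
    mol = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError("conformer embedding failed")
    if optimize:
        AllChem.MMFFOptimizeMolecule(mol)
    return Chem.RemoveHs(mol)


def perceive_features(
    mol: Chem.Mol, rules: dict[str, str] = DEFAULT_FEATURE_RULES, conf_id: int = -1
) -> list[PharmacophoreFeature]:
    """Typed feature points with 3D coordinates from one conformer.

    Point features (A/D/H/N/P) sit on their source atom; aromatic-ring (R)
    features sit at the ring centroid.  Requires 3D coordinates.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D coordinates; embed a conformer first")
    conf = mol.GetConformer(conf_id)

    def pos(idx: int) -> np.ndarray:
        p = conf.GetAtomPosition(idx)
        return np.array([p.x, p.y, p.z])

    features: list[PharmacophoreFeature] = []
    for ftype, smarts in rules.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid feature SMARTS for {ftype!r}: {smarts!r}")
        seen: set[int] = set()
        for match in mol.GetSubstructMatches(patt):
            idx = match[0]
            if idx in seen:
                continue
            seen.add(idx)
            features.append(PharmacophoreFeature(type=ftype, position=pos(idx), atoms=(idx,)))
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            centroid = np.mean([pos(i) for i in ring], axis=0)
            features.append(PharmacophoreFeature(type="R", position=centroid, atoms=tuple(ring)))
    return features


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of P onto Q (proper rotation only).

    Returns (rotation R, translation t, rmsd) with R @ p + t ≈ q; the SVD
    determinant correction forbids reflections.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def match(
    mol: Chem.Mol,
    hypothesis: PharmacophoreHypothesis,
    tolerance: float | None = None,
    rules: dict[str, str] = DEFAULT_FEATURE_RULES,
    features: Sequence[PharmacophoreFeature] | None = None,
) -> MatchResult | None:
    """Best rigid fit of a conformer's features to the hypothesis, or None.

    Assignments map distinct conformer features of matching type onto the
    hypothesis slots; an assignment survives only if every inter-feature
    distance is within ``tolerance`` of the hypothesis distance.  Survivors
    are superposed by Kabsch and the minimum-RMSD assignment is returned
    with fit = max(0, 1 - rmsd / tolerance).
    """
    tol = hypothesis.tolerance if tolerance is None else tolerance
    feats = list(features) if features is not None else perceive_features(mol, rules)
    slots = hypothesis.feature_types
    by_type: dict[str, list[int]] = {}
    for i, f in enumerate(feats):
        by_type.setdefault(f.type, []).append(i)
    if any(t not in by_type for t in slots):
        return None

    ref = hypothesis.coordinates()
    D_hyp = hypothesis.distances
    best: MatchResult | None = None
    for assignment in itertools.product(*[by_type[t] for t in slots]):
        if len(set(assignment)) != len(assignment):
            continue
        pts = np.array([feats[i].position for i in assignment])
        ok = True
        for a, b in itertools.combinations(range(len(slots)), 2):
            if abs(np.linalg.norm(pts[a] - pts[b]) - D_hyp[a, b]) > tol:
                ok = False
                break
        if not ok:
            continue
        R, t, rmsd = kabsch(pts, ref)
        if best is None or rmsd < best.rmsd:
            best = MatchResult(
                mapping=tuple(assignment),
                rmsd=rmsd,
                fit=max(0.0, 1.0 - rmsd / tol),
                rotation=R,
                translation=t,
            )
    return best


def enumerate_hypotheses(
    features: Sequence[PharmacophoreFeature],
    k: int = 4,
    distance_bounds: tuple[float, float] | None = None,
    tolerance: float = 2.0,
) -> list[PharmacophoreHypothesis]:
    """All k-subsets of reference features as candidate hypotheses.

    ``distance_bounds = (lo, hi)`` keeps only subsets whose pairwise
    distances all lie inside the bounds.  With fewer than ``k`` features
    the list is empty.  Without bounds the count is C(n_features, k).
    """
    out: list[PharmacophoreHypothesis] = []
    for combo in itertools.combinations(range(len(features)), k):
        pts = np.array([features[i].position for i in combo])
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        if distance_bounds is not None:
            lo, hi = distance_bounds
            off_diag = D[np.triu_indices(k, 1)]
            if (off_diag < lo).any() or (off_diag > hi).any():
                continue
        out.append(
            PharmacophoreHypothesis(
                feature_types=tuple(features[i].type for i in combo),
                distances=D,
                tolerance=tolerance,
                reference_coords=pts,
            )
        )
    return out


def score_hypothesis(
    hypothesis: PharmacophoreHypothesis,
    actives: Sequence[Chem.Mol],
    inactives: Sequence[Chem.Mol],
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    rules: dict[str, str] = DEFAULT_FEATURE_RULES,
) -> float:
    """Survival-lite hypothesis score (transparent surrogate).

    score = w1 * (fraction of actives matched)
          + w2 * (mean fit over matched actives)
          - w3 * (fraction of inactives matched)

    Deterministic given the conformers; bounded by w1 + w2 when every
    active fits perfectly and no inactive matches.
    """
    if len(actives) == 0:
        raise ValueError("score_hypothesis requires at least one active")
    w1, w2, w3 = weights
    fits = []
    n_matched = 0
    for mol in actives:
        res = match(mol, hypothesis, rules=rules)
        if res is not None:
            n_matched += 1
            fits.append(res.fit)
    frac_active = n_matched / len(actives)
    mean_fit = float(np.mean(fits)) if fits else 0.0
    frac_inactive = 0.0
    if inactives:
        hits = sum(1 for mol in inactives if match(mol, hypothesis, rules=rules) is not None)
        frac_inactive = hits / len(inactives)
    return w1 * frac_active + w2 * mean_fit - w3 * frac_inactive


def write_aligned_sdf(
    mols: Sequence[Chem.Mol],
    matches: Sequence[MatchResult | None],
    path: str,
    ids: Sequence[str] | None = None,
) -> int:
    """Write conformers into the hypothesis frame as a multi-record SDF.

    Each matched molecule is rigidly transformed by its match's rotation/
    translation; unmatched molecules are skipped.  Returns the number of
    records written.
    """
    writer = Chem.SDWriter(str(path))
    written = 0
    for i, (mol, res) in enumerate(zip(mols, matches)):
        if res is None:
            continue
        out = Chem.Mol(mol)
        conf = out.GetConformer()
        for a in range(out.GetNumAtoms()):
            p = conf.GetAtomPosition(a)
            v = res.rotation @ np.array([p.x, p.y, p.z]) + res.translation
            conf.SetAtomPosition(a, v.tolist())
        if ids is not None:
            out.SetProp("_Name", str(ids[i]))
        out.SetProp("match_rmsd", f"{res.rmsd:.6f}")
        out.SetProp("match_fit", f"{res.fit:.6f}")
        writer.write(out)
        written += 1
    writer.close()
    return written


def hypothesis_to_dict(h: PharmacophoreHypothesis) -> dict:
    return {
        "feature_types": list(h.feature_types),
        "distances": h.distances.tolist(),
        "tolerance": h.tolerance,
    }


def hypothesis_from_dict(d: dict) -> PharmacophoreHypothesis:
    return PharmacophoreHypothesis(
        feature_types=tuple(d["feature_types"]),
        distances=np.asarray(d["distances"], dtype=float),
        tolerance=float(d.get("tolerance", 2.0)),
    )
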