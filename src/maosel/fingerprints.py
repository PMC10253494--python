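"""Folded circular fingerprints and per-bit selectivity statistics.

Each compound is encoded as an ECFP4-style fingerprint (Morgan algorithm,
bond radius 2, folded to 1024 bits by default).  For every bit this module
computes carrier counts and class-conditional frequencies in the selective
vs non-selective class, plus two ROC-AUC readings of how well the bit
discriminates selectivity:

* ``auc_bit`` — the bit value as score, selectivity class as label.  For a
  binary score this reduces to the closed form
  ``s*(1-t) + 0.5*(s*t + (1-s)*(1-t))`` with ``s = freq_sel``,
  ``t = freq_nonsel`` (ties credited 0.5, the Mann-Whitney convention).
* ``auc_sirank`` — the selectivity index as score, bit carriage as label.

Hashed bit indices are implementation-specific opaque labels; substructure
interpretation goes through :func:`substructure_for_bit`, which extracts
the atom environment that set a bit, and :func:`assign_zones`, which maps
representative substructures to user-declared molecular zones (e.g. the
fused-core, linker and substituent regions A-E of an inhibitor series).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.stats import rankdata

from .dataset import NON_SELECTIVE, SELECTIVE, CompoundRecord

logger = logging.getLogger(__name__)


@dataclass
class FingerprintMatrix:
    """Binary n_compounds x n_bits matrix with row order matching ids."""

    matrix: np.ndarray  # uint8, entries in {0, 1}
    ids: list[str]
    radius: int = 2
    n_bits: int = 1024

    def __post_init__(self) -> None:
        if self.n_bits & (self.n_bits - 1):
            raise ValueError("n_bits must be a power of two")
        if self.matrix.shape != (len(self.ids), self.n_bits):
            raise ValueError("matrix shape inconsistent with ids/n_bits")


@dataclass
class BitStat:
    """Per-bit selectivity statistics."""

    bit: int
    count_sel: int
    count_nonsel: int
    freq_sel: float
    freq_nonsel: float
    auc_bit: float
    auc_sirank: float | None = None
    substructure_smiles: str | None = None
    zone: str | None = None


@dataclass
class BitStatTable:
    """Bit statistics together with the class sizes they were computed on."""

    stats: list[BitStat]
    n_sel: int
    n_nonsel: int

    def __iter__(self):
        return iter(self.stats)

    def __len__(self):
        return len(self.stats)


def _mol(rec: CompoundRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(rec, Chem.Mol):
        return rec
    smiles = rec.smiles if isinstance(rec, CompoundRecord) else rec
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol


def _generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def compute_fingerprints(
    records: Sequence[CompoundRecord | Chem.Mol | str], radius: int = 2, n_bits: int = 1024
) -> FingerprintMatrix:
    """Morgan (ECFP-style) fingerprints folded to ``n_bits``.

    ``radius`` counts bonds, so the default radius 2 corresponds to the
    conventional diameter-4 fingerprint (ECFP4).
    """
    gen = _generator(radius, n_bits)
    rows = np.zeros((len(records), n_bits), dtype=np.uint8)
    ids = []
    for i, rec in enumerate(records):
        mol = _mol(rec)
        rows[i] = np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)
        ids.append(rec.id if isinstance(rec, CompoundRecord) else f"mol{i}")
    return FingerprintMatrix(matrix=rows, ids=ids, radius=radius, n_bits=n_bits)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney ROC AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Computed from the rank-sum statistic with midranks, so ties receive
    0.5 credit.  ``labels`` is boolean (True = positive class).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("rank_auc requires both classes to be non-empty")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def binary_score_auc(freq_pos: float, freq_neg: float) -> float:
    """Closed-form Mann-Whitney AUC for a binary score.

    With carrier frequency ``s`` in the positive and ``t`` in the negative
    class: AUC = s(1-t) + 0.5(st + (1-s)(1-t)).
    """
    s, t = freq_pos, freq_neg
    return s * (1 - t) + 0.5 * (s * t + (1 - s) * (1 - t))


def bit_statistics(
    fingerprints: FingerprintMatrix,
    classes: Sequence[str],
    si: Sequence[float] | None = None,
) -> BitStatTable:
    """Carrier counts, class-conditional frequencies and AUCs per bit.

    ``classes`` holds the selectivity class per row; both classes must be
    non-empty.  When ``si`` is given, ``auc_sirank`` (SI as score, bit
    carriage as label) is computed for every bit carried by at least one
    and not all compounds.
    """
    classes = np.asarray(classes)
    if len(classes) != len(fingerprints.ids):
        raise ValueError("classes length must match fingerprint rows")
    sel_mask = classes == SELECTIVE
    nonsel_mask = classes == NON_SELECTIVE
    n_sel = int(sel_mask.sum())
    n_nonsel = int(nonsel_mask.sum())
    if n_sel == 0 or n_nonsel == 0:
        raise ValueError("both selectivity classes must be non-empty")
    M = fingerprints.matrix.astype(bool)
    si_arr = np.asarray(si, dtype=float) if si is not None else None

    stats: list[BitStat] = []
    for bit in range(fingerprints.n_bits):
        col = M[:, bit]
        count_sel = int(col[sel_mask].sum())
        count_nonsel = int(col[nonsel_mask].sum())
        freq_sel = count_sel / n_sel
        freq_nonsel = count_nonsel / n_nonsel
        auc_si = None
        if si_arr is not None:
            carried = col[sel_mask | nonsel_mask]
            if 0 < carried.sum() < carried.size:
                auc_si = rank_auc(si_arr[sel_mask | nonsel_mask], carried)
        stats.append(
            BitStat(
                bit=bit,
                count_sel=count_sel,
                count_nonsel=count_nonsel,
                freq_sel=freq_sel,
                freq_nonsel=freq_nonsel,
                auc_bit=binary_score_auc(freq_sel, freq_nonsel),
                auc_sirank=auc_si,
            )
        )
    return BitStatTable(stats=stats, n_sel=n_sel, n_nonsel=n_nonsel)


def prevalence_filter(table: BitStatTable, min_fraction: float = 0.10) -> BitStatTable:
    """Keep bits whose overall carrier fraction is >= ``min_fraction``."""
    if not 0.0 <= min_fraction < 1.0:
        raise ValueError("min_fraction must be in [0, 1)")
    n = table.n_sel + table.n_nonsel
    kept = [s for s in table.stats if (s.count_sel + s.count_nonsel) / n >= min_fraction]
    return BitStatTable(stats=kept, n_sel=table.n_sel, n_nonsel=table.n_nonsel)


def mean_bits_per_molecule(
    fingerprints: FingerprintMatrix, bits: Sequence[int], classes: Sequence[str]
) -> dict[str, float]:
    """Mean number of set bits (restricted to ``bits``) per molecule, by class."""
    if len(bits) == 0:
        raise ValueError("bit subset must be non-empty")
    classes = np.asarray(classes)
    sub = fingerprints.matrix[:, list(bits)].astype(float)
    counts = sub.sum(axis=1)
    return {
        cls: float(counts[classes == cls].mean())
        for cls in dict.fromkeys(classes.tolist())  # preserves first-seen order
    }


def substructure_for_bit(
    record: CompoundRecord | Chem.Mol | str, bit: int, radius: int = 2, n_bits: int = 1024
) -> str:
    """SMILES of the atom environment that sets ``bit`` in this molecule.

    Among the environments hashing to the bit after folding, the smallest
    radius (then lowest atom index) is returned.  Raises if the molecule
    does not carry the bit.
    """
    mol = _mol(record)
    gen = _generator(radius, n_bits)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetFingerprint(mol, additionalOutput=ao)
    envs = ao.GetBitInfoMap().get(bit)
    if not envs:
        raise ValueError(f"molecule does not carry bit {bit}")
    atom, r = min(envs, key=lambda e: (e[1], e[0]))
    if r == 0:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[atom])
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, r, atom)
    submol = Chem.PathToSubmol(mol, bond_ids)
    return Chem.MolToSmiles(submol)


def attach_substructures(
    table: BitStatTable,
    records: Sequence[CompoundRecord | Chem.Mol | str],
    fingerprints: FingerprintMatrix,
) -> BitStatTable:
    """Fill each stat's representative substructure from its first carrier."""
    M = fingerprints.matrix.astype(bool)
    out = []
    for stat in table.stats:
        carriers = np.flatnonzero(M[:, stat.bit])
        if carriers.size:
            smi = substructure_for_bit(
                records[carriers[0]], stat.bit, fingerprints.radius, fingerprints.n_bits
            )
            stat = replace(stat, substructure_smiles=smi)
        out.append(stat)
    return BitStatTable(stats=out, n_sel=table.n_sel, n_nonsel=table.n_nonsel)


def fragment_mol(fragment_smiles: str) -> Chem.Mol | None:
    """Parse an atom-environment fragment leniently.

    Environment fragments may contain aromatic atoms without a complete
    ring, which strict SMILES parsing rejects; kekulization is therefore
    skipped.
    """
    mol = Chem.MolFromSmiles(fragment_smiles, sanitize=False)
    if mol is None:
        return None
    try:
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    except Exception:
        return None
    return mol


def assign_zones(table: BitStatTable, zone_map: Mapping[str, str]) -> BitStatTable:
    """Label bits whose representative substructure matches a zone pattern.

    ``zone_map`` maps SMARTS patterns to zone labels (e.g. ``A``-``E``).
    The first matching pattern wins; a substructure matching several zones
    logs a warning.  Bits without a substructure or match keep zone None.
    """
    compiled = []
    for patt, label in zone_map.items():
        q = Chem.MolFromSmarts(patt)
        if q is None:
            raise ValueError(f"invalid zone SMARTS: {patt!r}")
        compiled.append((patt, q, label))
    out = []
    for stat in table.stats:
        zone = None
        if stat.substructure_smiles:
            frag = fragment_mol(stat.substructure_smiles)
            if frag is not None:
                matches = [(p, lab) for p, q, lab in compiled if frag.HasSubstructMatch(q)]
                if matches:
                    zone = matches[0][1]
                    if len(matches) > 1:
                        logger.warning(
                            "bit %d substructure matches multiple zones %s; keeping first",
                            stat.bit,
                            [lab for _, lab in matches],
                        )
        out.append(replace(stat, zone=zone))
    return BitStatTable(stats=out, n_sel=table.n_sel, n_nonsel=table.n_nonsel)


def bitstats_to_frame(table: BitStatTable):
    """Per-bit statistics as a DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "bit": [s.bit for s in table.stats],
            "count_sel": [s.count_sel for s in table.stats],
            "count_nonsel": [s.count_nonsel for s in table.stats],
            "freq_sel": [s.freq_sel for s in table.stats],
            "freq_nonsel": [s.freq_nonsel for s in table.stats],
            "auc_bit": [s.auc_bit for s in table.stats],
            "auc_sirank": [s.auc_sirank for s in table.stats],
            "substructure_smiles": [s.substructure_smiles for s in table.stats],
            "zone": [s.zone for s in table.stats],
        }
    )
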