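"""End-to-end orchestration: prepare -> profile -> cliffs -> pharmacophore
-> QSAR -> validation, driven by one serialisable configuration.

Every run writes its resolved configuration next to its outputs, all
randomness is seeded from the config (no wall-clock seeding), and stage
outputs are plain CSV/JSON/GraphML so any stage can be rerun standalone.
Rerunning with the same config reproduces the outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from rdkit import Chem

from . import cliffs as cliffs_mod
from . import fingerprints as fp_mod
from . import pharmacophore as ph_mod
from . import qsar as qsar_mod
from . import synthetic as syn_mod
from . import validation as val_mod
from .dataset import (
    SELECTIVE,
    classify_selectivity,
    dataset_summary,
    load_dataset,
    records_from_frame,
    records_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run (YAML-serialisable)."""

    # input: either a compound CSV or a synthetic dataset spec
    input_csv: str | None = None
    ic50_unit: str = "nM"
    synthetic_n: int = 126
    synthetic_selective_fraction: float = 34 / 126
    # dataset
    si_threshold: float = 50.0
    # fingerprints
    fp_radius: int = 2
    fp_n_bits: int = 1024
    prevalence_min_fraction: float = 0.10
    zone_map: dict = field(default_factory=dict)
    # cliffs
    similarity_backend: str = "ecfp-tanimoto"
    cliff_mode: str = "activity"
    cliff_top_k: int = 20
    edge_threshold: float = 0.55
    n_clusters: int = 8
    # pharmacophore (optional stage)
    run_pharmacophore: bool = True
    pharmacophore_k: int = 4
    pharmacophore_tolerance: float = 2.0
    n_actives: int = 11
    n_inactives: int = 8
    max_hypotheses_scored: int = 30
    # qsar + validation (optional stage)
    run_qsar: bool = True
    qsar_mode: str = "grid"  # "grid" (abstract occupancy set) or "molecular"
    grid_dims: tuple[int, int, int] = (5, 4, 3)
    grid_spacing: float = 1.0
    n_active_cells: int = 10
    qsar_noise_sd: float = 0.35
    n_factors: int = 4
    split_fraction: float = 0.70
    n_permutations: int = 100
    # bookkeeping
    seed: int = 0
    outdir: str = "run"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "grid_dims" in d:
            d["grid_dims"] = tuple(d["grid_dims"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def stage_prepare(config: RunConfig, outdir: Path) -> list:
    """Load or simulate the dataset, classify selectivity, summarise."""
    if config.input_csv:
        result = load_dataset(config.input_csv, ic50_unit=config.ic50_unit)
        records = result.records
        result.rejects.to_csv(outdir / "rejects.csv", index=False)
        if result.duplicates:
            _write_json({"duplicates": result.duplicates}, outdir / "duplicates.json")
    else:
        records, gt = syn_mod.generate_dataset(
            n=config.synthetic_n,
            selective_fraction=config.synthetic_selective_fraction,
            seed=config.seed,
        )
        syn_mod.write_dataset(records, gt, outdir)
    records = classify_selectivity(records, config.si_threshold)
    records_to_frame(records).to_csv(outdir / "dataset_normalized.csv", index=False)
    _write_json(dataset_summary(records), outdir / "summary.json")
    return records


def stage_profile(config: RunConfig, records, outdir: Path) -> fp_mod.BitStatTable:
    fps = fp_mod.compute_fingerprints(records, config.fp_radius, config.fp_n_bits)
    classes = [r.selectivity_class for r in records]
    si = [r.si for r in records]
    table = fp_mod.bit_statistics(fps, classes, si)
    table = fp_mod.prevalence_filter(table, config.prevalence_min_fraction)
    table = fp_mod.attach_substructures(table, records, fps)
    if config.zone_map:
        table = fp_mod.assign_zones(table, config.zone_map)
    kept_bits = [s.bit for s in table.stats]
    means = fp_mod.mean_bits_per_molecule(fps, kept_bits, classes) if kept_bits else {}
    fp_mod.bitstats_to_frame(table).to_csv(outdir / "bitstats.csv", index=False)
    _write_json(
        {
            "radius": config.fp_radius,
            "n_bits": config.fp_n_bits,
            "prevalence_min_fraction": config.prevalence_min_fraction,
            "n_bits_kept": len(kept_bits),
            "mean_bits_per_molecule": means,
        },
        outdir / "profile_meta.json",
    )
    return table


def stage_cliffs(config: RunConfig, records, outdir: Path) -> None:
    fps = fp_mod.compute_fingerprints(records, config.fp_radius, config.fp_n_bits)
    sim = cliffs_mod.pairwise_similarity(fps)
    for mode in ("activity", "selectivity"):
        pairs = cliffs_mod.detect_cliffs(records, sim, mode=mode, top_k=config.cliff_top_k)
        cliffs_mod.cliffs_to_frame(pairs).to_csv(outdir / f"cliffs_{mode}.csv", index=False)
    import networkx as nx

    G = cliffs_mod.build_network(records, sim, config.edge_threshold, mode=config.cliff_mode)
    nx.write_graphml(G, outdir / "network.graphml")
    labels = cliffs_mod.cluster(sim, k=config.n_clusters)
    import pandas as pd

    pd.DataFrame({"id": [r.id for r in records], "cluster": labels}).to_csv(
        outdir / "clusters.csv", index=False
    )


def stage_pharmacophore(config: RunConfig, records, outdir: Path) -> None:
    """Hypothesis search anchored on the most selective compound.

    Conformers are embedded for the most and least active compounds; all
    k-point hypotheses of the reference are scored with the survival-lite
    score and the winner is written out with its match report.
    """
    ranked = sorted(records, key=lambda r: (-(r.si or 0.0), r.id))
    reference = ranked[0]
    by_potency = sorted(records, key=lambda r: (-r.pic50_b, r.id))
    actives = by_potency[: config.n_actives]
    inactives = by_potency[-config.n_inactives :]

    def conf(rec):
        return ph_mod.embed_conformer(Chem.MolFromSmiles(rec.smiles), seed=config.seed)

    ref_mol = conf(reference)
    feats = ph_mod.perceive_features(ref_mol)
    hyps = ph_mod.enumerate_hypotheses(feats, k=config.pharmacophore_k, tolerance=config.pharmacophore_tolerance)
    if not hyps:
        _write_json({"reference": reference.id, "n_hypotheses": 0}, outdir / "hypothesis.json")
        return
    active_confs = [conf(r) for r in actives]
    inactive_confs = [conf(r) for r in inactives]
    scored = []
    for h in hyps[: config.max_hypotheses_scored]:
        scored.append((ph_mod.score_hypothesis(h, active_confs, inactive_confs), h))
    scored.sort(key=lambda t: -t[0])
    best_score, best = scored[0]
    payload = ph_mod.hypothesis_to_dict(best)
    payload.update({"reference": reference.id, "score": best_score, "n_hypotheses": len(hyps)})
    _write_json(payload, outdir / "hypothesis.json")

    import pandas as pd

    rows = []
    for rec, mol in zip(actives + inactives, active_confs + inactive_confs):
        res = ph_mod.match(mol, best)
        rows.append(
            {
                "id": rec.id,
                "pic50_b": rec.pic50_b,
                "matched": res is not None,
                "rmsd": res.rmsd if res else None,
                "fit": res.fit if res else None,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "match_report.csv", index=False)


def stage_qsar_validate(config: RunConfig, records, outdir: Path) -> dict:
    """Grid-occupancy PLS + the full validation battery.

    In ``grid`` mode the occupancy matrix is the abstract synthetic set
    with planted coefficients; in ``molecular`` mode conformers of the
    dataset are embedded, aligned on their common scaffold frame and
    encoded over a shared grid.
    """
    if config.qsar_mode == "grid":
        X, y, beta = syn_mod.generate_aligned_grid_set(
            n=len(records),
            grid_dims=config.grid_dims,
            n_active_cells=config.n_active_cells,
            noise_sd=config.qsar_noise_sd,
            seed=config.seed + 1,
        )
        grid = None
    elif config.qsar_mode == "molecular":
        from rdkit.Chem import AllChem

        mols = [ph_mod.embed_conformer(Chem.MolFromSmiles(r.smiles), seed=config.seed) for r in records]
        # rigid-align everything onto the most selective compound's conformer
        ref_idx = max(range(len(records)), key=lambda i: records[i].si or 0.0)
        ref = mols[ref_idx]
        for i, mol in enumerate(mols):
            if i == ref_idx:
                continue
            try:
                AllChem.GetO3A(mol, ref).Align()
            except Exception:
                logger.warning("compound %s: O3A alignment failed; kept unaligned", records[i].id)
        X, grid = qsar_mod.encode_occupancy(mols)
        X = X.astype(float)
        y = np.array([r.pic50_b for r in records])
    else:
        raise ValueError(f"unknown qsar_mode {config.qsar_mode!r}")

    idx = list(range(len(y)))
    train_idx, test_idx = val_mod.split_train_test(idx, config.split_fraction, seed=config.seed)
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]

    model = qsar_mod.fit_pls(X_tr, y_tr, n_factors=config.n_factors, grid=grid,
                             stability_seed=config.seed)
    qsar_mod.factor_stats_frame(model).to_csv(outdir / "qsar_stats.csv", index=False)

    pred_tr = model.predict(X_tr)
    pred_te = model.predict(X_te)
    ext = val_mod.external_metrics(y_tr, y_te, pred_te)

    def fit_r2(Xp, yp):
        m = qsar_mod.fit_pls(Xp, yp, n_factors=config.n_factors, stability_subsets=0)
        return m.factor_stats[-1].r2

    yrand = val_mod.y_randomization(
        X_tr, y_tr, fit_r2, n_perm=config.n_permutations, seed=config.seed
    )
    last = model.factor_stats[-1]
    report = val_mod.ValidationReport(
        r2_tr=last.r2,
        q2_test=ext["q2f1"],
        pearson_r_test=ext["pearson_r"],
        sd=last.sd,
        f_value=last.f,
        p_value=last.p,
        q2f1=ext["q2f1"],
        q2f2=ext["q2f2"],
        q2f3=ext["q2f3"],
        ccc_tr=val_mod.concordance_ccc(y_tr, pred_tr),
        ccc_test=ext["ccc_test"],
        rmse_tr=float(np.sqrt(np.mean((y_tr - pred_tr) ** 2))),
        rmse_test=ext["rmse_test"],
        mae_tr=float(np.mean(np.abs(y_tr - pred_tr))),
        mae_test=ext["mae_test"],
        r2_pred=ext["r2_pred"],
        stability=last.stability,
        yrand_pass=yrand.passed,
        split_seed=config.seed,
    )
    _write_json(report.to_dict(), outdir / "validation.json")
    import pandas as pd

    pd.DataFrame([report.to_dict()]).to_csv(outdir / "validation.csv", index=False)
    return report.to_dict()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    if config.input_csv and not Path(config.input_csv).exists():
        raise FileNotFoundError(f"input_csv not found: {config.input_csv}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    stages: list[tuple[str, callable]] = []
    records = None

    def _run(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    records = _run("prepare", stage_prepare, config, outdir)
    _run("profile", stage_profile, config, records, outdir)
    _run("cliffs", stage_cliffs, config, records, outdir)
    if config.run_pharmacophore:
        _run("pharmacophore", stage_pharmacophore, config, records, outdir)
    if config.run_qsar:
        _run("qsar+validate", stage_qsar_validate, config, records, outdir)
    logger.info("pipeline complete: %s", outdir)
    return outdir


def report(run_dir: str | Path) -> str:
    """Assemble a Markdown report from a completed run directory.

    Idempotent; missing stages are noted rather than fatal.  Every number
    shown traces to a CSV/JSON artifact in the run directory.
    """
    import pandas as pd

    run_dir = Path(run_dir)
    lines = ["# Selectivity profiling run report", ""]

    summary_path = run_dir / "summary.json"
    if summary_path.exists():
        with open(summary_path) as fh:
            summary = json.load(fh)
        lines += [
            "## Dataset",
            f"- n = {summary['n']}, classes: {summary['class_counts']}",
            f"- global pIC50 span: {summary['pic50_span']:.2f} log units",
            "",
        ]
    else:
        lines += ["## Dataset", "- missing stage: prepare", ""]

    bits_path = run_dir / "bitstats.csv"
    if bits_path.exists():
        bits = pd.read_csv(bits_path)
        if len(bits):
            top = bits.sort_values("auc_bit", ascending=False).head(5)
            lines += ["## Top selectivity-discriminating bits (by bit-AUC)", ""]
            lines.append("| bit | freq_sel | freq_nonsel | auc_bit | substructure |")
            lines.append("|---|---|---|---|---|")
            for _, row in top.iterrows():
                lines.append(
                    f"| {int(row.bit)} | {row.freq_sel:.3f} | {row.freq_nonsel:.3f} "
                    f"| {row.auc_bit:.3f} | `{row.substructure_smiles}` |"
                )
            lines.append("")
    else:
        lines += ["## Bit profile", "- missing stage: profile", ""]

    cliffs_path = run_dir / "cliffs_activity.csv"
    if cliffs_path.exists():
        cl = pd.read_csv(cliffs_path)
        if len(cl) == 0:
            lines += ["## Activity cliffs", "- none detected", ""]
        else:
            lines += ["## Activity cliffs (top 5 by SALI)", ""]
            for _, row in cl.head(5).iterrows():
                score = "inf" if row.infinite else f"{row.sali:.1f}"
                lines.append(f"- {row.i} / {row.j}: SALI {score}, delta {row.activity_delta:.3f}, sim {row.sim:.3f}")
            lines.append("")
    else:
        lines += ["## Activity cliffs", "- missing stage: cliffs", ""]

    val_path = run_dir / "validation.json"
    if val_path.exists():
        with open(val_path) as fh:
            val = json.load(fh)
        ok = (val["q2_test"] or 0) > 0.6 and (val["pearson_r_test"] or 0) > 0.8
        lines += [
            "## QSAR validation battery",
            f"- training r2 = {val['r2_tr']:.3f}, external Q2 (F1) = {val['q2f1']:.3f}, "
            f"Pearson R = {val['pearson_r_test']:.3f}",
            f"- Q2F2 = {val['q2f2']:.3f}, Q2F3 = {val['q2f3']:.3f}, CCC(test) = {val['ccc_test']:.3f}",
            f"- RMSE train/test = {val['rmse_tr']:.3f}/{val['rmse_test']:.3f}, "
            f"MAE train/test = {val['mae_tr']:.3f}/{val['mae_test']:.3f}",
            f"- Y-randomization: {'pass' if val['yrand_pass'] else 'FAIL'}",
            f"- acceptance thresholds (Q2 > 0.6 and Pearson R > 0.8): {'met' if ok else 'NOT met'}",
            "",
        ]
    else:
        lines += ["## QSAR validation battery", "- missing stage: qsar+validate", ""]

    text = "\n".join(lines)
    with open(run_dir / "report.md", "w") as fh:
        fh.write(text)
    return text
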