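"""End-to-end orchestration: simulate -> connect -> filter -> metrics -> classify.

Each stage writes its artifacts under the run directory and is skipped on
re-run when its outputs already exist, so a partially failed run resumes
from the cached artifacts. All randomness flows from the config seed; a
seed manifest and a timestamped log are written per run.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import crossvalidate, edge_feature_matrix
from .config import PipelineConfig
from .connectivity import build_sl_fcgs
from .graphs import (
    assemble_mlfcg,
    comodulogram,
    group_average_comodulogram,
    mpc,
    omst_filter,
)
from .io import (
    read_cohort,
    read_subject_graphs,
    write_cohort,
    write_subject_graphs,
)
from .simulate import default_plan, generate_cohort


def _log(run_dir: Path, msg: str) -> None:
    stamp = time.strftime("%Y-%m-%d %H:%M:%S")
    with open(run_dir / "run.log", "a") as fh:
        fh.write(f"[{stamp}] {msg}\n")


def _init_run(config: PipelineConfig, outdir: str | Path) -> Path:
    run_dir = Path(outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    manifest = {"seed": config.seed, "package_version": __version__}
    try:
        import scipy
        import sklearn

        manifest["numpy"] = np.__version__
        manifest["scipy"] = scipy.__version__
        manifest["scikit-learn"] = sklearn.__version__
    except ImportError:  # pragma: no cover
        pass
    (run_dir / "seed_manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


def stage_simulate(config: PipelineConfig, run_dir: Path) -> Path:
    cohort_path = run_dir / "cohort.h5"
    if cohort_path.exists():
        _log(run_dir, "simulate: cohort.h5 cached, skipping")
        return cohort_path
    t0 = time.time()
    plan = default_plan(n_rois=config.n_rois, seed=config.seed)
    plan = plan.__class__(
        n_rois=plan.n_rois,
        edges=plan.edges,
        group_effects=plan.group_effects,
        bands=config.bands,
        noise_exponent=config.noise_exponent,
        snr=config.snr,
        seed=config.seed,
    )
    recs, truth = generate_cohort(
        plan,
        n_subjects_per_group=config.n_subjects_per_group,
        epochs=config.epochs,
        epoch_len_s=config.epoch_len_s,
        fs=config.fs,
    )
    write_cohort(cohort_path, recs)
    truth.to_csv(run_dir / "ground_truth.csv", index=False)
    _log(run_dir, f"simulate: {len(recs)} subjects in {time.time() - t0:.1f} s")
    return cohort_path


def stage_connect(config: PipelineConfig, run_dir: Path, cohort_path: Path) -> Path:
    graph_dir = run_dir / "graphs"
    graph_dir.mkdir(exist_ok=True)
    t0 = time.time()
    n_done = 0
    for rec in read_cohort(cohort_path):
        out = graph_dir / f"{rec.subject_id}.h5"
        if out.exists():
            continue
        graphs = build_sl_fcgs(
            rec, config.estimator, bands=config.bands, cfc_symmetrize=config.cfc_symmetrize
        )
        write_subject_graphs(out, graphs)
        n_done += 1
    _log(run_dir, f"connect[{config.estimator}]: {n_done} subjects in {time.time() - t0:.1f} s")
    return graph_dir


def _subject_layers(config: PipelineConfig, run_dir: Path) -> dict[str, list]:
    graph_dir = run_dir / "graphs"
    out = {}
    for path in sorted(graph_dir.glob("*.h5")):
        out[path.stem] = read_subject_graphs(path, config.bands)[config.estimator]
    return out


def stage_omst(config: PipelineConfig, run_dir: Path) -> Path:
    """Per-layer OMST filtering plus multilayer OMST on the flattened graph."""
    omst_dir = run_dir / "omst"
    omst_dir.mkdir(exist_ok=True)
    t0 = time.time()
    for sid, layers in _subject_layers(config, run_dir).items():
        out = omst_dir / f"{sid}.h5"
        if out.exists():
            continue
        filtered = []
        for g in layers:
            res = omst_filter(g.W)
            filtered.append(type(g)(estimator=g.estimator, mode=g.mode, W=res.W_filtered))
        write_subject_graphs(out, filtered)
        ml = assemble_mlfcg(layers)
        ml_res = omst_filter(ml.flattened)
        import h5py

        with h5py.File(out, "a") as f:
            f.create_dataset("multilayer/W_filtered", data=ml_res.W_filtered)
    _log(run_dir, f"omst: done in {time.time() - t0:.1f} s")
    return omst_dir


def stage_mpc(config: PipelineConfig, run_dir: Path) -> Path:
    groups = _subject_groups(run_dir)
    rows = []
    for path in sorted((run_dir / "omst").glob("*.h5")):
        layers = read_subject_graphs(path, config.bands)[config.estimator]
        res = mpc([g.W for g in layers])
        rows.append({"subject": path.stem, "group": groups[path.stem], "global_mpc": res.global_mpc}
                    | {f"roi_{i}": v for i, v in enumerate(res.per_node)})
    out = run_dir / "mpc.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    _log(run_dir, f"mpc: {len(rows)} subjects")
    return out


def stage_comodulogram(config: PipelineConfig, run_dir: Path) -> list[Path]:
    import h5py

    groups = _subject_groups(run_dir)
    band_names = [b.name for b in config.bands]
    per_group: dict[int, list] = {1: [], 2: []}
    for path in sorted((run_dir / "omst").glob("*.h5")):
        with h5py.File(path, "r") as f:
            Wf = f["multilayer/W_filtered"][()]
        cm = comodulogram(Wf, n_rois=config.n_rois, band_names=band_names)
        per_group[groups[path.stem]].append(cm)
    outs = []
    for grp, tables in per_group.items():
        if not tables:
            continue
        avg = group_average_comodulogram(tables)
        out = run_dir / f"comodulogram_group{grp}.csv"
        pd.DataFrame(avg.PD, index=band_names, columns=band_names).to_csv(out)
        outs.append(out)
    _log(run_dir, "comodulogram: group averages written")
    return outs


def _subject_groups(run_dir: Path) -> dict[str, int]:
    return {
        rec.subject_id: rec.group for rec in read_cohort(run_dir / "cohort.h5")
    }


def stage_classify(config: PipelineConfig, run_dir: Path) -> Path:
    groups = _subject_groups(run_dir)
    layers_by_subject = _subject_layers(config, run_dir)
    sids = sorted(layers_by_subject)
    y = np.array([groups[s] for s in sids])
    rows = []
    consensus_rows = []
    t0 = time.time()
    for scheme in config.cv_schemes:
        for route in config.routes:
            if route == "mpc":
                df = pd.read_csv(run_dir / "mpc.csv").set_index("subject").loc[sids]
                X = df[[c for c in df.columns if c.startswith("roi_")]].to_numpy()
                results = [("mpc", crossvalidate(
                    X, y, scheme=scheme, route="mpc", k_rank=config.k_rank,
                    m_consensus=config.m_consensus, seed=config.seed))]
            elif route == "edge":
                results = []
                n_layers = len(layers_by_subject[sids[0]])
                for li in range(n_layers):
                    fm = edge_feature_matrix(
                        [layers_by_subject[s][li].W for s in sids], y,
                        mode_label=layers_by_subject[sids[0]][li].mode.label)
                    results.append((fm.feature_ids[0][0], crossvalidate(
                        fm, scheme=scheme, route="edge", k_rank=config.k_rank,
                        m_consensus=config.m_consensus, seed=config.seed)))
            else:  # tensor route runs on the OMST-filtered graphs
                results = []
                filt = {
                    s: read_subject_graphs(run_dir / "omst" / f"{s}.h5", config.bands)[config.estimator]
                    for s in sids
                }
                for li in range(len(filt[sids[0]])):
                    stack = np.stack([filt[s][li].W for s in sids])
                    results.append((filt[sids[0]][li].mode.label, crossvalidate(
                        stack, y, scheme=scheme, route="tensor",
                        d1=min(config.d1, config.n_rois), d2=min(config.d2, config.n_rois),
                        seed=config.seed)))
            for mode_label, res in results:
                rows.append({
                    "scheme": scheme, "route": route, "estimator": config.estimator,
                    "mode": mode_label, "sensitivity": res.sensitivity,
                    "specificity": res.specificity, "accuracy": res.accuracy,
                    "accuracy_sd": res.accuracy_sd,
                })
                for fid, freq in res.consensus_features:
                    consensus_rows.append({
                        "scheme": scheme, "route": route, "mode": mode_label,
                        "feature": str(fid), "folds_selected": freq,
                    })
    out = run_dir / "results.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    if consensus_rows:
        pd.DataFrame(consensus_rows).to_csv(run_dir / "consensus_features.tsv", sep="\t", index=False)
    _log(run_dir, f"classify: {len(rows)} result rows in {time.time() - t0:.1f} s")
    return out


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, cohort_path: str | Path | None = None
) -> Path:
    """Run every stage; returns the run directory."""
    run_dir = _init_run(config, outdir)
    _log(run_dir, f"run start (mlfc {__version__}, seed {config.seed})")
    cohort = Path(cohort_path) if cohort_path else stage_simulate(config, run_dir)
    if cohort != run_dir / "cohort.h5" and not (run_dir / "cohort.h5").exists():
        # stages below locate the cohort inside the run dir
        import shutil

        shutil.copy(cohort, run_dir / "cohort.h5")
    stage_connect(config, run_dir, run_dir / "cohort.h5")
    stage_omst(config, run_dir)
    stage_mpc(config, run_dir)
    stage_comodulogram(config, run_dir)
    stage_classify(config, run_dir)
    _log(run_dir, "run complete")
    return run_dir
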