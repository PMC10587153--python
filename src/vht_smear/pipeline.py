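"""End-to-end pipeline: synth -> preprocess -> extract -> select -> fuse -> classify.

A single JSON-serialisable :class:`RunConfig` drives every stage; each random
stage carries an explicit seed, so a rerun with an identical config rewrites
byte-identical artifacts (manifests, feature tables, selection JSON and the
final report).  Stage timings go to a separate log file so they never touch
the reproducible artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Tuple

import pandas as pd

from . import aco, classify, deep, features, preprocess, synth


@dataclass
class RunConfig:
    """Declarative configuration of one full pipeline run."""

    source: str = "synthetic"            # synthetic | directory
    n_per_class: int = 150               # synthetic source size
    root: str | None = None              # directory source
    side: int = 200
    target_per_class: int | None = None  # balance-by-augmentation target
    vht_grid: int = 4
    deep_dim: int = 4096
    deep_seed: int = 0
    data_seed: int = 0
    aco_params: dict = field(default_factory=dict)
    fusion_grid: List[Tuple[int, int]] = field(default_factory=lambda: [(100, 100)])
    variants: List[str] = field(default_factory=lambda: ["cubic-svm"])
    split_seed: int = 0
    out_dir: str = "run"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["fusion_grid"] = [tuple(p) for p in d.get("fusion_grid", [])]
        return cls(**d)


def _stage(log, name, t0):
    log.append(f"{name}: {time.perf_counter() - t0:.2f}s")


def run(config: RunConfig) -> dict:
    """Execute every stage in order; return the (JSON-serialisable) report.

    Artifacts written under ``config.out_dir``: images + ``manifest.csv``,
    ``vht.csv``, ``deep.csv``, ``selected.json``, ``report.csv``,
    ``report.json`` and a non-reproducible ``run.log`` with stage timings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: List[str] = []

    # --- data ---
    t0 = time.perf_counter()
    if config.source == "synthetic":
        cfg = synth.GeneratorConfig(image_size=config.side, seed=config.data_seed)
        manifest = synth.generate_dataset(config.n_per_class, cfg, out / "images")
    elif config.source == "directory":
        root = Path(config.root or "")
        rows = []
        for cdir in sorted(p for p in root.iterdir() if p.is_dir()):
            for img in sorted(cdir.glob("*.png")) + sorted(cdir.glob("*.jpg")):
                rows.append({"path": str(img), "label": cdir.name,
                             "provenance": "real"})
        if not rows:
            raise RuntimeError(f"stage 'manifest' failed: no images under {root}")
        manifest = pd.DataFrame(rows, columns=["path", "label", "provenance"])
    else:
        raise RuntimeError(f"stage 'manifest' failed: unknown source {config.source!r}")
    _stage(log, "data", t0)

    # --- preprocess / augmentation balance ---
    t0 = time.perf_counter()
    if config.target_per_class is not None:
        manifest = preprocess.balance_dataset(
            manifest, config.target_per_class, seed=config.data_seed,
            out_dir=out / "images")
    manifest.to_csv(out / "manifest.csv", index=False)
    _stage(log, "preprocess", t0)

    # --- feature extraction ---
    t0 = time.perf_counter()
    vht_table = features.extract_manifest(manifest, grid=config.vht_grid,
                                          side=config.side)
    vht_table.to_csv(out / "vht.csv", index=False)
    _stage(log, "vht_extract", t0)

    t0 = time.perf_counter()
    backend = deep.surrogate_backend(seed=config.deep_seed, dim=config.deep_dim)
    deep_table = deep.featurize(manifest, backend, side=config.side)
    deep_table.to_csv(out / "deep.csv", index=False)
    _stage(log, "deep_extract", t0)

    # --- selection + fusion + classification ---
    t0 = time.perf_counter()
    y = manifest["label"].to_numpy()
    feat_cols_d = [c for c in deep_table.columns if c.startswith("deep_")]
    feat_cols_v = [c for c in vht_table.columns if c.startswith("vht_")]
    selectors: List[aco.AntColonySelector] = []
    report_df = classify.run_fusion_grid(
        deep_table[feat_cols_d], vht_table[feat_cols_v], y,
        grid=config.fusion_grid, variants=config.variants,
        seed=config.split_seed, aco_params=config.aco_params,
        selectors_out=selectors)
    report_df.to_csv(out / "report.csv", index=False)
    _stage(log, "fuse_classify", t0)

    if selectors:
        sel = selectors[0]
        selection = {"indices": [int(i) for i in sel.support_],
                     "fitness_history": sel.fitness_history_}
        best_fitness = sel.state_.best_fitness
    else:
        selection, best_fitness = {"indices": [], "fitness_history": []}, None
    (out / "selected.json").write_text(json.dumps(selection, indent=2))

    report = {
        "config": json.loads(RunConfig.to_json(config)),
        "n_images": int(len(manifest)),
        "results": report_df.to_dict(orient="records"),
        "selected_fitness": best_fitness,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return report
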