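"""End-to-end workflow orchestration.

Stage order follows the analysis workflow: raw (or simulated) runs ->
COW alignment -> optional baseline subtraction -> interval-wise PARAFAC2
per derivatization channel -> channel concatenation into one feature
table -> creatinine normalization -> log10 + autoscale -> VIP selection ->
GA selection -> PLS-DA with repeated double cross-validation -> report.
Each stage writes its artifacts before the next starts and is recorded in
a run manifest (seeds, wall times, output hashes) sufficient for replay.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chrom_io
from .alignment import align_tensor, subtract_baseline
from .chemometrics import (
    ga_select,
    log10_autoscale,
    repeated_double_cv,
    roc_auc,
    selectivity_ratio,
    sr_tiers,
    vip_select,
)
from .chemometrics.plsda import fit_plsda
from .datatypes import FeatureTable, ThreeWayArray
from .parafac2 import (
    creatinine_normalize,
    deconvolve_tensor,
    propose_intervals,
    read_intervals,
)
from .synthetic import make_dataset

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "expression_direction"]

DEFAULTS: dict = {
    "mode": "synthetic",
    "seed": 0,
    "out_dir": "pipeline_out",
    "channels": [
        {"tag": "TMS", "n_samples": 40, "n_rt": 300, "n_mz": 80, "R": 12,
         "shift_max": 3, "snr_db": 25.0, "baseline_amplitude": 0.0,
         "elution_mode": "shifted_gaussian"},
    ],
    "align": {"enabled": True, "segment_len": 40, "slack": 5, "reference": "median_tic"},
    "baseline": {"enabled": False, "method": "asls"},
    "intervals": {"file": None, "auto": True, "R_default": 3},
    "parafac2": {"max_iter": 10000, "tol": 1.0e-8, "n_starts": 3},
    "preprocess": {"pseudo": None},
    "selection": {
        "vip_threshold": 1.0,
        "ga": {"enabled": True, "pop_size": 64, "n_generations": 100,
               "crossover_rate": 0.8, "mutation_rate": 0.01},
    },
    "dcv": {"outer_k": 5, "inner_k": 5, "n_repetitions": 30, "threshold": 0.5},
    "report": {"equivalence_band": 0.1},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see DEFAULTS for the schema)."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = _merge(DEFAULTS, self.raw)
        self.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.raw[key]

    def validate(self) -> None:
        c = self.raw
        if c["mode"] not in {"synthetic", "cdf"}:
            raise ValueError(f"unknown mode {c['mode']!r}")
        if not c["channels"]:
            raise ValueError("at least one channel must be configured")
        al = c["align"]
        if al["enabled"] and not (0 <= al["slack"] < al["segment_len"]):
            raise ValueError("alignment requires 0 <= slack < segment_len")
        iv = c["intervals"]
        if iv["file"] is None and not iv["auto"]:
            raise ValueError(
                "deconvolution needs an interval file or intervals.auto=true"
            )
        if iv["file"] is not None and not Path(iv["file"]).exists():
            raise ValueError(f"interval file {iv['file']} does not exist")
        if c["mode"] == "cdf":
            for ch in c["channels"]:
                if "path" not in ch or not Path(ch["path"]).exists():
                    raise ValueError(
                        f"channel {ch.get('tag')} needs an existing 'path' of .CDF files"
                    )
        d = c["dcv"]
        if d["outer_k"] < 2 or d["inner_k"] < 2:
            raise ValueError("dcv fold counts must be >= 2")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_channel(ch: dict, cfg: PipelineConfig, seed: int):
    if cfg["mode"] == "synthetic":
        ds = make_dataset(
            n_samples=ch.get("n_samples", 40),
            n_rt=ch.get("n_rt", 300),
            n_mz=ch.get("n_mz", 80),
            R=ch.get("R", 12),
            mode=ch.get("elution_mode", "shifted_gaussian"),
            shift_max=ch.get("shift_max", 3),
            snr_db=ch.get("snr_db"),
            baseline_amplitude=ch.get("baseline_amplitude", 0.0),
            seed=seed,
            channel_tag=ch.get("tag", "TMS"),
        )
        return ds.tensor, ds.creatinine, ds.truth.class_labels, ds
    runs = [chrom_io.read_cdf_run(p) for p in sorted(Path(ch["path"]).glob("*.cdf"))]
    if not runs:
        runs = [chrom_io.read_cdf_run(p) for p in sorted(Path(ch["path"]).glob("*.CDF"))]
    tensor = chrom_io.bin_to_tensor(
        runs, ch.get("mz_lo", 40), ch.get("mz_hi", 650), channel_tag=ch.get("tag", "TMS")
    )
    meta = pd.read_csv(ch["metadata"]) if "metadata" in ch else None
    if meta is None:
        raise ValueError("cdf mode needs per-channel 'metadata' CSV (class, creatinine)")
    return tensor, meta["creatinine"].values, meta["class"].values, None


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute every stage; returns the run manifest (also written to disk)."""
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"config": cfg.raw, "stages": [], "seed": seed}

    def record(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": {str(f): _sha256(f) for f in files if f.exists()},
            }
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    # -- load / simulate + align + deconvolve per channel ------------------
    tables = []
    labels = creatinine = None
    for i, ch in enumerate(cfg["channels"]):
        tag = ch.get("tag", f"CH{i}")
        t0 = time.perf_counter()
        tensor, creat, y, _ds = _load_channel(ch, cfg, seed + i)
        creatinine, labels = creat, np.asarray(y)
        record(f"load[{tag}]", t0, [])

        if cfg["align"]["enabled"]:
            t0 = time.perf_counter()
            tensor, _paths = align_tensor(
                tensor,
                reference_rule=cfg["align"]["reference"],
                segment_len=cfg["align"]["segment_len"],
                slack=cfg["align"]["slack"],
            )
            record(f"align[{tag}]", t0, [])

        if cfg["baseline"]["enabled"]:
            t0 = time.perf_counter()
            tensor = subtract_baseline(tensor, method=cfg["baseline"]["method"])
            record(f"baseline[{tag}]", t0, [])

        t0 = time.perf_counter()
        if cfg["intervals"]["file"]:
            intervals = [
                iv for iv in read_intervals(cfg["intervals"]["file"])
                if iv.channel_tag == tag
            ]
        else:
            intervals = propose_intervals(tensor, r_hint=cfg["intervals"]["R_default"])
        table, _models = deconvolve_tensor(
            tensor,
            intervals,
            R_default=cfg["intervals"]["R_default"],
            creatinine=creat,
            max_iter=cfg["parafac2"]["max_iter"],
            tol=cfg["parafac2"]["tol"],
            seed=seed,
            n_starts=cfg["parafac2"]["n_starts"],
        )
        path = out / f"features_{tag}.csv"
        chrom_io.write_feature_table(table, path)
        record(f"deconvolve[{tag}]", t0, [path])
        tables.append(table)

    # -- merge channels (column concatenation, channel-tagged names) -------
    t0 = time.perf_counter()
    values = pd.concat([t.values for t in tables], axis=1)
    prov = pd.concat([t.provenance for t in tables], axis=0)
    table = FeatureTable(
        values=values, provenance=prov,
        creatinine=pd.Series(creatinine, index=values.index),
    )
    table = creatinine_normalize(table)
    merged_path = out / "features_merged.csv"
    chrom_io.write_feature_table(table, merged_path)
    record("merge+creatinine", t0, [merged_path])

    # -- preprocessing ------------------------------------------------------
    t0 = time.perf_counter()
    Z, scal = log10_autoscale(table, pseudo=cfg["preprocess"]["pseudo"])
    y = np.asarray(labels).astype(int)
    record("log10_autoscale", t0, [])

    # -- selection ----------------------------------------------------------
    t0 = time.perf_counter()
    vip = vip_select(Z, y, threshold=cfg["selection"]["vip_threshold"], seed=seed)
    Zv = Z[:, vip.selected]
    ga_cfg = cfg["selection"]["ga"]
    if ga_cfg["enabled"] and Zv.shape[1] >= 2:
        ga = ga_select(
            Zv, y,
            pop_size=ga_cfg["pop_size"],
            n_generations=ga_cfg["n_generations"],
            crossover_rate=ga_cfg["crossover_rate"],
            mutation_rate=ga_cfg["mutation_rate"],
            seed=seed,
        )
        final_idx = vip.selected[ga.selected]
        n_ga_discarded = int(len(vip.selected) - len(ga.selected))
    else:
        final_idx = vip.selected
        n_ga_discarded = 0
    sel_path = out / "selection.json"
    chrom_io.write_json_summary(
        {
            "n_input_variables": int(Z.shape[1]),
            "n_vip_selected": int(len(vip.selected)),
            "n_ga_discarded": n_ga_discarded,
            "n_final": int(len(final_idx)),
            "vip_scores": vip.trace["vip"],
            "final_variables": [scal["kept_columns"][j] for j in final_idx],
        },
        sel_path,
    )
    record("selection", t0, [sel_path])

    # -- classification ------------------------------------------------------
    t0 = time.perf_counter()
    d = cfg["dcv"]
    dcv = repeated_double_cv(
        Z[:, final_idx], y,
        outer_k=d["outer_k"], inner_k=d["inner_k"],
        n_repetitions=d["n_repetitions"], threshold=d["threshold"], seed=seed,
    )
    dcv_path = out / "dcv_summary.json"
    chrom_io.write_json_summary(dcv.summary(), dcv_path)
    pred_path = out / "cv_predictions.csv"
    pd.DataFrame(
        dcv.predictions.T, index=values.index,
        columns=[f"rep{r}" for r in range(dcv.predictions.shape[0])],
    ).to_csv(pred_path, index_label="sample_id")
    record("dcv", t0, [dcv_path, pred_path])

    # -- report --------------------------------------------------------------
    t0 = time.perf_counter()
    report_files = make_report(
        out_dir=out,
        Z=Z,
        y=y,
        final_idx=final_idx,
        variable_names=scal["kept_columns"],
        dcv=dcv,
        equivalence_band=cfg["report"]["equivalence_band"],
        seed=seed,
    )
    record("report", t0, report_files)
    manifest["final_variables"] = [scal["kept_columns"][j] for j in final_idx]
    manifest["dcv_summary"] = dcv.summary()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def expression_direction(
    Z: np.ndarray, y: np.ndarray, equivalence_band: float = 0.1
) -> list[str]:
    """Call each variable over/under/comparable in the positive class.

    Uses the class-mean difference of the autoscaled log values; absolute
    standardized differences below ``equivalence_band`` (in sd units) are
    called comparable.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y).astype(int)
    diff = Z[y == 1].mean(axis=0) - Z[y == 0].mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    std_diff = diff / np.where(sd > 0, sd, 1.0)
    return [
        "comparable" if abs(d) < equivalence_band
        else ("overexpression" if d > 0 else "underexpression")
        for d in std_diff
    ]


def make_report(
    out_dir: str | Path,
    Z: np.ndarray,
    y: np.ndarray,
    final_idx: np.ndarray,
    variable_names: list[str],
    dcv,
    equivalence_band: float = 0.1,
    seed: int = 0,
) -> list[Path]:
    """Write the human-readable summary and the four standard plots.

    The document reports dCV sensitivity/specificity (mean +/- sd), AUC,
    the selected-variable table with expression direction, and plots:
    CV-predicted Y scatter, ROC curve, selectivity-ratio bars, and
    boxplots of the top-tier variables.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    final_idx = np.asarray(final_idx, dtype=int)
    s = dcv.summary()

    lines = [
        "# Classification report",
        "",
        f"- sensitivity: {100 * s['sensitivity_mean']:.1f} +/- {100 * s['sensitivity_sd']:.1f} %",
        f"- specificity: {100 * s['specificity_mean']:.1f} +/- {100 * s['specificity_sd']:.1f} %",
        f"- AUC (CV): {s['auc_mean']:.3f} +/- {s['auc_sd']:.3f}",
        f"- misclassified per repetition: {s['misclassified_pos_mean']:.1f} positive, "
        f"{s['misclassified_neg_mean']:.1f} negative",
        "",
    ]

    if final_idx.size == 0:
        lines += ["## Selected variables", "", "No variables selected."]
        report = out / "report.md"
        report.write_text("\n".join(lines) + "\n")
        return [report]

    Zf = Z[:, final_idx]
    names = [variable_names[j] for j in final_idx]
    direction = expression_direction(Zf, y, equivalence_band)

    model = fit_plsda(Zf, y.astype(float), min(3, Zf.shape[1], len(y) - 1), scale=True)
    sr = selectivity_ratio(model, Zf)
    tiers = sr_tiers(sr)

    lines += ["## Selected variables", "",
              "| variable | expression in positive class | selectivity ratio |",
              "|---|---|---|"]
    for j, (name, d) in enumerate(zip(names, direction)):
        lines.append(f"| {name} | {d} | {sr[j]:.3f} |")
    lines += [
        "",
        f"Variables with SR > 0.1: {len(tiers['strong'])}; "
        f"between 0.07 and 0.1: {len(tiers['moderate'])}.",
    ]
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    files.append(report)

    rep0 = dcv.predictions[0]
    fig, ax = plt.subplots(figsize=(6, 4))
    jitter = np.linspace(0, 1, len(rep0))
    for cls, color in ((0, "tab:blue"), (1, "tab:red")):
        m = y == cls
        ax.scatter(jitter[m], rep0[m], c=color, label=f"class {cls}", s=18)
    ax.axhline(dcv.threshold, ls="--", c="k", lw=1)
    ax.set_ylabel("CV-predicted Y")
    ax.set_xlabel("sample")
    ax.legend()
    fig.tight_layout()
    f = out / "cv_predictions.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    files.append(f)

    pts, auc = roc_auc(rep0, y)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(pts[:, 0], pts[:, 1], "-o", ms=2)
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC (one repetition), AUC = {auc:.3f}")
    fig.tight_layout()
    f = out / "roc.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    files.append(f)

    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(sr)), 4))
    order = np.argsort(-sr)
    colors = ["tab:green" if sr[j] > 0.1 else ("tab:red" if sr[j] > 0.07 else "0.6")
              for j in order]
    ax.bar(range(len(sr)), sr[order], color=colors)
    ax.axhline(0.1, c="tab:green", ls="--", lw=1)
    ax.axhline(0.07, c="tab:red", ls="--", lw=1)
    ax.set_xticks(range(len(sr)))
    ax.set_xticklabels([names[j] for j in order], rotation=90, fontsize=6)
    ax.set_ylabel("selectivity ratio")
    fig.tight_layout()
    f = out / "selectivity_ratio.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    files.append(f)

    top = [int(j) for j in order if sr[j] > 0.07][:14] or [int(order[0])]
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(top)), 4))
    data, positions, labels_x = [], [], []
    for i, j in enumerate(top):
        data += [Zf[y == 0, j], Zf[y == 1, j]]
        positions += [3 * i, 3 * i + 1]
        labels_x.append(names[j])
    bp = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
    for i, box in enumerate(bp["boxes"]):
        box.set_facecolor("tab:blue" if i % 2 == 0 else "tab:red")
    ax.set_xticks([3 * i + 0.5 for i in range(len(top))])
    ax.set_xticklabels(labels_x, rotation=90, fontsize=6)
    ax.set_ylabel("autoscaled log10 value")
    fig.tight_layout()
    f = out / "boxplots.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    files.append(f)
    return files
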