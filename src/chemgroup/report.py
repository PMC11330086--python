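"""Result bundles, figures, and the three running modes over the manifest.

:func:`write_results` renders a finished manifest into a downloadable
bundle: the manifest JSON, a parameters CSV, the grouping-results CSV
(record id, SMILES, 2-D coordinates, cluster), the descriptor CSV, the
removed-rows CSV, SVG figures (cluster scatter, shape-coded by activity
label when present; per-cluster SHAP strip plots), a Markdown summary, and
an index with checksums. Output is byte-stable: fixed float formatting,
sorted keys, and a fixed SVG hash salt.

:func:`replay_from_manifest` implements "New Analysis with Prior
Configuration" (rerun: reuse every option, hyperparameter, and seed, skip
the search stages in favor of stored selected values) and "View Past
Results" (re-render with zero recomputation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from chemgroup.dataio import Dataset, RunManifest, save_manifest
from chemgroup.pipeline import PipelineConfig, run_pipeline

FLOAT_FMT = "%.6g"

matplotlib.rcParams["svg.hashsalt"] = "chemgroup"


@dataclass
class ReportBundle:
    outdir: Path
    files: dict[str, Path]  # bundle-relative name -> path
    index_path: Path


def _fmt(x: float) -> str:
    return FLOAT_FMT % float(x)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _savefig(fig, path: Path) -> None:
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def _scatter_figure(stage: dict) -> "plt.Figure":
    emb = np.asarray(stage["embedding"], dtype=float)
    labels = np.asarray(stage["labels"], dtype=int)
    activity = stage.get("activity_labels")
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("tab10")
    for c in sorted(set(labels.tolist())):
        m = labels == c
        color = "lightgray" if c == -1 else cmap(c % 10)
        name = "noise" if c == -1 else f"cluster {c}"
        if activity is not None:
            act = np.asarray(activity)
            # activity encoded by marker shape: dots vs x-shaped points
            for val, marker in zip(sorted(set(act.tolist())), ["o", "x", "s", "^", "D"]):
                mm = m & (act == val)
                if mm.any():
                    ax.scatter(
                        emb[mm, 0], emb[mm, 1], c=[color], marker=marker, s=18,
                        label=f"{name}, label {val}" if c != -1 else None,
                    )
        else:
            ax.scatter(emb[m, 0], emb[m, 1], c=[color], s=18, label=name)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend(fontsize=6, loc="best")
    ax.set_title("Grouping results (2-D projection)")
    fig.tight_layout()
    return fig


def _shap_figure(cluster: str, ranks: list, dists: dict) -> "plt.Figure":
    fig, ax = plt.subplots(figsize=(6, 4))
    names = [r[0] for r in ranks[: len(dists)] if r[0] in dists]
    for i, name in enumerate(reversed(names)):
        vals = np.asarray(dists[name], dtype=float)
        ax.scatter(vals, np.full(len(vals), i), s=8, alpha=0.6)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_yticks(range(len(names)))
    ax.set_yticklabels(list(reversed(names)), fontsize=7)
    ax.set_xlabel("SHAP value (one-vs-rest)")
    ax.set_title(f"Cluster {cluster}: top descriptor attributions")
    fig.tight_layout()
    return fig


def write_results(manifest: RunManifest, outdir: str | Path) -> ReportBundle:
    """Write the full result bundle for a finished manifest.

    Re-running on the same manifest overwrites byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "figures").mkdir(exist_ok=True)
    files: dict[str, Path] = {}

    def add(name: str, path: Path) -> None:
        files[name] = path

    # manifest
    mpath = outdir / "manifest.json"
    save_manifest(manifest, mpath)
    add("manifest.json", mpath)

    # parameters CSV
    rows = []
    cfg = manifest.options.get("config", {})
    for k in sorted(cfg):
        rows.append(("config." + k, json.dumps(cfg[k], sort_keys=True)))
    for k in sorted(manifest.seeds):
        rows.append(("seed." + k, str(manifest.seeds[k])))
    ppath = outdir / "parameters.csv"
    pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(ppath, index=False)
    add("parameters.csv", ppath)

    # removed rows CSV
    removed = []
    for stage in ("input", "standardize"):
        if manifest.has_stage(stage):
            removed.extend(manifest.get_stage(stage).get("removed_rows", []))
    rpath = outdir / "removed_rows.csv"
    pd.DataFrame(removed, columns=["source_index", "reason"]).to_csv(rpath, index=False)
    add("removed_rows.csv", rpath)

    # descriptors CSV
    feat = manifest.get_stage("features")
    dpath = outdir / "descriptors.csv"
    df = pd.DataFrame(
        np.asarray(feat["values"], dtype=float), columns=feat["column_names"]
    )
    df.insert(0, "row_id", feat["row_ids"])
    df.to_csv(dpath, index=False, float_format=FLOAT_FMT)
    add("descriptors.csv", dpath)

    # grouping results CSV
    grp = manifest.get_stage("grouping")
    emb = np.asarray(grp["embedding"], dtype=float)
    gpath = outdir / "grouping_results.csv"
    pd.DataFrame(
        {
            "record_id": feat["row_ids"],
            "smiles": feat["smiles"],
            "x": emb[:, 0],
            "y": emb[:, 1],
            "cluster": np.asarray(grp["labels"], dtype=int),
        }
    ).to_csv(gpath, index=False, float_format=FLOAT_FMT)
    add("grouping_results.csv", gpath)

    # figures
    spath = outdir / "figures" / "scatter.svg"
    _savefig(_scatter_figure(grp), spath)
    add("figures/scatter.svg", spath)
    if manifest.has_stage("interpretation"):
        interp = manifest.get_stage("interpretation")
        for cluster, ranks in sorted(interp["rankings"].items()):
            fpath = outdir / "figures" / f"shap_cluster_{cluster}.svg"
            _savefig(
                _shap_figure(cluster, ranks, interp["distributions"][cluster]), fpath
            )
            add(f"figures/shap_cluster_{cluster}.svg", fpath)

    # summary markdown
    lines = ["# Chemical grouping report", ""]
    inp = manifest.get_stage("input")
    lines.append(
        f"Input: {inp['n_input']} records; {inp['n_retained']} retained, "
        f"{inp['n_unreadable']} unreadable, {inp['n_missing']} missing values."
    )
    if inp.get("class_counts"):
        lines.append(f"Class counts: {json.dumps(inp['class_counts'], sort_keys=True)}.")
    lines.append(
        f"Features: {feat['descriptor'].get('type')} "
        f"({len(feat['column_names'])} columns after filtering/selection stages "
        f"recorded in the manifest), scaling = {feat['scaling']}."
    )
    n_clusters = len({c for c in np.asarray(grp["labels"]).tolist() if c != -1})
    sil = grp["silhouette"]
    lines.append(
        f"Grouping: {grp['config']['cluster_method']} on "
        f"{grp['config']['projection_method']} "
        f"({'projected' if grp['config'].get('projected') else 'two-stage'}); "
        f"{n_clusters} clusters; silhouette = {_fmt(sil)}."
    )
    if manifest.has_stage("interpretation"):
        lines += ["", "## Interpretation", "", manifest.get_stage("interpretation")["summary"]]
    spath_md = outdir / "summary.md"
    spath_md.write_text("\n".join(lines) + "\n")
    add("summary.md", spath_md)

    # index with checksums
    index_path = outdir / "index.json"
    index = {name: _sha256(path) for name, path in sorted(files.items())}
    index_path.write_text(json.dumps(index, indent=2, sort_keys=True) + "\n")

    return ReportBundle(outdir=outdir, files=files, index_path=index_path)


def replay_from_manifest(
    manifest: RunManifest, new_dataset: Dataset | str | Path | None = None
) -> RunManifest:
    """Replay a finished run.

    With ``new_dataset`` (rerun mode) every option, hyperparameter, and
    seed is reused and the search stages are skipped in favor of the stored
    selected values; a new results manifest is returned. Without it (view
    mode) the stored manifest is returned unchanged for re-rendering, with
    zero recomputation.
    """
    for required in ("input", "features", "grouping"):
        if not manifest.has_stage(required):
            raise ValueError(f"manifest missing stage {required!r} required for replay")

    if new_dataset is None:
        return manifest  # view mode: nothing recomputed

    config = PipelineConfig.from_dict(manifest.options["config"])
    grouping_cfg = dict(manifest.get_stage("grouping")["config"])
    supervised = (
        grouping_cfg.get("shap_based")
        or config.selection_method != "none"
        or config.variance_filter_mode == "auto"
        or config.correlation_filter_mode == "auto"
    )
    if supervised and isinstance(new_dataset, Dataset) and new_dataset.label_kind == "none":
        raise ValueError(
            "manifest records a supervised run but the new dataset has no labels"
        )

    overrides: dict = {"grouping_config": grouping_cfg}
    for f in manifest.get_stage("filter").get("filters", []):
        if f["method"] == "variance":
            overrides["variance_threshold"] = f["threshold"]
        else:
            overrides["correlation_threshold"] = f["threshold"]
    if manifest.has_stage("selection"):
        overrides["selected_columns"] = manifest.get_stage("selection")["selected_columns"]

    return run_pipeline(new_dataset, config, overrides=overrides)
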