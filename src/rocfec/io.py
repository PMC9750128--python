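"""Readers and writers for the package's tabular formats.

Score tables, ROC curve CSV/JSON, digitized-curve CSV (as produced by
curve-tracing software), GMT gene sets, edge lists and dense weight
matrices, and FEC result tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .egad import AnnotationMatrix, WeightedNetwork
from .fec import FEC
from .roc import RocCurve, ScoredLabels

__all__ = [
    "read_scored_labels",
    "write_scored_labels",
    "read_curve_csv",
    "write_curve_csv",
    "read_curve_json",
    "write_curve_json",
    "read_digitized_curve",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_dense_matrix",
    "write_dense_matrix",
    "fecs_to_frame",
    "write_fecs",
    "write_manifest",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    # sniff comma vs tab
    return pd.read_csv(path, sep=None, engine="python")


def read_scored_labels(path: str | Path) -> ScoredLabels:
    """Read an `id, score, label` table (comma- or tab-separated, header)."""
    df = _read_table(path)
    missing = {"id", "score", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return ScoredLabels(df["id"].astype(str).tolist(),
                        df["score"].to_numpy(float),
                        df["label"].to_numpy(int))


def write_scored_labels(data: ScoredLabels, path: str | Path) -> None:
    pd.DataFrame({"id": data.ids, "score": data.scores, "label": data.labels}).to_csv(
        path, sep="\t", index=False
    )


def write_curve_csv(curve: RocCurve, path: str | Path) -> None:
    pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr}).to_csv(path, index=False)


def read_curve_csv(path: str | Path, n_pos: int = 100, n_neg: int = 100) -> RocCurve:
    """Read a strict two-column `fpr,tpr` CSV written by ``write_curve_csv``."""
    df = pd.read_csv(path)
    return RocCurve(df[["fpr", "tpr"]].to_numpy(float), n_pos, n_neg, {"source": str(path)})


def write_curve_json(curve: RocCurve, path: str | Path) -> None:
    payload = {
        "points": curve.points.tolist(),
        "n_pos": curve.n_pos,
        "n_neg": curve.n_neg,
        "meta": curve.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_curve_json(path: str | Path) -> RocCurve:
    payload = json.loads(Path(path).read_text())
    return RocCurve(np.asarray(payload["points"]), payload["n_pos"],
                    payload["n_neg"], payload.get("meta", {}))


def read_digitized_curve(
    path: str | Path,
    n_pos: int = 100,
    n_neg: int = 100,
    repair: Optional[str] = None,
) -> RocCurve:
    """Read a digitized ROC curve from a two-column x,y CSV.

    Points are sorted by x and clamped to [0, 1]; (0, 0) and (1, 1) are
    appended when absent (recorded in meta).  Decreasing y values — a
    common digitization artifact — raise a parse error unless
    ``repair="isotonic"`` is passed, which replaces y by its running
    maximum; automatic repair is opt-in because silently straightening a
    curve biases the KS statistics computed from it.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace("\t", ",").split(",")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if ln == 1:  # header line
                    continue
                raise ValueError(f"{path}:{ln}: non-numeric value") from None
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least two points")
    pts = np.asarray(sorted(rows), dtype=float)
    if pts.min() < -0.05 or pts.max() > 1.05:
        raise ValueError(f"{path}: coordinates far outside [0, 1]")
    pts = np.clip(pts, 0.0, 1.0)
    meta: dict = {"source": str(path)}
    if np.any(np.diff(pts[:, 1]) < 0):
        if repair == "isotonic":
            pts[:, 1] = np.maximum.accumulate(pts[:, 1])
            meta["repaired"] = "isotonic"
        else:
            ln = int(np.flatnonzero(np.diff(pts[:, 1]) < 0)[0]) + 2
            raise ValueError(
                f"{path}: tpr decreases near sorted point {ln}; "
                "pass repair='isotonic' to repair explicitly"
            )
    if pts[0, 0] > 0 or pts[0, 1] > 0:
        pts = np.vstack(([0.0, 0.0], pts))
        meta["prepended_origin"] = True
    if pts[-1, 0] < 1 or pts[-1, 1] < 1:
        pts = np.vstack((pts, [1.0, 1.0]))
        meta["appended_unit"] = True
    return RocCurve(pts, n_pos, n_neg, meta)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def annotation_matrix_from_gmt(
    sets: dict[str, list[str]], gene_ids: list[str]
) -> AnnotationMatrix:
    index = {g: i for i, g in enumerate(gene_ids)}
    names = list(sets)
    ind = np.zeros((len(gene_ids), len(names)), dtype=int)
    for j, name in enumerate(names):
        for g in sets[name]:
            if g in index:
                ind[index[g], j] = 1
    return AnnotationMatrix(gene_ids, names, ind)


def read_edge_list(path: str | Path) -> WeightedNetwork:
    """Read a `gene_a, gene_b[, weight]` edge list into a symmetric matrix."""
    df = _read_table(path)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError(f"{path}: need columns gene_a, gene_b")
    genes = sorted(set(df["gene_a"].astype(str)) | set(df["gene_b"].astype(str)))
    index = {g: i for i, g in enumerate(genes)}
    w = np.zeros((len(genes), len(genes)))
    weights = df["weight"].to_numpy(float) if "weight" in df.columns else np.ones(len(df))
    for a, b, v in zip(df["gene_a"].astype(str), df["gene_b"].astype(str), weights):
        i, j = index[a], index[b]
        w[i, j] = w[j, i] = v
    return WeightedNetwork(genes, w)


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    ii, jj = np.nonzero(np.triu(net.weights))
    pd.DataFrame({
        "gene_a": [net.gene_ids[i] for i in ii],
        "gene_b": [net.gene_ids[j] for j in jj],
        "weight": net.weights[ii, jj],
    }).to_csv(path, sep="\t", index=False)


def read_dense_matrix(path: str | Path) -> WeightedNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return WeightedNetwork([str(g) for g in df.index], df.to_numpy(float))


def write_dense_matrix(net: WeightedNetwork, path: str | Path) -> None:
    pd.DataFrame(net.weights, index=net.gene_ids, columns=net.gene_ids).to_csv(path, sep="\t")


def fecs_to_frame(fecs: list[FEC]) -> pd.DataFrame:
    rows = []
    for f in fecs:
        (f0, t0), (f1, t1) = f.subcurve.start, f.subcurve.end
        rows.append({
            "fpr0": f0, "tpr0": t0, "fpr1": f1, "tpr1": t1,
            "ks_raw": f.ks_raw, "n_sub": f.n_sub, "ks_norm": f.ks_norm,
            "p_value": f.p_value, "fpr_span": f.fpr_span,
            "tpr_span": f.tpr_span, "slope": f.slope,
        })
    cols = ["fpr0", "tpr0", "fpr1", "tpr1", "ks_raw", "n_sub", "ks_norm",
            "p_value", "fpr_span", "tpr_span", "slope"]
    return pd.DataFrame(rows, columns=cols)


def write_fecs(fecs: list[FEC], path: str | Path) -> None:
    path = Path(path)
    df = fecs_to_frame(fecs)
    if path.suffix == ".json":
        path.write_text(df.to_json(orient="records", indent=1))
    else:
        df.to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, **entries) -> None:
    """Write a machine-readable run manifest (inputs, parameters, seed)."""
    import rocfec

    payload = {"rocfec_version": rocfec.__version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
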