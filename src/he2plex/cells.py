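"""Pseudo-cell extraction, random-forest cell typing, joint t-SNE embedding
and immune-phenotype density analysis.

A pseudo-cell is the disk of configurable diameter (10 µm by default)
around a nucleus coordinate; marker expression is the pixel mean over that
disk.  Immune phenotyping quantifies CD8+ T-cell densities inside the
intratumoral and stromal compartments of the tumour centre (iCD8 / sCD8,
counts per µm²) and classifies samples hot vs cold from those densities.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .synthetic import MarkerStack

log = logging.getLogger(__name__)

CELL_CLASSES = ["tumour", "B", "CD8 T", "CD4 T", "other"]


def extract_pseudo_cells(stack: MarkerStack, coords: np.ndarray,
                         diameter_um: float = 10.0) -> pd.DataFrame:
    """Cell table of per-marker disk means around nucleus coordinates.

    `coords` is (n, 2) as (x, y) on the marker grid.  Out-of-bounds centers
    are skipped with a log message; disks are clipped at image borders.
    """
    c, h, w = stack.data.shape
    r_px = (diameter_um / 2.0) / stack.um_per_px
    rows = []
    rad = int(np.ceil(r_px))
    for i, (cx, cy) in enumerate(np.asarray(coords, dtype=float)):
        if not (0 <= cx < w and 0 <= cy < h):
            log.info("cell %d at (%.1f, %.1f) outside image; skipped", i, cx, cy)
            continue
        x0, x1 = max(0, int(np.floor(cx)) - rad), min(w, int(np.ceil(cx)) + rad + 1)
        y0, y1 = max(0, int(np.floor(cy)) - rad), min(h, int(np.ceil(cy)) + rad + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px * r_px
        if not disk.any():
            disk = np.zeros_like(disk)
            disk[int(round(cy)) - y0, int(round(cx)) - x0] = True
        row = {"cell_id": i, "x": cx, "y": cy}
        for m, name in enumerate(stack.channels):
            row[name] = float(stack.data[m, y0:y1, x0:x1][disk].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def disk_pixel_count(diameter_um: float, um_per_px: float = 1.0,
                     cx: float = 0.0, cy: float = 0.0) -> int:
    """Number of grid pixels inside the pseudo-cell disk (for sanity checks)."""
    r = (diameter_um / 2.0) / um_per_px
    rad = int(np.ceil(r))
    yy, xx = np.mgrid[-rad:rad + 1, -rad:rad + 1]
    return int(np.sum((xx - (cx % 1)) ** 2 + (yy - (cy % 1)) ** 2 <= r * r))


# ---------------------------------------------------------------------------
# cell typing
# ---------------------------------------------------------------------------

def train_cell_typer(table: pd.DataFrame, markers: list[str],
                     label_col: str = "type", n_estimators: int = 100,
                     max_depth: int = 30, seed: int = 0
                     ) -> RandomForestClassifier:
    """Random forest on per-cell marker means (100 trees, depth 30)."""
    labels = table[label_col]
    if labels.nunique() < 2:
        raise ValueError("need at least two cell classes to train")
    clf = RandomForestClassifier(n_estimators=n_estimators, max_depth=max_depth,
                                 oob_score=True, random_state=seed)
    clf.fit(table[markers].to_numpy(), labels.to_numpy())
    return clf


def apply_cell_typer(clf: RandomForestClassifier, table: pd.DataFrame,
                     markers: list[str]) -> pd.DataFrame:
    missing = [m for m in markers if m not in table.columns]
    if missing:
        raise ValueError(f"marker columns missing at apply time: {missing}")
    out = table.copy()
    out["predicted_type"] = clf.predict(table[markers].to_numpy())
    return out


# ---------------------------------------------------------------------------
# joint t-SNE
# ---------------------------------------------------------------------------

def joint_tsne(gt_tables: list[pd.DataFrame], gen_tables: list[pd.DataFrame],
               markers: list[str], n_per_roi: int = 1000, perplexity: float = 50,
               n_iter: int = 1000, seed: int = 0
               ) -> tuple[np.ndarray, pd.DataFrame]:
    """Joint 2-D embedding of subsampled GT and generated cells.

    Subsamples up to `n_per_roi` cells per ROI from each source (all cells
    when an ROI has fewer, logged), embeds the concatenation, and returns
    per-marker color values scaled to [0, 1] and clipped at the 99th
    percentile.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for source, tables in (("gt", gt_tables), ("generated", gen_tables)):
        for ri, t in enumerate(tables):
            if len(t) > n_per_roi:
                t = t.iloc[rng.choice(len(t), n_per_roi, replace=False)]
            else:
                log.info("ROI %d (%s): only %d cells available", ri, source, len(t))
            sub = t[markers].copy()
            sub["source"] = source
            sub["roi"] = ri
            frames.append(sub)
    data = pd.concat(frames, ignore_index=True)
    x = data[markers].to_numpy()
    if perplexity >= len(x):
        raise ValueError("perplexity must be smaller than the number of cells")
    init = "pca" if x.shape[1] >= 2 else "random"
    emb = TSNE(n_components=2, perplexity=perplexity, max_iter=n_iter,
               random_state=seed, init=init).fit_transform(x)
    colors = data.copy()
    for m in markers:
        v = data[m].to_numpy(dtype=float)
        cap = np.percentile(v, 99)
        v = np.minimum(v, cap)
        rng_ = v.max() - v.min()
        colors[m] = (v - v.min()) / rng_ if rng_ > 0 else 0.0
    return emb, colors


# ---------------------------------------------------------------------------
# immune phenotyping
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhenotypeDensities:
    icd8: float                  # CD8+ T cells per µm², intratumoral compartment
    scd8: float                  # CD8+ T cells per µm², stromal compartment
    intratumoral_area_um2: float
    stromal_area_um2: float


def phenotype_densities(table: pd.DataFrame, masks: dict,
                        um_per_px: float = 1.0,
                        cd8_label: str = "CD8 T",
                        type_col: str = "predicted_type") -> PhenotypeDensities:
    """iCD8/sCD8 densities inside the tumour-centre compartments.

    A cell belongs to the compartment containing its center pixel
    (half-open grid: center rounded to the nearest pixel index).  Cells in
    `excluded` regions are removed first.  Raises when a compartment has
    zero area (density undefined).
    """
    intr = masks["intratumoral"]
    strm = masks["stromal"]
    excl = masks.get("excluded")
    px_area = um_per_px ** 2
    a_i = float(intr.sum()) * px_area
    a_s = float(strm.sum()) * px_area
    if a_i == 0 or a_s == 0:
        raise ValueError("zero-area compartment: density undefined")
    cd8 = table[table[type_col] == cd8_label]
    xi = np.clip(np.round(cd8["x"].to_numpy()).astype(int), 0, intr.shape[1] - 1)
    yi = np.clip(np.round(cd8["y"].to_numpy()).astype(int), 0, intr.shape[0] - 1)
    if excl is not None and len(xi):
        keep = ~excl[yi, xi]
        xi, yi = xi[keep], yi[keep]
    n_i = int(intr[yi, xi].sum()) if len(xi) else 0
    n_s = int(strm[yi, xi].sum()) if len(xi) else 0
    return PhenotypeDensities(icd8=n_i / a_i, scd8=n_s / a_s,
                              intratumoral_area_um2=a_i, stromal_area_um2=a_s)


def hot_cold_classifier(densities: pd.DataFrame, labels: np.ndarray,
                        n_splits: int = 5, seed: int = 0) -> dict:
    """Random-forest hot/cold classifier on (iCD8, sCD8) with stratified CV.

    Returns per-fold F1 and macro AUROC plus their mean ± sd, and a
    classifier refit on all data.
    """
    x = densities[["icd8", "scd8"]].to_numpy()
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for cross-validation")
    counts = np.bincount(pd.factorize(y)[0])
    if counts.min() < n_splits:
        raise ValueError("a fold would contain a single class; reduce n_splits")
    f1s, aucs = [], []
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for tr, te in skf.split(x, y):
        clf = RandomForestClassifier(n_estimators=100, max_depth=30,
                                     random_state=seed)
        clf.fit(x[tr], y[tr])
        pred = clf.predict(x[te])
        proba = clf.predict_proba(x[te])
        f1s.append(f1_score(y[te], pred, average="weighted"))
        if proba.shape[1] == 2:
            aucs.append(roc_auc_score(y[te], proba[:, 1]))
        else:
            aucs.append(roc_auc_score(y[te], proba, multi_class="ovr",
                                      average="macro"))
    final = RandomForestClassifier(n_estimators=100, max_depth=30,
                                   random_state=seed).fit(x, y)
    return {"f1_mean": float(np.mean(f1s)), "f1_sd": float(np.std(f1s)),
            "auroc_mean": float(np.mean(aucs)), "auroc_sd": float(np.std(aucs)),
            "f1_folds": f1s, "auroc_folds": aucs, "classifier": final}
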