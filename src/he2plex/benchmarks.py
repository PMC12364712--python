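"""Desk-scale end-to-end benchmarks on the synthetic simulator.

Each function generates its own data, runs the relevant pipeline and returns
scalar summaries.  They double as smoke tests (does training move the model
in the right direction?) and as the quantities the acceptance script
reports.  Problem sizes are chosen for a single CPU: 128->32 px patches,
3-marker panel, narrow networks, a few hundred optimizer steps.
"""
from __future__ import annotations

import numpy as np

from . import cells as cells_mod
from . import evaluation, mil, training
from .nn import autograd as ag
from .nn.autograd import Tensor
from .objectives import pyramid_loss
from .synthetic import (CELL_TYPES, TissueSimConfig, simulate_cell_table,
                        simulate_paired_roi, simulate_survival_cohort)

SMOKE_MARKERS = ["MelanA", "CD8a", "HLA-ABC"]
SMOKE_EXPRESSION = np.array([
    [0.9, 0.0, 0.5],
    [0.0, 0.9, 0.6],
    [0.0, 0.0, 0.6],
    [0.0, 0.0, 0.6],
    [0.0, 0.0, 0.5],
    [0.0, 0.0, 0.4],
])


def _smoke_sim_config(seed: int) -> TissueSimConfig:
    return TissueSimConfig(canvas_size=64, n_cells=60,
                           marker_panel=list(SMOKE_MARKERS),
                           expression=SMOKE_EXPRESSION.copy(),
                           tumour_centre_margin_px=4, seed=seed)


def _stack_metrics(gt: np.ndarray, pred: np.ndarray) -> dict:
    msss = [evaluation.ms_ssim(gt[c], pred[c], n_scales=3)
            for c in range(gt.shape[0])]
    with ag.no_grad():
        pl = float(pyramid_loss(Tensor(gt[None]), Tensor(pred[None])).data)
    return {"ms_ssim": float(np.mean(msss)), "pyramid_loss": pl}


def generative_smoke(seed: int = 0, steps: int = 500, n_train: int = 3,
                     n_test: int = 2) -> dict:
    """Train the desk preset and compare held-out metrics vs the untrained
    model (identical initialization)."""
    train_rois = [simulate_paired_roi(_smoke_sim_config(seed + i))[0]
                  for i in range(n_train)]
    test_rois = [simulate_paired_roi(_smoke_sim_config(seed + 1000 + i))[0]
                 for i in range(n_test)]
    cfg = training.desk_config(steps=steps, seed=seed)

    with ag.default_dtype(np.float32):
        untrained, _ = training.build_models(cfg)
    result = training.train(cfg, train_rois)

    def held_out(model):
        agg = {"ms_ssim": [], "pyramid_loss": []}
        for roi in test_rois:
            pred = training.translate(model, roi.he_image)
            m = _stack_metrics(roi.marker_stack.data, pred)
            agg["ms_ssim"].append(m["ms_ssim"])
            agg["pyramid_loss"].append(m["pyramid_loss"])
        return {k: float(np.mean(v)) for k, v in agg.items()}

    before = held_out(untrained)
    after = held_out(result.translator)
    finite = all(np.isfinite(v) for row in result.logs
                 for v in row.values() if v is not None)
    return {"ms_ssim_untrained": before["ms_ssim"],
            "ms_ssim_trained": after["ms_ssim"],
            "pyramid_untrained": before["pyramid_loss"],
            "pyramid_trained": after["pyramid_loss"],
            "all_losses_finite": bool(finite),
            "steps": steps,
            "final_losses": result.logs[-1]}


def colocalization_recovery(seed: int = 0, n_rois: int = 20,
                            n_cells: int = 2000) -> dict:
    """Recover a planted marker co-expression structure from cell tables.

    The population Spearman of each pair is computed from the generative
    model itself by large-sample simulation of the cell-type mixture; the
    per-ROI estimate averaged over ROIs must sit within ±0.05 of it.
    """
    cfg = TissueSimConfig(canvas_size=256, n_cells=n_cells,
                          tumour_centre_margin_px=8, seed=seed)
    markers = cfg.marker_panel
    tables = []
    for i in range(n_rois):
        c = TissueSimConfig(canvas_size=256, n_cells=n_cells,
                            tumour_centre_margin_px=8, seed=seed + i)
        tables.append(simulate_cell_table(c))
    scc_table, mse_self = evaluation.colocalization_scc(
        tables, [t.copy() for t in tables], markers)

    # population oracle: draw cell types from the mixture at large n and
    # read expressions straight from the expression matrix
    rng = np.random.default_rng(seed + 999)
    props = np.array([cfg.cell_type_proportions[t] for t in CELL_TYPES])
    types = rng.choice(len(CELL_TYPES), size=200_000, p=props)
    from scipy.stats import spearmanr
    devs = []
    for _, row in scc_table.iterrows():
        ia = markers.index(row.marker_a)
        ib = markers.index(row.marker_b)
        pop = spearmanr(cfg.expression[types, ia],
                        cfg.expression[types, ib]).statistic
        devs.append(abs(row.scc_gt - pop))
    return {"max_abs_scc_deviation": float(np.max(devs)),
            "mse_gt_vs_gt": float(mse_self),
            "n_pairs": int(len(scc_table)),
            "n_retained": int(scc_table.retained.sum())}


# disjoint marker support per cell type: the separable condition under which
# the typer is benchmarked (rows: tumour, CD8 T, CD4 T, B, endothelial, other)
SEPARABLE_EXPRESSION = np.array([
    # MelanA S100 gp100 SOX10 CD3 CD8a CD20 CD16 CD31 HLA-ABC HLA-DR
    [0.9, 0.8, 0.8, 0.9, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 0.9, 0.9, 0.0, 0.0, 0.0, 0.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 0.9, 0.0, 0.0, 0.0, 0.0, 0.6, 0.0],
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.9, 0.0, 0.0, 0.0, 0.7],
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.9, 0.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.7, 0.0, 0.3, 0.3],
])


def cell_typing_benchmark(seed: int = 0, n_cells: int = 800,
                          noise_sd: float = 0.1) -> dict:
    """Macro-F1 of the random-forest typer under separable profiles.

    Cell-level marker profiles come from the simulator's planted expression
    matrix (disjoint marker support per class) plus Gaussian measurement
    noise; train and test are independent cohorts.  A second, harder number
    is also reported: typing from pseudo-cell disk means on rendered images,
    where overlapping cells mix their neighbours' signal.
    """
    from sklearn.metrics import f1_score

    rng = np.random.default_rng(seed)

    def profile_table(s):
        cfg = TissueSimConfig(canvas_size=256, n_cells=n_cells,
                              expression=SEPARABLE_EXPRESSION.copy(),
                              tumour_centre_margin_px=6, seed=s)
        t = simulate_cell_table(cfg)
        t[cfg.marker_panel] += rng.normal(0, noise_sd,
                                          (len(t), len(cfg.marker_panel)))
        return t, cfg.marker_panel

    train_t, markers = profile_table(seed)
    test_t, _ = profile_table(seed + 1)
    clf = cells_mod.train_cell_typer(train_t, markers, seed=seed)
    typed = cells_mod.apply_cell_typer(clf, test_t, markers)
    f1 = f1_score(test_t["type"], typed["predicted_type"], average="macro")

    # image-derived variant: pseudo-cell means from the rendered stack
    def imaged_table(s):
        _, scene = simulate_paired_roi(
            TissueSimConfig(canvas_size=256, n_cells=180,
                            expression=SEPARABLE_EXPRESSION.copy(),
                            tumour_centre_margin_px=6, seed=s))
        t = cells_mod.extract_pseudo_cells(scene.marker_stack,
                                           scene.centers, 10.0)
        t["type"] = scene.cell_table["type"].reindex(t["cell_id"]).to_numpy()
        return t

    tr_img = imaged_table(seed + 10)
    te_img = imaged_table(seed + 11)
    clf_img = cells_mod.train_cell_typer(tr_img, markers, seed=seed)
    typed_img = cells_mod.apply_cell_typer(clf_img, te_img, markers)
    f1_img = f1_score(te_img["type"], typed_img["predicted_type"],
                      average="macro")
    return {"macro_f1": float(f1), "macro_f1_imaged": float(f1_img),
            "oob_score": float(clf.oob_score_),
            "n_train_cells": int(len(train_t)),
            "n_test_cells": int(len(test_t))}


def survival_recovery(seed: int = 0, n_patients: int = 200,
                      epochs: int = 15) -> dict:
    """Held-out time-dependent C-index at zero and large planted effect."""
    out = {}
    for name, effect in (("null", 0.0), ("strong", 4.0)):
        bags = simulate_survival_cohort(n_patients, bag_size=8,
                                        feature_dim=16, effect_size=effect,
                                        censor_rate=0.2, seed=seed)
        split = int(0.7 * n_patients)
        train_bags, test_bags = bags[:split], bags[split:]
        cfg = mil.MilConfig(feature_dim=16, hidden=8, n_out=4, seed=seed)
        model, _ = mil.train_mil(train_bags, cfg, epochs=epochs, lr=2e-3,
                                 seed=seed)
        risks = mil.predict_risks(model, test_bags)
        res = mil.evaluate_survival(
            risks, np.array([b.time for b in test_bags]),
            np.array([b.censor for b in test_bags]),
            train_times=np.array([b.time for b in train_bags]),
            train_censors=np.array([b.censor for b in train_bags]))
        out[f"cindex_{name}_effect"] = res["cindex"]
        if name == "strong":
            out["logrank_p_strong_effect"] = res["logrank_p"]
    return out
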