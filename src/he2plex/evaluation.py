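"""Full-reference image metrics (PSNR, MS-SSIM, RMSE-SW), human-perception
error scoring, and the spatial co-localization statistic (Spearman
correlations of marker pairs on cell-level expressions, with the
mean-squared error between ground-truth and generated correlation profiles).
"""
from __future__ import annotations

import dataclasses
import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import spearmanr

log = logging.getLogger(__name__)

# standard published MS-SSIM scale weights (M = 5)
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def psnr(y: np.ndarray, y_hat: np.ndarray, dynamic_range: float = 1.0) -> float:
    """10·log10(L²/MSE); identical images give +inf (documented sentinel)."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("psnr: shape mismatch")
    if dynamic_range <= 0:
        raise ValueError("dynamic range must be positive")
    mse = float(np.mean((y - y_hat) ** 2))
    if mse == 0.0:
        return np.inf
    return float(10.0 * np.log10(dynamic_range ** 2 / mse))


def ssim(y: np.ndarray, y_hat: np.ndarray, dynamic_range: float = 1.0,
         win_size: int = 7, gaussian: bool = False, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03,
         full_window: bool = False) -> float:
    """Single-scale structural similarity with local (or one global) window.

    Local moments are population statistics over a uniform or Gaussian
    window; the map is averaged over the valid interior.  With
    ``full_window=True`` a single window spanning the whole image is used
    (global means/variances/covariance) — the textbook one-window formula.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("ssim: shape mismatch")
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    if full_window:
        mu1, mu2 = y.mean(), y_hat.mean()
        v1, v2 = y.var(), y_hat.var()
        cov = ((y - mu1) * (y_hat - mu2)).mean()
        return float(((2 * mu1 * mu2 + c1) * (2 * cov + c2))
                     / ((mu1 ** 2 + mu2 ** 2 + c1) * (v1 + v2 + c2)))
    if min(y.shape) < win_size:
        raise ValueError("image smaller than the SSIM window")
    if gaussian:
        def filt(a):
            return ndimage.gaussian_filter(a, sigma)
    else:
        def filt(a):
            return ndimage.uniform_filter(a, win_size)
    mu1, mu2 = filt(y), filt(y_hat)
    v1 = filt(y * y) - mu1 ** 2
    v2 = filt(y_hat * y_hat) - mu2 ** 2
    cov = filt(y * y_hat) - mu1 * mu2
    smap = (((2 * mu1 * mu2 + c1) * (2 * cov + c2))
            / ((mu1 ** 2 + mu2 ** 2 + c1) * (v1 + v2 + c2)))
    pad = (win_size - 1) // 2
    interior = smap[pad:smap.shape[0] - pad, pad:smap.shape[1] - pad]
    return float(interior.mean())


def _downsample2(a: np.ndarray) -> np.ndarray:
    h, w = a.shape
    a = a[:h - h % 2, :w - w % 2]
    return a.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def ms_ssim(y: np.ndarray, y_hat: np.ndarray, dynamic_range: float = 1.0,
            n_scales: int = 5, weights: tuple | None = None,
            win_size: int = 7, **ssim_kwargs) -> float:
    """Weighted product of per-scale SSIM values across dyadic scales.

    Per-scale values are floored at 0 before exponentiation so the score
    stays in [0, 1] for nonnegative weights.  For n_scales != 5 the first n
    standard weights are renormalized.
    """
    if weights is None:
        w = np.array(MSSSIM_WEIGHTS[:n_scales], dtype=float)
        weights = tuple(w / w.sum()) if n_scales != 5 else tuple(w)
    if len(weights) != n_scales:
        raise ValueError("need one weight per scale")
    if min(np.asarray(y).shape) // 2 ** (n_scales - 1) < win_size:
        raise ValueError("image too small for the requested number of scales")
    cy, ch = np.asarray(y, dtype=np.float64), np.asarray(y_hat, dtype=np.float64)
    score = 1.0
    for j in range(n_scales):
        s = max(ssim(cy, ch, dynamic_range, win_size=win_size, **ssim_kwargs), 0.0)
        score *= s ** weights[j]
        if j + 1 < n_scales:
            cy, ch = _downsample2(cy), _downsample2(ch)
    return float(score)


def rmse_sw(y: np.ndarray, y_hat: np.ndarray, window: tuple[int, int] = (8, 8),
            stride: int = 8) -> float:
    """Root of the mean over sliding windows of the per-window MSE."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("rmse_sw: shape mismatch")
    if stride <= 0:
        raise ValueError("stride must be positive")
    w, h = window
    hh, ww = y.shape
    if w > hh or h > ww:
        raise ValueError("window larger than image")
    sq = (y - y_hat) ** 2
    mses = []
    for y0 in range(0, hh - w + 1, stride):
        for x0 in range(0, ww - h + 1, stride):
            mses.append(sq[y0:y0 + w, x0:x0 + h].mean())
    return float(np.sqrt(np.mean(mses)))


# ---------------------------------------------------------------------------
# human-perception error scores
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HypeTrial:
    item_id: str
    is_real: bool        # ground truth
    judged_real: bool    # rater verdict
    marker_set: str = ""


def hype_scores(trials: list[HypeTrial]) -> tuple[float, float, float]:
    """(overall, on-generated, on-real) human error rates, in percent.

    TP: real judged real; TN: generated judged generated; FP: generated
    judged real; FN: real judged generated.
    """
    tp = sum(t.is_real and t.judged_real for t in trials)
    fn = sum(t.is_real and not t.judged_real for t in trials)
    fp = sum((not t.is_real) and t.judged_real for t in trials)
    tn = sum((not t.is_real) and not t.judged_real for t in trials)
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one real and one generated trial")
    overall = (fp + fn) / (tp + tn + fp + fn) * 100.0
    on_fake = fp / (tn + fp) * 100.0
    on_real = fn / (tp + fn) * 100.0
    return overall, on_fake, on_real


# ---------------------------------------------------------------------------
# co-localization (Spearman correlation of marker pairs on cell tables)
# ---------------------------------------------------------------------------

def pairwise_scc(table: pd.DataFrame, markers: list[str]) -> dict:
    """Spearman correlation for every marker pair on one ROI's cell table.

    Pairs with a constant marker are skipped (undefined correlation).
    """
    out = {}
    for a, b in combinations(markers, 2):
        xa, xb = table[a].to_numpy(), table[b].to_numpy()
        if np.all(xa == xa[0]) or np.all(xb == xb[0]):
            log.info("constant marker in pair (%s, %s); ROI skipped", a, b)
            continue
        out[(a, b)] = float(spearmanr(xa, xb).statistic)
    return out


def colocalization_scc(gt_tables: list[pd.DataFrame],
                       gen_tables: list[pd.DataFrame],
                       markers: list[str],
                       threshold: float = 0.15) -> tuple[pd.DataFrame, float]:
    """Average per-ROI marker-pair Spearman correlations and their MSE.

    Pair retained iff the |average ground-truth correlation| exceeds the
    threshold (strong positive > 0.15 or strong negative < −0.15); the MSE
    is computed between GT and generated averages over retained pairs.
    """
    if len(gt_tables) != len(gen_tables):
        raise ValueError("need matched GT/generated ROI lists")
    acc_gt: dict = {}
    acc_gen: dict = {}
    for tg, tn in zip(gt_tables, gen_tables):
        for pair, v in pairwise_scc(tg, markers).items():
            acc_gt.setdefault(pair, []).append(v)
        for pair, v in pairwise_scc(tn, markers).items():
            acc_gen.setdefault(pair, []).append(v)
    rows = []
    for pair in sorted(acc_gt):
        gt_avg = float(np.mean(acc_gt[pair]))
        gen_avg = float(np.mean(acc_gen.get(pair, [np.nan])))
        retained = abs(gt_avg) > threshold
        rows.append({"marker_a": pair[0], "marker_b": pair[1],
                     "scc_gt": gt_avg, "scc_gen": gen_avg,
                     "retained": retained})
    table = pd.DataFrame(rows)
    kept = table[table.retained & table.scc_gen.notna()]
    mse = float(np.mean((kept.scc_gt - kept.scc_gen) ** 2)) if len(kept) else np.nan
    return table, mse


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def metric_report(gt_stacks: list[np.ndarray], gen_stacks: list[np.ndarray],
                  channels: list[str], dynamic_range: float = 1.0,
                  n_scales: int = 3) -> pd.DataFrame:
    """Per-ROI, per-marker PSNR / MS-SSIM / RMSE-SW table."""
    rows = []
    for ri, (gt, gen) in enumerate(zip(gt_stacks, gen_stacks)):
        for ci, name in enumerate(channels):
            rows.append({
                "roi": ri, "marker": name,
                "psnr": psnr(gt[ci], gen[ci], dynamic_range),
                "ms_ssim": ms_ssim(gt[ci], gen[ci], dynamic_range,
                                   n_scales=n_scales),
                "rmse_sw": rmse_sw(gt[ci], gen[ci]),
            })
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd across ROIs, per marker and overall."""
    per_marker = report.groupby("marker")[["psnr", "ms_ssim", "rmse_sw"]].agg(
        ["mean", "std"])
    overall = report[["psnr", "ms_ssim", "rmse_sw"]].agg(["mean", "std"])
    overall.index.name = "stat"
    per_marker.loc["__all__"] = overall.T.stack()
    return per_marker
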