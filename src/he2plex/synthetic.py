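"""Synthetic paired H&E / marker-image simulator and survival-cohort generator.

The simulator emulates the data regime of paired histology studies: a
marker grid at 1 µm/px and an H&E image `he_scale_factor`× finer
(0.25 µm/px for the default factor 4), with cell-type-driven marker
expression, Gaussian optics blur, truncated additive noise, and a
controllable affine jitter of the H&E copy standing in for slice-to-slice
displacement between consecutive sections.  Every quantity downstream
modules estimate (marker co-expression, cell types, region densities,
survival effect sizes) is planted here with known ground truth.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_MARKERS = ["MelanA", "S100", "gp100", "SOX10", "CD3", "CD8a",
                   "CD20", "CD16", "CD31", "HLA-ABC", "HLA-DR"]
CELL_TYPES = ["tumour", "CD8 T", "CD4 T", "B", "endothelial", "other"]

# rows: cell types, cols: DEFAULT_MARKERS.  Tumour types express tumour
# markers strongly and immune markers ~0; immune types the converse.
DEFAULT_EXPRESSION = np.array([
    # MelanA S100 gp100 SOX10 CD3  CD8a CD20 CD16 CD31 HLA-ABC HLA-DR
    [0.90, 0.85, 0.80, 0.90, 0.0, 0.0, 0.0, 0.0, 0.0, 0.50, 0.20],  # tumour
    [0.0, 0.0, 0.0, 0.0, 0.90, 0.90, 0.0, 0.0, 0.0, 0.60, 0.10],    # CD8 T
    [0.0, 0.0, 0.0, 0.0, 0.90, 0.0, 0.0, 0.0, 0.0, 0.60, 0.10],     # CD4 T
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.90, 0.0, 0.0, 0.60, 0.70],     # B
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.90, 0.50, 0.10],     # endothelial
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.50, 0.0, 0.40, 0.30],     # other
])

DEFAULT_PROPORTIONS = {"tumour": 0.45, "CD8 T": 0.12, "CD4 T": 0.10,
                       "B": 0.08, "endothelial": 0.05, "other": 0.20}

# stylized two-color H&E rendering: dark basophilic nuclei on eosin background
EOSIN_BG = np.array([0.92, 0.74, 0.82])
HEMATOXYLIN_NUCLEUS = np.array([0.26, 0.18, 0.46])


@dataclasses.dataclass
class TissueSimConfig:
    canvas_size: int = 96                      # marker-grid px (1 µm/px)
    he_scale_factor: int = 4
    n_cells: int = 140
    cell_type_proportions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    marker_panel: list = dataclasses.field(default_factory=lambda: list(DEFAULT_MARKERS))
    expression: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_EXPRESSION.copy())
    nucleus_radius_um: float = 3.0
    blur_sigma: float = 1.0
    noise_sd: float = 0.05
    max_translation_px: float = 3.0            # H&E-grid px
    max_rotation_deg: float = 2.0
    tumour_centre_margin_px: int = 12          # scaled-down analogue of a 500 µm margin
    seed: int = 0

    def validate(self):
        props = np.array([self.cell_type_proportions[t] for t in CELL_TYPES])
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("cell-type proportions must sum to 1")
        if self.expression.shape != (len(CELL_TYPES), len(self.marker_panel)):
            raise ValueError("expression matrix shape mismatch")
        if np.any(self.expression < 0) or np.any(self.expression > 1):
            raise ValueError("expression entries must lie in [0, 1]")
        r = self.nucleus_radius_um
        if self.n_cells * np.pi * r * r > 0.9 * self.canvas_size ** 2:
            raise ValueError(
                f"canvas {self.canvas_size}px too small for {self.n_cells} "
                f"cells of radius {r}")


@dataclasses.dataclass
class MarkerStack:
    data: np.ndarray          # (C, H, W), values in [0, 1]
    channels: list
    um_per_px: float = 1.0


@dataclasses.dataclass
class PairedROI:
    he_image: np.ndarray      # (fH, fW, 3) float in [0, 1]
    marker_stack: MarkerStack
    he_to_marker: np.ndarray  # 3x3 affine undoing the jitter (H&E px units)
    metadata: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class GroundTruthScene:
    centers: np.ndarray       # (n, 2) marker-grid (x, y)
    types: np.ndarray         # (n,) int index into CELL_TYPES
    type_names: list
    raw_markers: np.ndarray   # (C, H, W) pre-blur, pre-noise
    marker_stack: MarkerStack
    he_image: np.ndarray
    he_clean: np.ndarray      # before affine jitter
    jitter: np.ndarray        # applied 3x3 affine (H&E px)
    jitter_inverse: np.ndarray
    masks: dict               # tumour_centre / intratumoral / stromal / tumour_support
    cell_table: pd.DataFrame


def _disk_mask(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    x0, x1 = max(0, int(np.floor(cx - r - 1))), min(w, int(np.ceil(cx + r + 2)))
    y0, y1 = max(0, int(np.floor(cy - r - 1))), min(h, int(np.ceil(cy + r + 2)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    m = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    full = np.zeros((h, w), dtype=bool)
    full[y0:y1, x0:x1] = m
    return full


def _affine_matrix(tx: float, ty: float, theta_deg: float, center: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    to_c = np.array([[1, 0, -center], [0, 1, -center], [0, 0, 1.0]])
    from_c = np.array([[1, 0, center], [0, 1, center], [0, 0, 1.0]])
    trans = np.array([[1, 0, tx], [0, 1, ty], [0, 0, 1.0]])
    return trans @ from_c @ rot @ to_c


def _apply_affine_rgb(img: np.ndarray, mat: np.ndarray, cval: np.ndarray) -> np.ndarray:
    """Warp (H, W, 3) by the (x, y) affine `mat` (output <- input coords)."""
    inv = np.linalg.inv(mat)
    # ndimage uses (row, col) = (y, x) ordering
    m = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    off = np.array([inv[1, 2], inv[0, 2]])
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[:, :, ch] = ndimage.affine_transform(
            img[:, :, ch], m, offset=off, order=1, mode="constant",
            cval=float(cval[ch]))
    return out


def _sample_cells(config: TissueSimConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Cell types from the configured mixture; tumour cells cluster around a
    blob center so the region masks are non-trivial."""
    n, size = config.n_cells, config.canvas_size
    r = config.nucleus_radius_um
    props = np.array([config.cell_type_proportions[t] for t in CELL_TYPES])
    types = rng.choice(len(CELL_TYPES), size=n, p=props)
    centers = np.empty((n, 2))
    blob = rng.uniform(0.3 * size, 0.7 * size, size=2)
    for i in range(n):
        if CELL_TYPES[types[i]] == "tumour":
            c = blob + rng.normal(0, 0.18 * size, size=2)
            centers[i] = np.clip(c, r, size - 1 - r)
        else:
            centers[i] = rng.uniform(r, size - 1 - r, size=2)
    return centers, types


def simulate_cell_table(config: TissueSimConfig) -> pd.DataFrame:
    """Cell table only (no rendering): id, position, type, marker columns.

    The marker columns hold the per-cell expression levels from the planted
    expression matrix — the ground truth that pseudo-cell extraction
    estimates from rendered images.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    centers, types = _sample_cells(config, rng)
    table = pd.DataFrame({"cell_id": np.arange(config.n_cells),
                          "x": centers[:, 0], "y": centers[:, 1],
                          "type": [CELL_TYPES[t] for t in types]})
    for m, name in enumerate(config.marker_panel):
        table[name] = config.expression[types, m]
    return table


def simulate_paired_roi(config: TissueSimConfig) -> tuple[PairedROI, GroundTruthScene]:
    """Render one paired pseudo-H&E / marker ROI with known ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, size, f = config.n_cells, config.canvas_size, config.he_scale_factor
    r = config.nucleus_radius_um  # marker grid is 1 µm/px

    centers, types = _sample_cells(config, rng)

    # --- marker stack -------------------------------------------------------
    c_mark = len(config.marker_panel)
    raw = np.zeros((c_mark, size, size))
    for i in range(n):
        disk = _disk_mask(size, size, centers[i, 0], centers[i, 1], r)
        for m in range(c_mark):
            e = config.expression[types[i], m]
            if e > 0:
                raw[m][disk] += e
    stack = np.empty_like(raw)
    for m in range(c_mark):
        ch = ndimage.gaussian_filter(raw[m], config.blur_sigma) \
            if config.blur_sigma > 0 else raw[m].copy()
        if config.noise_sd > 0:
            ch = ch + rng.normal(0, config.noise_sd, ch.shape)
        ch = np.clip(ch, 0.0, None)
        lo, hi = ch.min(), ch.max()
        stack[m] = (ch - lo) / (hi - lo) if hi > lo else np.zeros_like(ch)

    # --- pseudo-H&E at f× resolution ---------------------------------------
    hsize = size * f
    he = np.ones((hsize, hsize, 3)) * EOSIN_BG
    nucleus_r = r * f * 0.7  # nuclei smaller than the whole cell
    for i in range(n):
        disk = _disk_mask(hsize, hsize, centers[i, 0] * f, centers[i, 1] * f,
                          nucleus_r)
        he[disk] = HEMATOXYLIN_NUCLEUS
    he = ndimage.gaussian_filter(he, sigma=(0.5 * f / 4, 0.5 * f / 4, 0))
    he_clean = he.copy()

    if config.max_translation_px > 0 or config.max_rotation_deg > 0:
        tx = rng.uniform(-config.max_translation_px, config.max_translation_px)
        ty = rng.uniform(-config.max_translation_px, config.max_translation_px)
        th = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
        jitter = _affine_matrix(tx, ty, th, center=(hsize - 1) / 2)
        he = _apply_affine_rgb(he, jitter, EOSIN_BG)
    else:
        jitter = np.eye(3)
    inverse = np.linalg.inv(jitter)

    # --- region masks -------------------------------------------------------
    tumour_img = np.zeros((size, size))
    for i in range(n):
        if CELL_TYPES[types[i]] == "tumour":
            yi, xi = int(round(centers[i, 1])), int(round(centers[i, 0]))
            tumour_img[yi, xi] += 1.0
    density = ndimage.gaussian_filter(tumour_img, 0.12 * size)
    support = density > 0.2 * density.max() if density.max() > 0 else density > 0
    margin = config.tumour_centre_margin_px
    centre = ndimage.binary_erosion(support, iterations=margin) if margin > 0 else support
    intratumoral = centre & (density > 0.5 * density.max())
    stromal = centre & ~intratumoral
    masks = {"tumour_support": support, "tumour_centre": centre,
             "intratumoral": intratumoral, "stromal": stromal}

    # --- cell table ---------------------------------------------------------
    rows = {"cell_id": np.arange(n), "x": centers[:, 0], "y": centers[:, 1],
            "type": [CELL_TYPES[t] for t in types]}
    table = pd.DataFrame(rows)
    for m, name in enumerate(config.marker_panel):
        table[name] = config.expression[types, m]
    yi = np.clip(np.round(centers[:, 1]).astype(int), 0, size - 1)
    xi = np.clip(np.round(centers[:, 0]).astype(int), 0, size - 1)
    region = np.full(n, "none", dtype=object)
    region[stromal[yi, xi]] = "stromal"
    region[intratumoral[yi, xi]] = "intratumoral"
    table["region"] = region

    marker_stack = MarkerStack(stack, list(config.marker_panel), um_per_px=1.0)
    roi = PairedROI(he_image=he, marker_stack=marker_stack, he_to_marker=inverse,
                    metadata={"seed": config.seed})
    scene = GroundTruthScene(centers=centers, types=types, type_names=list(CELL_TYPES),
                             raw_markers=raw, marker_stack=marker_stack,
                             he_image=he, he_clean=he_clean, jitter=jitter,
                             jitter_inverse=inverse, masks=masks, cell_table=table)
    return roi, scene


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SurvivalBag:
    patient_id: int
    features_h: np.ndarray    # (bag_size, d) "histology" modality
    features_p: np.ndarray    # (bag_size, d) "marker" modality
    time: float
    time_bin: int
    censor: int               # 0 = death observed, 1 = censored
    label: int                # binary subtype label derived from latent risk
    risk_true: float


def discretize_by_quartiles(times: np.ndarray, cuts: np.ndarray | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Quartile binning into 4 half-open intervals [t_{j-1}, t_j).

    Returns (bin labels in 0..3, cut points).  Times beyond the last cut
    fall in the last bin.  When `cuts` is given it is used as-is (train-set
    statistics applied to new data).
    """
    times = np.asarray(times, dtype=float)
    if cuts is None:
        if np.unique(times).size < 4:
            raise ValueError("need >= 4 distinct times for quartile cuts")
        cuts = np.quantile(times, [0.25, 0.5, 0.75])
    bins = np.searchsorted(cuts, times, side="right")
    return np.minimum(bins, 3), np.asarray(cuts)


def simulate_survival_cohort(n_patients: int, bag_size: int = 16,
                             feature_dim: int = 32, effect_size: float = 1.0,
                             censor_rate: float = 0.2, seed: int = 0,
                             n_informative: int = 8) -> list[SurvivalBag]:
    """Cohort of MIL bags with a planted latent risk.

    A latent score u ~ N(0,1) per patient defines the risk
    ``r = effect_size * u``; event times are exponential with rate exp(r),
    censoring is independent uniform on (0, t_event).  The risk is embedded
    additively in the first `n_informative` feature dimensions of every
    instance (both modalities, disjoint noise), so effect_size 0 yields
    bags carrying no survival signal.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n_patients)
    risk = effect_size * u
    t_event = rng.exponential(1.0 / np.exp(risk))
    censored = rng.random(n_patients) < censor_rate
    t_obs = np.where(censored, rng.uniform(0, t_event), t_event)
    bins, _ = discretize_by_quartiles(t_obs)
    label = (u > np.median(u)).astype(int)

    bags = []
    for i in range(n_patients):
        fh = rng.standard_normal((bag_size, feature_dim))
        fp = rng.standard_normal((bag_size, feature_dim))
        fh[:, :n_informative] += risk[i]
        fp[:, :n_informative] += risk[i]
        bags.append(SurvivalBag(patient_id=i, features_h=fh, features_p=fp,
                                time=float(t_obs[i]), time_bin=int(bins[i]),
                                censor=int(censored[i]), label=int(label[i]),
                                risk_true=float(risk[i])))
    return bags


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_scene(scene: GroundTruthScene, out_dir: str | Path):
    """Persist a scene as PNG/TIFF images plus CSV tables."""
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "he.png", (np.clip(scene.he_image, 0, 1) * 255).astype(np.uint8))
    tifffile.imwrite(out / "markers.tiff",
                     scene.marker_stack.data.astype(np.float32),
                     metadata={"channels": scene.marker_stack.channels,
                               "um_per_px": scene.marker_stack.um_per_px})
    for name, mask in scene.masks.items():
        iio.imwrite(out / f"mask_{name}.png", (mask.astype(np.uint8) * 255))
    scene.cell_table.to_csv(out / "cells.csv", index=False)
    with open(out / "jitter.json", "w") as fh:
        json.dump({"affine": scene.jitter.tolist(),
                   "inverse": scene.jitter_inverse.tolist()}, fh, indent=2)


def write_survival_cohort(bags: list[SurvivalBag], out_dir: str | Path):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [{"patient": b.patient_id, "time": b.time, "bin": b.time_bin,
             "censor": b.censor, "label": b.label} for b in bags]
    pd.DataFrame(rows).to_csv(out / "survival.csv", index=False)
    for b in bags:
        np.savez(out / f"bag_{b.patient_id:04d}.npz",
                 features_h=b.features_h, features_p=b.features_p)
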