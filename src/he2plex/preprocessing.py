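"""Marker normalization, MI template matching and stain handling.

The marker normalization chain is: clip at the 99.9th percentile →
arcsinh (cofactor 1) → per-sample Otsu background zeroing (after light
Gaussian smoothing) → centre/standardize → min–max to [0, 1], with every
statistic estimated on the training split only.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import color, filters

from .synthetic import MarkerStack


@dataclasses.dataclass
class ChannelStats:
    clip: float
    otsu: float
    mean: float
    sd: float
    min: float
    max: float


@dataclasses.dataclass
class NormalizationStats:
    channels: list
    cofactor: float
    stats: dict  # name -> ChannelStats
    otsu_on_arcsinh: bool = True

    def to_json(self, path: str | Path):
        payload = {"channels": self.channels, "cofactor": self.cofactor,
                   "otsu_on_arcsinh": self.otsu_on_arcsinh,
                   "stats": {k: dataclasses.asdict(v) for k, v in self.stats.items()}}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        payload = json.loads(Path(path).read_text())
        stats = {k: ChannelStats(**v) for k, v in payload["stats"].items()}
        return cls(channels=payload["channels"], cofactor=payload["cofactor"],
                   stats=stats, otsu_on_arcsinh=payload["otsu_on_arcsinh"])


def percentile_clip_value(values: np.ndarray, q: float = 99.9) -> float:
    return float(np.percentile(values, q))


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance (Otsu's criterion)."""
    image = np.asarray(image)
    if np.unique(image).size < 2:
        raise ValueError("otsu_threshold: image is constant")
    return float(filters.threshold_otsu(image, nbins=nbins))


def _smooth_for_otsu(channel: np.ndarray, kernel_size: int = 3,
                     sigma: float = 3.0) -> np.ndarray:
    # Gaussian pre-smoothing with a small truncated kernel before Otsu
    radius = (kernel_size - 1) // 2
    return ndimage.gaussian_filter(channel, sigma=sigma,
                                   truncate=radius / sigma)


def fit_normalization(train_stacks: list[MarkerStack], cofactor: float = 1.0,
                      clip_q: float = 99.9, otsu_on_arcsinh: bool = True
                      ) -> NormalizationStats:
    """Fit the per-marker normalization chain on the training split.

    The Otsu background threshold is computed per sample pooled over all of
    that sample's ROIs; here the ROI list passed in constitutes one sample.
    """
    if not train_stacks:
        raise ValueError("need at least one training stack")
    channels = train_stacks[0].channels
    stats: dict[str, ChannelStats] = {}
    for ci, name in enumerate(channels):
        pooled = np.concatenate([s.data[ci].ravel() for s in train_stacks])
        clip = percentile_clip_value(pooled, clip_q)
        x = np.arcsinh(np.minimum(pooled, clip) / cofactor)
        if otsu_on_arcsinh:
            smoothed = [_smooth_for_otsu(
                np.arcsinh(np.minimum(s.data[ci], clip) / cofactor))
                for s in train_stacks]
        else:
            smoothed = [_smooth_for_otsu(np.minimum(s.data[ci], clip))
                        for s in train_stacks]
        pooled_smooth = np.concatenate([s.ravel() for s in smoothed])
        try:
            thr = otsu_threshold(pooled_smooth)
        except ValueError:
            thr = -np.inf  # constant channel: nothing to zero
        x = x.copy()
        x[x <= thr] = 0.0
        sd = float(x.std())
        mean = float(x.mean())
        if sd == 0.0:
            warnings.warn(f"channel {name} constant after thresholding; "
                          "standardization skipped")
            z = x - mean
        else:
            z = (x - mean) / sd
        stats[name] = ChannelStats(clip=clip, otsu=float(thr), mean=mean,
                                   sd=sd, min=float(z.min()), max=float(z.max()))
    return NormalizationStats(channels=list(channels), cofactor=cofactor,
                              stats=stats, otsu_on_arcsinh=otsu_on_arcsinh)


def apply_normalization(stack: MarkerStack, norm: NormalizationStats) -> MarkerStack:
    out = np.empty_like(stack.data, dtype=np.float64)
    for ci, name in enumerate(stack.channels):
        st = norm.stats[name]
        x = np.arcsinh(np.minimum(stack.data[ci], st.clip) / norm.cofactor)
        x[x <= st.otsu] = 0.0
        z = (x - st.mean) / st.sd if st.sd > 0 else x - st.mean
        rng_ = st.max - st.min
        out[ci] = np.clip((z - st.min) / rng_, 0.0, 1.0) if rng_ > 0 else np.zeros_like(z)
    return MarkerStack(out, list(stack.channels), stack.um_per_px)


# ---------------------------------------------------------------------------
# mutual-information template matching
# ---------------------------------------------------------------------------

def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """MI of two images from a bins×bins joint histogram."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


@dataclasses.dataclass
class RigidMatch:
    dx: int
    dy: int
    rotation_deg: float
    mi: float

    def to_affine(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s, self.dx], [s, c, self.dy], [0, 0, 1.0]])


def _rotate(img: np.ndarray, deg: float) -> np.ndarray:
    k = deg / 90.0
    if np.isclose(k, round(k)):
        return np.rot90(img, -int(round(k)) % 4)
    return ndimage.rotate(img, -deg, reshape=False, order=1, mode="nearest")


def template_match_mi(fixed: np.ndarray, moving: np.ndarray,
                      max_shift: int | None = None,
                      rotations: tuple = (0.0, 90.0, 180.0, 270.0),
                      bins: int = 32, min_overlap: float = 0.25) -> RigidMatch:
    """Exhaustive rigid search maximizing mutual information.

    Scores every (rotation, integer dx, dy) candidate on the overlap of the
    two single-channel images; candidates whose overlap falls below
    ``min_overlap`` of the image area are skipped.  Returns the transform
    mapping moving-image coordinates onto the fixed image.
    """
    if fixed.ndim != 2 or moving.ndim != 2:
        raise ValueError("template_match_mi expects single-channel images")
    h, w = fixed.shape
    if max_shift is None:
        max_shift = max(1, int(0.25 * min(h, w)))
    best: RigidMatch | None = None
    for rot in rotations:
        m = _rotate(moving, rot)
        for dy in range(-max_shift, max_shift + 1):
            for dx in range(-max_shift, max_shift + 1):
                fy0, fy1 = max(0, dy), min(h, m.shape[0] + dy)
                fx0, fx1 = max(0, dx), min(w, m.shape[1] + dx)
                if (fy1 - fy0) * (fx1 - fx0) < min_overlap * h * w:
                    continue
                fsub = fixed[fy0:fy1, fx0:fx1]
                msub = m[fy0 - dy:fy1 - dy, fx0 - dx:fx1 - dx]
                mi = mutual_information(fsub, msub, bins)
                if best is None or mi > best.mi:
                    best = RigidMatch(dx=dx, dy=dy, rotation_deg=rot, mi=mi)
    if best is None:
        raise ValueError("no candidate with sufficient overlap")
    return best


# ---------------------------------------------------------------------------
# stain handling
# ---------------------------------------------------------------------------

def h_channel_deconvolution(rgb: np.ndarray) -> np.ndarray:
    """Haematoxylin concentration image via standard H&E color deconvolution."""
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return color.rgb2hed(rgb)[:, :, 0]


# reference Macenko stain basis (columns: haematoxylin, eosin OD directions)
MACENKO_REFERENCE = np.array([[0.5626, 0.2159],
                              [0.7201, 0.8012],
                              [0.4062, 0.5581]])
MACENKO_REFERENCE_MAXC = np.array([1.9705, 1.0308])


def macenko_normalize(rgb: np.ndarray,
                      reference: np.ndarray = MACENKO_REFERENCE,
                      reference_max_c: np.ndarray = MACENKO_REFERENCE_MAXC,
                      io: float = 255.0, alpha: float = 1.0,
                      beta: float = 0.15) -> np.ndarray:
    """Macenko stain normalization of an RGB tile onto a reference basis.

    Optical density OD = −log((I+1)/Io); the 2-vector stain basis is the
    pair of extreme directions (robust alpha / 100−alpha percentile angles)
    in the top-2 OD eigenspace; concentrations are remapped so their 99th
    percentiles match the reference maxima.  Near-white tiles (no tissue)
    are returned unchanged with a warning.
    """
    img = np.asarray(rgb, dtype=np.float64)
    scaled = img * 255.0 if img.max() <= 1.0 + 1e-9 else img
    od = -np.log((scaled.reshape(-1, 3) + 1.0) / io)
    tissue = od[np.all(od > beta, axis=1)]
    if tissue.shape[0] < 10:
        warnings.warn("macenko_normalize: no tissue OD found; tile unchanged")
        return np.asarray(rgb).copy()
    _, eigvecs = np.linalg.eigh(np.cov(tissue.T))
    basis = eigvecs[:, 1:3]  # top-2 eigenvectors
    proj = tissue @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi_min, phi_max = np.percentile(phi, alpha), np.percentile(phi, 100 - alpha)
    v1 = basis @ np.array([np.cos(phi_min), np.sin(phi_min)])
    v2 = basis @ np.array([np.cos(phi_max), np.sin(phi_max)])
    if v1[0] > v2[0]:
        stain = np.column_stack([v1, v2])
    else:
        stain = np.column_stack([v2, v1])
    stain *= np.sign(stain.sum(axis=0, keepdims=True))  # OD-positive directions
    conc = np.linalg.lstsq(stain, od.T, rcond=None)[0]  # (2, npix)
    max_c = np.percentile(conc, 99, axis=1)
    max_c[max_c <= 0] = 1.0
    conc = conc * (reference_max_c / max_c)[:, None]
    od_norm = (reference @ conc).T
    out = io * np.exp(-od_norm) - 1.0
    out = np.clip(out, 0, 255).reshape(img.shape)
    return out / 255.0 if img.max() <= 1.0 + 1e-9 else out


def save_affine_json(mat: np.ndarray, path: str | Path):
    """3x3 affine, row-major, pixel units, origin at top-left (0-based)."""
    Path(path).write_text(json.dumps({"affine": np.asarray(mat).tolist()}, indent=2))


def load_affine_json(path: str | Path) -> np.ndarray:
    return np.array(json.loads(Path(path).read_text())["affine"], dtype=float)
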