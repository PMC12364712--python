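"""Pseudo-cells, cell typing, t-SNE and immune-phenotype densities."""
import numpy as np
import pandas as pd
import pytest

from he2plex.cells import (apply_cell_typer, disk_pixel_count,
                           extract_pseudo_cells, hot_cold_classifier,
                           joint_tsne, phenotype_densities, train_cell_typer)
from he2plex.synthetic import (MarkerStack, TissueSimConfig,
                               simulate_paired_roi)

from conftest import small_sim_config


def test_uniform_channel_gives_uniform_means():
    stack = MarkerStack(np.full((2, 32, 32), 0.7), ["a", "b"])
    coords = np.array([[5.0, 5.0], [16.0, 20.0], [30.0, 30.0]])
    table = extract_pseudo_cells(stack, coords, diameter_um=10)
    assert np.allclose(table[["a", "b"]].to_numpy(), 0.7)
    assert len(table) == 3


def test_disk_pixel_count_matches_enumeration_oracle():
    # brute-force rasterized disk at 1 µm/px, 10 µm diameter, integer center
    r = 5.0
    count = 0
    for y in range(-6, 7):
        for x in range(-6, 7):
            if x * x + y * y <= r * r:
                count += 1
    assert disk_pixel_count(10.0, 1.0) == count
    # the extractor averages over exactly that pixel set
    img = np.zeros((32, 32))
    img[10:22, 10:22] = 1.0
    stack = MarkerStack(img[None], ["m"])
    table = extract_pseudo_cells(stack, np.array([[16.0, 16.0]]), 10.0)
    disk_sum = 0.0
    for y in range(32):
        for x in range(32):
            if (x - 16) ** 2 + (y - 16) ** 2 <= r * r:
                disk_sum += img[y, x]
    assert table["m"].iloc[0] == pytest.approx(disk_sum / count, rel=1e-12)


def test_cell_in_uniform_island_has_mean_one():
    img = np.zeros((64, 64))
    yy, xx = np.mgrid[:64, :64]
    img[(xx - 32) ** 2 + (yy - 32) ** 2 <= 36] = 1.0  # island radius 6 > disk 5
    stack = MarkerStack(img[None], ["m"])
    table = extract_pseudo_cells(stack, np.array([[32.0, 32.0]]), 10.0)
    assert table["m"].iloc[0] == pytest.approx(1.0)


def test_out_of_bounds_centers_skipped():
    stack = MarkerStack(np.zeros((1, 16, 16)), ["m"])
    table = extract_pseudo_cells(stack, np.array([[8.0, 8.0], [99.0, 2.0]]), 10)
    assert table["cell_id"].tolist() == [0]


def test_translation_equivariance_of_disk_means():
    rng = np.random.default_rng(0)
    img = rng.random((48, 48))
    shifted = np.roll(np.roll(img, 7, axis=0), 4, axis=1)
    t1 = extract_pseudo_cells(MarkerStack(img[None], ["m"]),
                              np.array([[20.0, 20.0]]), 10)
    t2 = extract_pseudo_cells(MarkerStack(shifted[None], ["m"]),
                              np.array([[24.0, 27.0]]), 10)
    assert t1["m"].iloc[0] == pytest.approx(t2["m"].iloc[0], rel=1e-12)


# ---------------------------------------------------------------------------
# cell typing
# ---------------------------------------------------------------------------

def _separable_cells(rng, n=600, separation=1.0):
    """Synthetic marker profiles with disjoint support per class."""
    profiles = {"tumour": [0.9, 0.0, 0.0], "B": [0.0, 0.9, 0.0],
                "CD8 T": [0.0, 0.0, 0.9]}
    rows = []
    for _ in range(n):
        t = rng.choice(list(profiles))
        x = np.array(profiles[t]) * separation + rng.normal(0, 0.15, 3)
        rows.append({"m1": x[0], "m2": x[1], "m3": x[2], "type": t})
    return pd.DataFrame(rows)


def test_separable_profiles_reach_high_macro_f1():
    from sklearn.metrics import f1_score
    rng = np.random.default_rng(1)
    train_t = _separable_cells(rng)
    test_t = _separable_cells(rng)
    clf = train_cell_typer(train_t, ["m1", "m2", "m3"], seed=0)
    typed = apply_cell_typer(clf, test_t, ["m1", "m2", "m3"])
    f1 = f1_score(test_t["type"], typed["predicted_type"], average="macro")
    assert f1 >= 0.95
    assert clf.oob_score_ > 0.9


def test_macro_f1_improves_with_class_separation():
    from sklearn.metrics import f1_score
    scores = []
    for sep in (0.15, 0.4, 1.0):
        rng = np.random.default_rng(2)
        train_t = _separable_cells(rng, separation=sep)
        test_t = _separable_cells(rng, separation=sep)
        clf = train_cell_typer(train_t, ["m1", "m2", "m3"], seed=0)
        typed = apply_cell_typer(clf, test_t, ["m1", "m2", "m3"])
        scores.append(f1_score(test_t["type"], typed["predicted_type"],
                               average="macro"))
    assert scores[0] < scores[1] < scores[2]


def test_single_class_input_raises():
    t = _separable_cells(np.random.default_rng(3))
    t["type"] = "tumour"
    with pytest.raises(ValueError, match="two cell classes"):
        train_cell_typer(t, ["m1", "m2", "m3"])


def test_missing_marker_columns_at_apply_raise():
    rng = np.random.default_rng(4)
    t = _separable_cells(rng)
    clf = train_cell_typer(t, ["m1", "m2", "m3"])
    with pytest.raises(ValueError, match="missing"):
        apply_cell_typer(clf, t.drop(columns=["m3"]), ["m1", "m2", "m3"])


# ---------------------------------------------------------------------------
# t-SNE
# ---------------------------------------------------------------------------

def test_joint_tsne_separates_planted_clusters():
    from sklearn.metrics import silhouette_score
    rng = np.random.default_rng(5)
    mk = ["m1", "m2"]

    def roi(center):
        return pd.DataFrame(rng.normal(center, 0.1, size=(120, 2)), columns=mk)

    gt = [roi([0, 0]), roi([3, 3])]
    gen = [roi([0, 0]), roi([3, 3])]
    emb, colors = joint_tsne(gt, gen, mk, n_per_roi=100, perplexity=30,
                             n_iter=300, seed=0)
    assert emb.shape == (400, 2)  # 2 ROIs x 2 sources x 100 cells
    labels = (colors["roi"] == 1).astype(int)
    assert silhouette_score(emb, labels) > 0.5


def test_tsne_color_values_scaled_and_clipped_at_p99():
    rng = np.random.default_rng(6)
    mk = ["m1"]
    t = pd.DataFrame({"m1": np.concatenate([rng.random(199), [1000.0]])})
    emb, colors = joint_tsne([t], [t.copy()], mk, n_per_roi=200,
                             perplexity=20, n_iter=260, seed=0)
    assert colors["m1"].max() == pytest.approx(1.0)
    # the extreme outlier is clipped: many values share the cap
    assert (colors["m1"] == 1.0).sum() >= 2


def test_tsne_perplexity_validation():
    t = pd.DataFrame({"m1": np.arange(10.0)})
    with pytest.raises(ValueError, match="perplexity"):
        joint_tsne([t], [t], ["m1"], n_per_roi=10, perplexity=50, n_iter=260)


# ---------------------------------------------------------------------------
# phenotype densities
# ---------------------------------------------------------------------------

def _mask_set(h=64, w=64):
    intr = np.zeros((h, w), dtype=bool)
    strm = np.zeros((h, w), dtype=bool)
    intr[:, :32] = True
    strm[:, 32:] = True
    return {"intratumoral": intr, "stromal": strm}


def test_no_cd8_cells_gives_zero_densities():
    table = pd.DataFrame({"x": [5.0], "y": [5.0], "predicted_type": ["tumour"]})
    d = phenotype_densities(table, _mask_set())
    assert d.icd8 == 0.0 and d.scd8 == 0.0


def test_density_arithmetic_example():
    # 50 CD8 cells uniformly inside a 1000x1000 µm intratumoral compartment
    rng = np.random.default_rng(7)
    intr = np.zeros((1100, 1100), dtype=bool)
    intr[:1000, :1000] = True
    strm = ~intr
    xs = rng.uniform(0, 999, 50)
    ys = rng.uniform(0, 999, 50)
    table = pd.DataFrame({"x": xs, "y": ys,
                          "predicted_type": ["CD8 T"] * 50})
    d = phenotype_densities(table, {"intratumoral": intr, "stromal": strm})
    assert d.icd8 == pytest.approx(50 / 1_000_000)
    assert d.icd8 == pytest.approx(5e-5)


def test_boundary_cells_follow_center_pixel_convention():
    masks = _mask_set()
    # center-pixel rule: x rounds to the nearest integer; 31.4 -> 31 (intr),
    # 31.6 -> 32 (stromal).  Oracle: point-in-half-open-rectangle test.
    table = pd.DataFrame({"x": [31.4, 31.6], "y": [10.0, 10.0],
                          "predicted_type": ["CD8 T", "CD8 T"]})
    d = phenotype_densities(table, masks)
    def in_rect(x, lo, hi):
        return lo <= round(x) < hi
    expected_i = sum(in_rect(x, 0, 32) for x in table.x) / masks["intratumoral"].sum()
    expected_s = sum(in_rect(x, 32, 64) for x in table.x) / masks["stromal"].sum()
    assert d.icd8 == pytest.approx(expected_i)
    assert d.scd8 == pytest.approx(expected_s)


def test_excluded_regions_removed_before_counting():
    masks = _mask_set()
    excl = np.zeros_like(masks["intratumoral"])
    excl[10, 10] = True
    masks["excluded"] = excl
    table = pd.DataFrame({"x": [10.0, 20.0], "y": [10.0, 10.0],
                          "predicted_type": ["CD8 T", "CD8 T"]})
    d = phenotype_densities(table, masks)
    assert d.icd8 == pytest.approx(1 / masks["intratumoral"].sum())


def test_zero_area_compartment_flagged():
    masks = {"intratumoral": np.zeros((8, 8), bool),
             "stromal": np.ones((8, 8), bool)}
    with pytest.raises(ValueError, match="zero-area"):
        phenotype_densities(pd.DataFrame({"x": [], "y": [],
                                          "predicted_type": []}), masks)


def test_doubling_coordinates_and_mask_quarters_density():
    rng = np.random.default_rng(8)
    intr = np.zeros((64, 64), bool)
    intr[:32, :32] = True
    strm = ~intr
    xs, ys = rng.uniform(0, 31, 20), rng.uniform(0, 31, 20)
    t1 = pd.DataFrame({"x": xs, "y": ys, "predicted_type": ["CD8 T"] * 20})
    d1 = phenotype_densities(t1, {"intratumoral": intr, "stromal": strm})
    intr2 = np.kron(intr, np.ones((2, 2), bool))
    strm2 = np.kron(strm, np.ones((2, 2), bool))
    t2 = pd.DataFrame({"x": xs * 2, "y": ys * 2,
                       "predicted_type": ["CD8 T"] * 20})
    d2 = phenotype_densities(t2, {"intratumoral": intr2, "stromal": strm2})
    assert d2.icd8 == pytest.approx(d1.icd8 / 4)


# ---------------------------------------------------------------------------
# hot/cold classifier
# ---------------------------------------------------------------------------

def test_perfectly_separated_densities_give_unit_f1():
    rng = np.random.default_rng(9)
    hot = pd.DataFrame({"icd8": rng.uniform(4e-5, 8e-5, 20),
                        "scd8": rng.uniform(4e-5, 8e-5, 20)})
    cold = pd.DataFrame({"icd8": rng.uniform(0, 5e-6, 20),
                         "scd8": rng.uniform(0, 5e-6, 20)})
    dens = pd.concat([hot, cold], ignore_index=True)
    labels = np.array(["hot"] * 20 + ["cold"] * 20)
    res = hot_cold_classifier(dens, labels, seed=0)
    assert res["f1_mean"] == pytest.approx(1.0)
    assert res["auroc_mean"] == pytest.approx(1.0)


def test_label_permutation_gives_chance_auroc():
    rng = np.random.default_rng(10)
    dens = pd.DataFrame({"icd8": rng.uniform(0, 1e-4, 120),
                         "scd8": rng.uniform(0, 1e-4, 120)})
    aurocs = []
    for rep in range(3):
        labels = rng.permutation(np.array(["hot", "cold"] * 60))
        res = hot_cold_classifier(dens, labels, seed=rep)
        aurocs.append(res["auroc_mean"])
    assert 0.35 <= np.mean(aurocs) <= 0.65


def test_single_class_folds_refused():
    dens = pd.DataFrame({"icd8": np.arange(6.0), "scd8": np.arange(6.0)})
    labels = np.array(["hot"] * 5 + ["cold"])
    with pytest.raises(ValueError, match="single class"):
        hot_cold_classifier(dens, labels, n_splits=5)


def test_simulator_scene_supports_end_to_end_phenotyping():
    cfg = small_sim_config(n_cells=120, canvas_size=96, seed=11)
    _, scene = simulate_paired_roi(cfg)
    cells = extract_pseudo_cells(scene.marker_stack,
                                 scene.centers, diameter_um=10)
    cells["predicted_type"] = scene.cell_table["type"].reindex(
        cells["cell_id"]).to_numpy()
    if not (scene.masks["intratumoral"].any() and scene.masks["stromal"].any()):
        pytest.skip("scene without both compartments")
    d = phenotype_densities(cells, scene.masks, type_col="predicted_type")
    assert d.icd8 >= 0 and d.scd8 >= 0
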