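"""Atlas mapping and hierarchical quantification: exact conservation identities."""

import numpy as np
import pandas as pd
import pytest

from cfosmap.atlas import (
    AffineTransform,
    ap_profile,
    counts_by_level,
    hemisphere_counts,
    layer_metrics,
    map_cells_to_atlas,
)
from cfosmap.volume import MaskVolume


def random_cells(atlas, n, seed, animals=("m1", "m2")):
    """Cells at random in-brain atlas voxels, expressed in image micrometres."""
    rng = np.random.default_rng(seed)
    inbrain = np.argwhere(atlas.annotation > 0)
    picks = inbrain[rng.integers(0, len(inbrain), size=n)]
    vs = np.asarray(atlas.voxel_size)
    um = picks * vs  # identity-scaled image: image um = atlas voxel * voxel size
    return pd.DataFrame(
        {
            "animal": rng.choice(animals, size=n),
            "z_um": um[:, 0],
            "y_um": um[:, 1],
            "x_um": um[:, 2],
        }
    )


@pytest.fixture()
def um_to_voxel(toy_atlas):
    return AffineTransform.scaling([1.0 / v for v in toy_atlas.voxel_size])


class TestMapping:
    def test_identity_lookup(self, toy_atlas, um_to_voxel):
        vox = np.argwhere(toy_atlas.annotation > 0)[0]
        label = toy_atlas.annotation[tuple(vox)]
        cells = pd.DataFrame([dict(zip(["z_um", "y_um", "x_um"], vox * np.asarray(toy_atlas.voxel_size)))])
        mapped = map_cells_to_atlas(cells, um_to_voxel, toy_atlas)
        assert mapped["region_id"].iloc[0] == label

    def test_outside_cell_unassigned(self, toy_atlas, um_to_voxel):
        cells = pd.DataFrame([{"z_um": -500.0, "y_um": 0.0, "x_um": 0.0}])
        mapped = map_cells_to_atlas(cells, um_to_voxel, toy_atlas)
        assert mapped["region_id"].iloc[0] == 0
        assert mapped["hemisphere"].iloc[0] == "unassigned"

    def test_translation_matches_brute_force_lookup(self, toy_atlas, um_to_voxel):
        cells = random_cells(toy_atlas, 60, seed=8)
        shift = np.eye(4)
        shift[2, 3] = 1.0  # one atlas voxel along x, applied after scaling
        transform = AffineTransform(shift @ um_to_voxel.matrix)
        mapped = map_cells_to_atlas(cells, transform, toy_atlas)
        vs = np.asarray(toy_atlas.voxel_size)
        for _, row in mapped.iterrows():
            vox = np.rint(row[["z_um", "y_um", "x_um"]].to_numpy(dtype=float) / vs).astype(int)
            vox[2] += 1
            expected = 0
            if np.all(vox >= 0) and np.all(vox < toy_atlas.annotation.shape):
                expected = toy_atlas.annotation[tuple(vox)]
            assert row["region_id"] == expected

    def test_round_trip_through_inverse(self, toy_atlas, um_to_voxel):
        cells = random_cells(toy_atlas, 40, seed=9)
        mapped = map_cells_to_atlas(cells, um_to_voxel, toy_atlas)
        back = um_to_voxel.inverse().apply(mapped[["atlas_z", "atlas_y", "atlas_x"]].to_numpy())
        np.testing.assert_allclose(back, cells[["z_um", "y_um", "x_um"]].to_numpy(), atol=1e-6)

    def test_singular_transform_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(m)

    def test_transform_json_round_trip(self, tmp_path, um_to_voxel):
        um_to_voxel.to_json(tmp_path / "t.json")
        back = AffineTransform.from_json(tmp_path / "t.json")
        np.testing.assert_allclose(back.matrix, um_to_voxel.matrix)


class TestCountsByLevel:
    def test_parent_counts_aggregate_children(self, toy_atlas, um_to_voxel):
        # plant exactly 3 cells in each of the 4 leaves
        vs = np.asarray(toy_atlas.voxel_size)
        rows = []
        for leaf in toy_atlas.ontology.nodes_at_level(3):
            vox = np.argwhere(toy_atlas.annotation == leaf)[:3]
            for v in vox:
                rows.append({"animal": "m1", "z_um": v[0] * vs[0], "y_um": v[1] * vs[1], "x_um": v[2] * vs[2]})
        cells = map_cells_to_atlas(pd.DataFrame(rows), um_to_voxel, toy_atlas)
        lvl2 = counts_by_level(cells, toy_atlas, 2)
        for _, row in lvl2[lvl2["region_id"] != 0].iterrows():
            n_children = len(toy_atlas.ontology.children(row["region_id"]))
            assert row["count"] == 3 * n_children

    def test_zero_cells_gives_full_zero_table(self, toy_atlas):
        empty = pd.DataFrame(columns=["z_um", "y_um", "x_um", "region_id", "hemisphere"])
        table = counts_by_level(empty.assign(region_id=pd.Series(dtype=int)), toy_atlas, 3)
        assert (table["count"] == 0).all()
        assert set(table[table["region_id"] != 0]["region_id"]) == set(
            toy_atlas.ontology.nodes_at_level(3)
        )

    def test_partition_identity_every_level(self, toy_atlas, um_to_voxel):
        cells = map_cells_to_atlas(random_cells(toy_atlas, 120, seed=5), um_to_voxel, toy_atlas)
        for level in toy_atlas.ontology.levels:
            table = counts_by_level(cells, toy_atlas, level)
            assert table["count"].sum() == len(cells)

    def test_unknown_level_rejected(self, toy_atlas):
        with pytest.raises(ValueError, match="level"):
            counts_by_level(pd.DataFrame({"region_id": []}), toy_atlas, 99)


class TestHemispheres:
    def test_left_plus_right_equals_bilateral(self, toy_atlas, um_to_voxel):
        cells = map_cells_to_atlas(random_cells(toy_atlas, 150, seed=2), um_to_voxel, toy_atlas)
        hemi = hemisphere_counts(cells, toy_atlas, 3)
        lvl = counts_by_level(cells, toy_atlas, 3).groupby("region_id")["count"].sum()
        for _, row in hemi.iterrows():
            assert row["count_L"] + row["count_R"] == row["count_bilateral"]
            assert row["count_bilateral"] == lvl[row["region_id"]]

    def test_mirror_symmetric_cells_balance(self, toy_atlas, um_to_voxel):
        vs = np.asarray(toy_atlas.voxel_size)
        mid = toy_atlas.midline_index
        rows = []
        for d in (1, 4):  # voxel pairs mirror-symmetric about the midline plane
            for vox_x in (mid - 1 - d, mid + d):
                rows.append({"animal": "m1", "z_um": 10 * vs[0], "y_um": 10 * vs[1], "x_um": vox_x * vs[2]})
        cells = map_cells_to_atlas(pd.DataFrame(rows), um_to_voxel, toy_atlas)
        hemi = hemisphere_counts(cells, toy_atlas, 3)
        assert hemi["count_L"].sum() == hemi["count_R"].sum()

    def test_all_left_cells_leave_right_empty(self, toy_atlas, um_to_voxel):
        vs = np.asarray(toy_atlas.voxel_size)
        rows = [
            {"animal": "m1", "z_um": 8 * vs[0], "y_um": 8 * vs[1], "x_um": x * vs[2]}
            for x in range(2, toy_atlas.midline_index - 1)
        ]
        cells = map_cells_to_atlas(pd.DataFrame(rows), um_to_voxel, toy_atlas)
        hemi = hemisphere_counts(cells, toy_atlas, 3)
        assert hemi["count_R"].sum() == 0


class TestLayers:
    def test_volume_ratio_of_constructed_mask(self, layered_atlas):
        ont = layered_atlas.ontology
        leaf = ont.nodes_at_level(3)[0]
        layer_node = ont.children(leaf)[0]
        in_layer = layered_atlas.annotation == layer_node
        mask = np.zeros_like(in_layer, dtype=np.uint8)
        vox = np.argwhere(in_layer)
        half = len(vox) // 2
        mask[tuple(vox[:half].T)] = 1
        empty_cells = pd.DataFrame({"region_id": pd.Series(dtype=int)})
        table = layer_metrics(empty_cells, MaskVolume(mask, layered_atlas.voxel_size), layered_atlas, leaf)
        tag = ont.nodes[layer_node].layer
        got = table.set_index("layer").loc[tag, "volume_ratio"]
        assert got == pytest.approx(half / len(vox))

    def test_empty_mask_zero_everywhere(self, layered_atlas):
        leaf = layered_atlas.ontology.nodes_at_level(3)[0]
        mask = MaskVolume(np.zeros_like(layered_atlas.annotation, dtype=np.uint8), layered_atlas.voxel_size)
        table = layer_metrics(pd.DataFrame({"region_id": pd.Series(dtype=int)}), mask, layered_atlas, leaf)
        assert (table["volume_ratio"] == 0).all()
        assert (table["density_per_mm3"] == 0).all()

    def test_layer_counts_sum_to_parent(self, layered_atlas):
        transform = AffineTransform.scaling([1.0 / v for v in layered_atlas.voxel_size])
        cells = map_cells_to_atlas(random_cells(layered_atlas, 90, seed=13), transform, layered_atlas)
        root = layered_atlas.ontology.root.id
        mask = MaskVolume(np.zeros_like(layered_atlas.annotation, dtype=np.uint8), layered_atlas.voxel_size)
        table = layer_metrics(cells, mask, layered_atlas, root)
        assert table["count"].sum() == (cells["region_id"] != 0).sum()

    def test_parent_without_layers_rejected(self, toy_atlas):
        with pytest.raises(ValueError, match="layer"):
            layer_metrics(pd.DataFrame({"region_id": []}),
                          MaskVolume(np.zeros_like(toy_atlas.annotation, dtype=np.uint8), toy_atlas.voxel_size),
                          toy_atlas, toy_atlas.ontology.root.id)


class TestAPProfile:
    def test_bins_sum_to_region_count(self, toy_atlas, um_to_voxel):
        cells = map_cells_to_atlas(random_cells(toy_atlas, 200, seed=21), um_to_voxel, toy_atlas)
        region = toy_atlas.ontology.nodes_at_level(2)[0]
        prof = ap_profile(cells, toy_atlas, region, n_bins=4)
        labels = toy_atlas.ontology.descendants(region)
        assert prof["count"].sum() == cells["region_id"].isin(labels).sum()

    def test_anterior_tip_cells_fall_in_first_bin(self, toy_atlas, um_to_voxel):
        region = toy_atlas.ontology.nodes_at_level(2)[0]
        labels = toy_atlas.ontology.descendants(region)
        vox = np.argwhere(np.isin(toy_atlas.annotation, labels))
        z_min = vox[:, 0].min()
        tip = vox[vox[:, 0] == z_min][:5]
        vs = np.asarray(toy_atlas.voxel_size)
        cells = pd.DataFrame(
            [{"animal": "m1", "z_um": v[0] * vs[0], "y_um": v[1] * vs[1], "x_um": v[2] * vs[2]} for v in tip]
        )
        mapped = map_cells_to_atlas(cells, um_to_voxel, toy_atlas)
        prof = ap_profile(mapped, toy_atlas, region, n_bins=3)
        per_bin = prof.groupby("ap_bin")["count"].sum()
        assert per_bin[0] == len(tip)
        assert per_bin[1:].sum() == 0

    def test_uniform_cells_roughly_uniform_bins(self, toy_atlas, um_to_voxel):
        cells = map_cells_to_atlas(random_cells(toy_atlas, 400, seed=30), um_to_voxel, toy_atlas)
        region = toy_atlas.ontology.root.id
        prof = ap_profile(cells, toy_atlas, region, n_bins=4)
        per_bin = prof.groupby("ap_bin")["count"].sum()
        n, p = per_bin.sum(), 1 / 4
        sd = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(per_bin - n * p) < 5 * sd)

    def test_too_few_bins_rejected(self, toy_atlas):
        with pytest.raises(ValueError):
            ap_profile(pd.DataFrame({"region_id": []}), toy_atlas, toy_atlas.ontology.root.id, n_bins=1)
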