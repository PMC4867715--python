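import io

import numpy as np
import pytest

from molarmorph.landmark_io import (
    MIRROR_SWAP_PAIRS,
    LandmarkConfiguration,
    LandmarkError,
    TaxonomyMap,
    apply_scale,
    assemble_dataset,
    mirror_permutation,
    read_coordinates_csv,
    read_taxonomy_csv,
    read_tps,
    standardize_side,
    write_coordinates_csv,
    write_tps,
)
from molarmorph.superimposition import procrustes_distance
from molarmorph.synthetic_data import make_template

from conftest import as_config


def tps_record(coords, spec_id="spec1", scale="0.01", side=None):
    lines = [f"LM={len(coords)}"]
    lines += [f"{x} {y}" for x, y in coords]
    lines.append(f"ID={spec_id}")
    if side:
        lines.append(f"SIDE={side}")
    if scale is not None:
        lines.append(f"SCALE={scale}")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def coords15():
    return [(float(i), float(i % 4)) for i in range(15)]


class TestReadTps:
    def test_single_record_fields(self, coords15):
        text = tps_record(coords15, spec_id="spec1", scale="0.01")
        configs = read_tps(io.StringIO(text), "M1")
        assert len(configs) == 1
        c = configs[0]
        assert c.specimen_id == "spec1"
        assert c.scale == 0.01
        assert c.tooth == "M1"
        np.testing.assert_allclose(c.landmarks, coords15)

    def test_multiple_records_preserve_order(self, coords15):
        text = "".join(
            tps_record(coords15, spec_id=f"s{i}") for i in range(3)
        )
        configs = read_tps(io.StringIO(text), "M2")
        assert [c.specimen_id for c in configs] == ["s0", "s1", "s2"]

    def test_wrong_landmark_count_names_record(self, coords15):
        good = tps_record(coords15, spec_id="ok")
        bad = "LM=14\n" + "\n".join(f"{x} {y}" for x, y in coords15[:14]) + "\nID=bad\n"
        with pytest.raises(LandmarkError, match="record 2"):
            read_tps(io.StringIO(good + bad), "M1")

    def test_non_numeric_coordinate(self, coords15):
        text = tps_record(coords15).replace("3.0 3.0", "3.0 oops", 1)
        with pytest.raises(LandmarkError, match="non-numeric"):
            read_tps(io.StringIO(text), "M1")

    def test_empty_file(self):
        with pytest.raises(LandmarkError, match="no landmark records"):
            read_tps(io.StringIO(""), "M1")

    def test_missing_scale_defaults_to_one_with_warning(self, coords15, caplog):
        text = tps_record(coords15, scale=None)
        with caplog.at_level("WARNING"):
            configs = read_tps(io.StringIO(text), "M1")
        assert configs[0].scale == 1.0
        assert any("SCALE" in r.message for r in caplog.records)

    def test_roundtrip(self, tmp_path, coords15):
        original = read_tps(io.StringIO(tps_record(coords15, side="left")), "M1")
        path = tmp_path / "out.tps"
        write_tps(original, path)
        again = read_tps(path, "M1")
        assert again[0].specimen_id == original[0].specimen_id
        assert again[0].side == "left"
        assert again[0].scale == original[0].scale
        np.testing.assert_allclose(again[0].landmarks, original[0].landmarks)

    def test_csv_roundtrip(self, tmp_path, coords15):
        configs = read_tps(io.StringIO(tps_record(coords15)), "M1")
        path = tmp_path / "coords.csv"
        write_coordinates_csv(configs, path)
        again = read_coordinates_csv(path)
        np.testing.assert_allclose(again[0].landmarks, configs[0].landmarks)
        assert again[0].scale == configs[0].scale


class TestConfigurationInvariants:
    def test_coincident_landmarks_rejected(self, coords15):
        coords15[3] = coords15[7]
        with pytest.raises(LandmarkError, match="coincide"):
            as_config(coords15)

    def test_nonfinite_rejected(self, coords15):
        coords15[0] = (np.nan, 0.0)
        with pytest.raises(LandmarkError, match="non-finite"):
            as_config(coords15)

    def test_nonpositive_scale_rejected(self, coords15):
        with pytest.raises(LandmarkError, match="scale"):
            as_config(coords15, scale=0.0)

    def test_wrong_count_rejected(self, coords15):
        with pytest.raises(LandmarkError, match="15"):
            as_config(coords15[:14])


def synthetic_left_antimere(config):
    """What the digitizer records for the left-side mirror image of a tooth."""
    perm = mirror_permutation(MIRROR_SWAP_PAIRS)
    lm = config.landmarks[perm] * np.array([-1.0, 1.0])
    lm = lm - lm.min(axis=0)
    return LandmarkConfiguration(
        specimen_id=config.specimen_id + "_L", tooth=config.tooth,
        side="left", landmarks=lm, scale=config.scale,
    )


class TestStandardizeSide:
    def test_right_is_identity(self, template):
        c = as_config(template)
        assert standardize_side(c) is c

    def test_double_mirror_is_involution(self, template):
        right = as_config(template)
        left = synthetic_left_antimere(right)
        restored = standardize_side(left)
        assert restored.side == "right"
        # translation may differ; shape and landmark order must be identical
        a = restored.landmarks - restored.landmarks.mean(axis=0)
        b = right.landmarks - right.landmarks.mean(axis=0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_mirroring_restores_homology(self, template, rng):
        """Procrustes distance of a mirrored left tooth to its right antimere
        template is tiny after standardization, large before."""
        shape = template + rng.normal(scale=0.05, size=template.shape)
        right = as_config(shape)
        left = synthetic_left_antimere(right)
        before = procrustes_distance(left.landmarks, right.landmarks)
        after = procrustes_distance(standardize_side(left).landmarks, right.landmarks)
        assert after < 1e-9
        assert before > 10 * after

    def test_unknown_side_rejected(self, template):
        c = as_config(template)
        object.__setattr__(c, "side", "top")
        with pytest.raises(LandmarkError, match="side"):
            standardize_side(c)


class TestApplyScale:
    def test_identity_scale(self, template):
        c = as_config(template, scale=1.0)
        assert apply_scale(c) is c

    def test_linearity(self):
        lm = [(2.0 * i, 4.0 * i) for i in range(1, 16)]
        c = as_config(lm, scale=0.5)
        scaled = apply_scale(c)
        np.testing.assert_allclose(scaled.landmarks[1], [2.0, 4.0])
        assert scaled.scale == 1.0

    def test_idempotent_by_contract(self, template):
        once = apply_scale(as_config(template, scale=0.25))
        twice = apply_scale(once)
        np.testing.assert_array_equal(once.landmarks, twice.landmarks)

    def test_commutes_with_mirroring(self, template):
        left = synthetic_left_antimere(as_config(template, scale=1.0))
        left = LandmarkConfiguration(
            specimen_id=left.specimen_id, tooth=left.tooth, side="left",
            landmarks=left.landmarks, scale=0.3,
        )
        a = standardize_side(apply_scale(left)).landmarks
        b = apply_scale(standardize_side(left)).landmarks
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        np.testing.assert_allclose(a, b, atol=1e-12)


def taxonomy_frame(ids, fossil=()):
    import pandas as pd

    rows = []
    for i in ids:
        rows.append(
            {
                "specimen_id": i,
                "species": "Saimiri sciureus",
                "genus": "Saimiri",
                "subfamily_G": "Saimiriinae",
                "subfamily_R": "Cebinae",
                "family": "Cebidae",
                "fossil_flag": i in fossil,
                "fossil_code": "F1" if i in fossil else "",
            }
        )
    return pd.DataFrame(rows)


class TestAssembleDataset:
    def make_configs(self, template, ids, tooth="M1"):
        return [as_config(template + k, specimen_id=i, tooth=tooth) for k, i in enumerate(ids)]

    def test_bookkeeping(self, template):
        configs = self.make_configs(template, ["a", "b", "c", "f1"])
        tax = TaxonomyMap(taxonomy_frame(["a", "b", "c", "f1"], fossil={"f1"}))
        ds = assemble_dataset(configs, tax, "M1")
        assert len(ds.configurations) == 4
        assert ds.fossil_ids == ["f1"]
        assert ds.extant_ids == ["a", "b", "c"]

    def test_missing_extant_named(self, template):
        configs = self.make_configs(template, ["a", "b"])
        tax = TaxonomyMap(taxonomy_frame(["a"]))
        with pytest.raises(LandmarkError, match="b"):
            assemble_dataset(configs, tax, "M1")

    def test_duplicate_ids_rejected(self, template):
        configs = self.make_configs(template, ["a", "a"])
        tax = TaxonomyMap(taxonomy_frame(["a"]))
        with pytest.raises(LandmarkError, match="duplicate"):
            assemble_dataset(configs, tax, "M1")

    def test_mixed_teeth_rejected(self, template):
        configs = self.make_configs(template, ["a"]) + self.make_configs(
            template, ["b"], tooth="M2"
        )
        tax = TaxonomyMap(taxonomy_frame(["a", "b"]))
        with pytest.raises(LandmarkError, match="teeth"):
            assemble_dataset(configs, tax, "M1")


class TestTaxonomyMap:
    def test_unknown_subfamily_rejected(self):
        frame = taxonomy_frame(["a"])
        frame.loc[0, "subfamily_G"] = "Madeupinae"
        with pytest.raises(LandmarkError, match="subfamily_G"):
            TaxonomyMap(frame)

    def test_csv_roundtrip(self, tmp_path):
        frame = taxonomy_frame(["a", "b", "f1"], fossil={"f1"})
        path = tmp_path / "tax.csv"
        frame.to_csv(path, index=False)
        tax = read_taxonomy_csv(path)
        assert tax.is_fossil("f1")
        assert list(tax.labels("genus", ["a", "b"])) == ["Saimiri", "Saimiri"]
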