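"""BSI scoring: component-to-bone matching by plurality, area ratios,
ICRP-style weighting, view fusion and exact agreement with phantom truth.
Synthetic weight tables are used so correctness never depends on the
shipped clinical values."""

import numpy as np
import pytest

from scintibsi.bsi import (BoneWeightTable, bone_ratio, compute_bsi,
                           default_weight_table, match_hotspots_to_bones)
from scintibsi.labels import (ANTERIOR_CLASSES, ANTERIOR_INDEX, METASTATIC,
                              POSTERIOR_INDEX, SkeletonLabelMap)
from scintibsi.phantom import PhantomSpec, generate_phantom

FEMUR = ANTERIOR_INDEX["femur"]
RIB = ANTERIOR_INDEX["rib"]
SCAPULA = ANTERIOR_INDEX["scapula"]


def _blank(shape=(40, 40)):
    return np.zeros(shape, dtype=np.uint8)


def _table(**kwargs):
    entries = {name: 0.05 for name in ANTERIOR_CLASSES[1:]}
    entries.update(kwargs)
    return BoneWeightTable(entries=entries, provenance="synthetic test table")


# --- matching ----------------------------------------------------------------

def test_lesion_inside_single_bone():
    skel, hot = _blank(), _blank()
    skel[10:20, 10:20] = FEMUR
    hot[12:14, 12:14] = METASTATIC
    assigned, excluded = match_hotspots_to_bones(hot, skel, ANTERIOR_CLASSES)
    assert len(assigned) == 1 and not excluded
    assert assigned[0]["bone"] == "femur"
    assert assigned[0]["area_px"] == 4


def test_plurality_assignment():
    skel, hot = _blank(), _blank()
    skel[0:10, 0:30] = RIB
    skel[10:20, 0:30] = SCAPULA
    hot[7:12, 0:10] = METASTATIC  # 30 px on rib, 20 px on scapula
    assigned, _ = match_hotspots_to_bones(hot, skel, ANTERIOR_CLASSES)
    assert assigned[0]["bone"] == "rib"


def test_background_only_component_excluded():
    skel, hot = _blank(), _blank()
    hot[5:8, 5:8] = METASTATIC
    assigned, excluded = match_hotspots_to_bones(hot, skel, ANTERIOR_CLASSES)
    assert not assigned
    assert len(excluded) == 1 and excluded[0]["area_px"] == 9


def test_matching_requires_coregistration():
    with pytest.raises(ValueError):
        match_hotspots_to_bones(_blank((10, 10)), _blank((20, 20)),
                                ANTERIOR_CLASSES)


# --- ratios ------------------------------------------------------------------

@pytest.mark.parametrize("hot,bone,expected", [(50, 1000, 0.05), (0, 1000, 0.0),
                                               (1000, 1000, 1.0),
                                               (2000, 1000, 1.0)])
def test_bone_ratio_values(hot, bone, expected):
    assert bone_ratio(hot, bone) == pytest.approx(expected)


def test_bone_ratio_zero_bone_area_rejected():
    with pytest.raises(ValueError):
        bone_ratio(10, 0)
    assert bone_ratio(0, 0) == 0.0


# --- compute_bsi -------------------------------------------------------------

def _dual(skel_ant, hot_ant, skel_post=None, hot_post=None):
    skel = SkeletonLabelMap(anterior=skel_ant,
                            posterior=skel_post if skel_post is not None
                            else _blank(skel_ant.shape))
    hot = {"anterior": hot_ant,
           "posterior": hot_post if hot_post is not None
           else _blank(hot_ant.shape)}
    return skel, hot


def test_single_view_arithmetic():
    # one bone, weight 0.1, ratio 0.5, anterior only -> BSI = 100*0.1*0.5 = 5
    skel, hot = _blank((50, 50)), _blank((50, 50))
    skel[0:20, 0:50] = ANTERIOR_INDEX["sternum"]  # anterior-only bone
    hot[0:10, 0:50] = METASTATIC
    table = _table(sternum=0.1)
    report = compute_bsi(*_dual(skel, hot), table)
    assert report.total_bsi == pytest.approx(5.0)


def test_spec_example_lesion_50px_in_1000px_bone():
    # weight 0.1, 50/1000 in both views -> mean of equal views = 0.5%
    skel, hot = _blank((50, 50)), _blank((50, 50))
    skel[0:20, 0:50] = FEMUR
    hot[0:1, 0:50] = METASTATIC
    skel_p = _blank((50, 50))
    skel_p[0:20, 0:50] = POSTERIOR_INDEX["femur"]
    hot_p = _blank((50, 50))
    hot_p[0:1, 0:50] = METASTATIC
    report = compute_bsi(*_dual(skel, hot, skel_p, hot_p), _table(femur=0.1))
    assert report.total_bsi == pytest.approx(100 * 0.1 * 50 / 1000)


def test_no_lesions_gives_zero():
    skel = _blank()
    skel[5:15, 5:15] = FEMUR
    report = compute_bsi(*_dual(skel, _blank()), _table())
    assert report.total_bsi == 0.0


def test_contributions_add_across_bones():
    skel, hot = _blank((60, 60)), _blank((60, 60))
    skel[0:10, 0:40] = FEMUR
    skel[30:40, 0:40] = ANTERIOR_INDEX["pelvis"]
    hot[0:2, 0:20] = METASTATIC
    hot[30:32, 0:20] = METASTATIC
    table = _table(femur=0.12, pelvis=0.10)
    both = compute_bsi(*_dual(skel, hot), table).total_bsi
    only_f = hot.copy(); only_f[30:32] = 0
    only_p = hot.copy(); only_p[0:2] = 0
    f = compute_bsi(*_dual(skel, only_f), table).total_bsi
    p = compute_bsi(*_dual(skel, only_p), table).total_bsi
    assert both == pytest.approx(f + p)


def test_view_fusion_averages_common_bones():
    skel_a, hot_a = _blank(), _blank()
    skel_a[0:10, 0:10] = FEMUR
    hot_a[0:2, 0:10] = METASTATIC          # anterior ratio 0.2
    skel_p, hot_p = _blank(), _blank()
    skel_p[0:10, 0:10] = POSTERIOR_INDEX["femur"]
    hot_p[0:4, 0:10] = METASTATIC          # posterior ratio 0.4
    report = compute_bsi(*_dual(skel_a, hot_a, skel_p, hot_p), _table(femur=0.1))
    assert report.total_bsi == pytest.approx(100 * 0.1 * 0.3)  # mean of views


def test_overlap_class_split_between_rib_and_scapula():
    skel_p, hot_p = _blank(), _blank()
    ov = POSTERIOR_INDEX["rib_scapula_overlap"]
    skel_p[0:10, 0:10] = ov                # 100 px -> 50 rib + 50 scapula
    hot_p[0:2, 0:10] = METASTATIC          # 20 px -> 10 rib + 10 scapula
    table = _table(rib=0.2, scapula=0.1)
    report = compute_bsi(*_dual(_blank(), _blank(), skel_p, hot_p), table)
    # each bone: ratio (10/50) = 0.2 -> contributions 100*(0.2+0.1)*0.2
    assert report.total_bsi == pytest.approx(100 * 0.2 * (0.2 + 0.1))


def test_missing_table_entry_names_the_bone():
    skel, hot = _blank(), _blank()
    skel[0:10, 0:10] = FEMUR
    hot[0:2, 0:10] = METASTATIC
    table = BoneWeightTable(entries={"rib": 0.1}, provenance="partial")
    with pytest.raises(KeyError, match="femur"):
        compute_bsi(*_dual(skel, hot), table)


def test_weight_fraction_bounds_validated():
    with pytest.raises(ValueError):
        BoneWeightTable(entries={"femur": 1.5})
    with pytest.raises(ValueError):
        BoneWeightTable(entries={"femur": 0.0})


def test_default_table_covers_all_bones():
    table = default_weight_table()
    for name in ANTERIOR_CLASSES[1:]:
        assert name in table
        assert 0 < table[name] < 1


# --- invariants on phantom truth ---------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_bsi_identity_on_phantom_truth(seed):
    case = generate_phantom(PhantomSpec(seed=seed, image_height_px=240,
                                        image_width_px=120))
    report = compute_bsi(case.skeleton_truth,
                         {"anterior": case.hotspot_truth_anterior,
                          "posterior": case.hotspot_truth_posterior},
                         default_weight_table())
    assert report.total_bsi == case.true_bsi


def test_bsi_monotone_in_lesion_area():
    skel = _blank((50, 50))
    skel[0:30, 0:30] = FEMUR
    table = _table(femur=0.1)
    values = []
    for rows in (2, 5, 10, 20):
        hot = _blank((50, 50))
        hot[0:rows, 0:30] = METASTATIC
        values.append(compute_bsi(*_dual(skel, hot), table).total_bsi)
    assert all(a < b for a, b in zip(values, values[1:]))


def test_bsi_upper_bound(small_case):
    table = default_weight_table()
    report = compute_bsi(small_case.skeleton_truth,
                         {"anterior": small_case.hotspot_truth_anterior,
                          "posterior": small_case.hotspot_truth_posterior},
                         table)
    involved = [b for b, row in report.per_bone.items() if row["contribution"] > 0]
    assert report.total_bsi <= 100 * sum(table[b] for b in involved) + 1e-9
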