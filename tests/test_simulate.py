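"""Synthetic telemetry generator: determinism, design invariants, and
recoverability of the planted structure."""

import warnings

import numpy as np
import pandas as pd
import pytest

from geosomtrack import cooccur, io, movement, neighbors, simulate


def small_config(**kw):
    defaults = dict(seed=99, n_females=4, n_males=4, n_rounds=3,
                    extent=simulate.SiteExtent(length=3000.0, width=400.0))
    defaults.update(kw)
    return simulate.SimulationConfig(**defaults)


def test_same_seed_bit_identical_output():
    cfg = small_config()
    hmap = simulate.generate_habitat_map(cfg)
    f1, t1 = simulate.simulate_trajectories(cfg, hmap)
    f2, t2 = simulate.simulate_trajectories(cfg, hmap)
    pd.testing.assert_frame_equal(f1, f2)
    assert t1.keep_prob == t2.keep_prob


def test_habitat_map_deterministic_and_covers_all_labels():
    cfg = small_config()
    m1 = simulate.generate_habitat_map(cfg)
    m2 = simulate.generate_habitat_map(cfg)
    assert len(m1.patches) == len(m2.patches)
    for (l1, p1), (l2, p2) in zip(m1.patches, m2.patches):
        assert l1 == l2 and p1.equals(p2)
    assert m1.labels_present() == set(io.HABITAT_LABELS)


def test_vegetation_patches_tile_without_overlap():
    cfg = small_config()
    hmap = simulate.generate_habitat_map(cfg)
    veg = [p for lab, p in hmap.patches if lab in io.VEGETATION_LABELS]
    total = sum(p.area for p in veg)
    from shapely.ops import unary_union
    union = unary_union(veg)
    assert union.area == pytest.approx(total, rel=1e-9)
    assert union.area == pytest.approx(cfg.extent.area, rel=1e-6)


def test_extent_too_small_rejected():
    cfg = small_config(extent=simulate.SiteExtent(length=100.0, width=30.0))
    with pytest.raises(ValueError, match="too small"):
        simulate.generate_habitat_map(cfg)


def test_empty_population_rejected():
    with pytest.raises(ValueError, match="empty population"):
        simulate.SimulationConfig(n_females=0, n_males=0)


def test_reference_dataset_design(reference):
    fixes, hmap, temps, truth = reference
    assert fixes["individual_id"].nunique() == 24
    sexes = fixes.groupby("individual_id")["sex"].first()
    assert (sexes == "F").sum() == 12 and (sexes == "M").sum() == 12
    assert sorted(fixes["survey_round"].unique()) == list(range(1, 13))
    assert len(temps) == 12


def test_reference_speed_moments_near_field_values(reference):
    fixes, *_ = reference
    steps = movement.compute_steps_all(fixes)
    summary = movement.movement_summary(steps)
    # within 25% of the field campaign's 48.3 / 96.2 m/h
    assert 48.3 * 0.75 <= summary["mean_speed"] <= 48.3 * 1.25
    assert 96.2 * 0.75 <= summary["sd_speed"] <= 96.2 * 1.25


def test_fixes_inside_extent_and_times_increasing(reference):
    fixes, *_ = reference
    ext = simulate.SimulationConfig().extent
    u, v = ext.to_local(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    assert u.min() >= -1e-6 and u.max() <= ext.length + 1e-6
    assert v.min() >= -1e-6 and v.max() <= ext.width + 1e-6
    for _, grp in fixes.groupby("individual_id"):
        assert grp["timestamp"].is_monotonic_increasing
        assert not grp["timestamp"].duplicated().any()


def test_speeds_nonnegative(reference):
    fixes, *_ = reference
    steps = movement.compute_steps_all(fixes)
    assert (steps["linear_speed"] >= 0).all()


def test_p_move_zero_with_no_plan_freezes_everyone():
    cfg = small_config(p_move=0.0, association_plan=())
    hmap = simulate.generate_habitat_map(cfg)
    fixes, _ = simulate.simulate_trajectories(cfg, hmap)
    steps = movement.compute_steps_all(fixes)
    assert (steps["linear_speed"] == 0).all()


def test_large_turn_kappa_concentrates_headings():
    def resultant(kappa):
        cfg = small_config(turn_kappa=kappa, association_plan=(),
                           home_strength=0.0,
                           keep_prob_range=(1.0, 1.0), p_move=1.0,
                           extent=simulate.SiteExtent(length=500_000.0,
                                                      width=400_000.0))
        hmap = simulate.generate_habitat_map(cfg)
        fixes, _ = simulate.simulate_trajectories(cfg, hmap)
        turns = []
        for _, grp in fixes.groupby("individual_id"):
            steps = movement.compute_steps(grp)
            turns.extend(steps["turning_angle"].dropna().tolist())
        return movement.rayleigh_r(np.asarray(turns))

    assert resultant(50.0) > resultant(0.01) + 0.2


def test_planted_attraction_beats_areal_null(reference):
    """Different-sex co-occurrence concentrates in the planted habitat
    relative to its areal share; with strength 0 it does not."""
    fixes, hmap, temps, truth = reference
    rate_on = _fm_rate_in_tg(fixes, hmap)
    null = _tg_area_share(hmap)

    cfg = simulate.SimulationConfig(
        association_plan=tuple(
            simulate.AssociationRule(r.pair_class, r.habitat, r.months,
                                     strength=0.0, n_pairs=r.n_pairs,
                                     days=r.days)
            for r in simulate.REFERENCE_PLAN))
    hmap0 = simulate.generate_habitat_map(cfg)
    fixes0, _ = simulate.simulate_trajectories(cfg, hmap0)
    rate_off = _fm_rate_in_tg(fixes0, hmap0)

    assert rate_on > 2 * null
    assert rate_off < rate_on / 2


def _fm_rate_in_tg(fixes, hmap):
    snaps = neighbors.build_snapshots(fixes)
    ev = cooccur.detect(snaps, 250.0)
    fm = ev[ev["pair_class"] == "FM"]
    if not len(fm):
        return 0.0
    pos = {(s.snapshot_time, m.individual_id): (m.x, m.y)
           for s in snaps for m in s.members.itertuples()}
    pts = pd.DataFrame({
        "x": [(pos[(t, a)][0] + pos[(t, b)][0]) / 2
              for t, a, b in zip(fm.snapshot_time, fm.id_a, fm.id_b)],
        "y": [(pos[(t, a)][1] + pos[(t, b)][1]) / 2
              for t, a, b in zip(fm.snapshot_time, fm.id_a, fm.id_b)],
        "individual_id": "x", "sex": "F",
        "timestamp": fm.snapshot_time.values, "survey_round": 1})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ann = io.annotate_habitat(pts, hmap)
    return float(ann["TG"].mean())


def _tg_area_share(hmap):
    areas = {}
    for lab, p in hmap.patches:
        areas[lab] = areas.get(lab, 0.0) + p.area
    veg = sum(v for k, v in areas.items() if k in io.VEGETATION_LABELS)
    return areas.get("TG", 0.0) / veg


def test_truth_serialization_round_trip(tmp_path, reference):
    *_, truth = reference
    path = tmp_path / "truth.json"
    truth.to_json(path)
    import json
    payload = json.loads(path.read_text())
    assert {r["pair_class"] for r in payload["rules"]} == {"FM", "FF", "MM"}
    assert len(payload["keep_prob"]) == 24
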