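"""Region-based normalized quantification on phantoms with known truth."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ovotools import regionquant as rq
from ovotools import segment3d as s3
from ovotools import synthgen as sg


def uniform_stack(shape=(6, 20, 20), value=3.0):
    return s3.ImageStack(
        data={"yolk": np.full(shape, value), "histone": np.full(shape, value)},
        voxel_size=(1.0, 1.0, 1.0),
    )


class TestOocyteTotalIntensity:
    def test_uniform_mask_exact(self):
        stack = uniform_stack(value=3.0)
        mask = np.zeros((6, 20, 20), bool)
        mask[1:4, 5:10, 5:10] = True
        total = rq.oocyte_total_intensity(stack, mask, midsection_z=3, channel="yolk")
        assert total == 3.0 * mask[:4].sum()

    def test_halving_midsection_monotone(self):
        rng = np.random.default_rng(0)
        stack = s3.ImageStack(
            data={"yolk": rng.random((8, 10, 10))}, voxel_size=(1, 1, 1)
        )
        mask = rng.random((8, 10, 10)) > 0.3
        t_deep = rq.oocyte_total_intensity(stack, mask, 6, "yolk")
        t_shallow = rq.oocyte_total_intensity(stack, mask, 3, "yolk")
        assert t_shallow <= t_deep

    def test_constant_uptake_rate_recovered(self):
        # yolk accumulating linearly: total(t) = rate * t over a fixed mask
        rate = 12.5
        mask = np.zeros((6, 12, 12), bool)
        mask[:4, 4:8, 4:8] = True
        times = np.arange(1, 11, dtype=float)
        totals = []
        for t in times:
            conc = rate * t / mask[:4].sum()
            vol = np.where(mask, conc, 0.0)
            stack = s3.ImageStack(data={"yolk": vol}, voxel_size=(1, 1, 1))
            totals.append(rq.oocyte_total_intensity(stack, mask, 3, "yolk"))
        slope = np.polyfit(times, totals, 1)[0]
        assert slope == pytest.approx(rate, rel=0.05)

    def test_empty_mask_rejected(self):
        stack = uniform_stack()
        with pytest.raises(ValueError):
            rq.oocyte_total_intensity(
                stack, np.zeros((6, 20, 20), bool), 3, "yolk"
            )


class TestNormalizeByFollicle:
    def test_self_reference_is_one(self):
        frame = np.full((4, 8, 8), 5.0)
        mask = np.zeros((4, 8, 8), bool)
        mask[1, 2:4, 2:4] = True
        assert rq.normalize_by_follicle(5.0, mask, frame, "mean") == 1.0

    @given(st.floats(min_value=0.1, max_value=1000.0))
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(0)
        frame = rng.random((4, 8, 8)) + 0.5
        mask = rng.random((4, 8, 8)) > 0.6
        raw = float(frame[1, 3, 3])
        base = rq.normalize_by_follicle(raw, mask, frame, "mean")
        scaled = rq.normalize_by_follicle(gain * raw, mask, gain * frame, "mean")
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_bleaching_phantom_flat_series(self):
        # static compartments under global exponential bleaching: the
        # normalized value is constant over time
        rng = np.random.default_rng(1)
        frame0 = rng.random((4, 8, 8)) + 1.0
        mask = rng.random((4, 8, 8)) > 0.6
        raw_region = np.zeros((4, 8, 8), bool)
        raw_region[2, 5:7, 5:7] = True
        values = []
        for t in range(5):
            decay = np.exp(-0.3 * t)
            frame = frame0 * decay
            raw = float(frame[raw_region].mean())
            values.append(rq.normalize_by_follicle(raw, mask, frame, "mean"))
        assert np.ptp(values) < 1e-12

    def test_zero_reference_rejected(self):
        frame = np.zeros((4, 8, 8))
        mask = np.ones((4, 8, 8), bool)
        with pytest.raises(ValueError):
            rq.normalize_by_follicle(1.0, mask, frame, "mean")


@pytest.fixture(scope="module")
def geo(dumping_series):
    return dumping_series.geometry[4]


class TestRoiPlacement:
    def test_ncc_roi_is_nuclear_free(self, geo, dumping_series):
        shape = dumping_series.frames[4].shape
        roi = rq.place_region_roi(shape, rq.RegionSpec("NCC", roi_edge_px=6), geo)
        assert not roi.contains_any(geo["nuclei"])

    def test_distance_constraints(self, geo, dumping_series):
        shape = dumping_series.frames[4].shape
        vox = geo["voxel_size"]
        comp = geo["compartments"]
        for reg in ("AO", "PO"):
            roi = rq.place_region_roi(shape, rq.RegionSpec(reg, roi_edge_px=6), geo)
            mid_z = roi.z_slices[1]
            cy = (roi.y0 + roi.edge / 2) * vox[1]
            cx = (roi.x0 + roi.edge / 2) * vox[2]
            if reg == "AO":
                # oocyte voxels whose anterior (-x) neighbour is nurse cytoplasm
                border = (comp == 2) & np.roll(comp == 1, 1, axis=2)
                bz, by, bx = np.nonzero(border)
            else:
                ooc = comp[mid_z] == 2
                xs = np.nonzero(ooc.any(axis=0))[0]
                by, bx = np.nonzero(ooc & (np.arange(comp.shape[2]) >= xs[-1] - 1))
                bz = np.full_like(by, mid_z)
            sel = bz == mid_z
            d = np.hypot(by[sel] * vox[1] - cy, bx[sel] * vox[2] - cx).min()
            assert d <= 17.0 + roi.edge * max(vox[1:])  # centroid constraint

    def test_rois_inside_ground_truth_compartments(self, geo, dumping_series):
        shape = dumping_series.frames[4].shape
        for reg, key in (("AO", "ao_region"), ("PO", "po_region")):
            roi = rq.place_region_roi(shape, rq.RegionSpec(reg, roi_edge_px=6), geo)
            sub = geo[key][
                list(roi.z_slices),
                roi.y0 : roi.y0 + roi.edge,
                roi.x0 : roi.x0 + roi.edge,
            ]
            assert sub.all()

    def test_impossible_placement_names_region(self, geo, dumping_series):
        shape = dumping_series.frames[4].shape
        with pytest.raises(ValueError, match="NCC"):
            rq.place_region_roi(
                shape, rq.RegionSpec("NCC", roi_edge_px=500), geo
            )


class TestRegionTimeseries:
    def test_nuclear_totals_strictly_decline(self, dumping_region_series):
        ncn = dumping_region_series["NCN"].to_numpy()
        assert np.all(np.diff(ncn) < 0)

    def test_cytoplasmic_series_rise_then_fall(self, dumping_region_series):
        for reg in ("NCC", "AO"):
            v = dumping_region_series[reg].to_numpy()
            i = int(np.argmax(v))
            assert 0 < i < len(v) - 1
            assert np.all(np.diff(v[: i + 1]) > 0)
            assert np.all(np.diff(v[i:]) < 0)

    def test_posterior_rise_delayed_after_anterior(self, dumping_region_series):
        ao = dumping_region_series["AO"].to_numpy()
        po = dumping_region_series["PO"].to_numpy()
        t = dumping_region_series.index.to_numpy()
        t_ao = t[np.argmax(ao >= ao.max() / 2)]
        t_po = t[np.argmax(po >= po.max() / 2)]
        assert t_po > t_ao

    def test_static_phantom_series_constant(self, dumping_series):
        frames = [dumping_series.frames[0]] * 6
        geometry = [dumping_series.geometry[0]] * 6
        specs = [rq.RegionSpec("NCC", roi_edge_px=6)]
        ts = rq.region_timeseries(frames, specs, geometry, frame_stride=2)
        assert np.ptp(ts["normalized"].to_numpy()) == 0.0

    def test_missing_geometry_rejected(self, dumping_series):
        specs = [rq.RegionSpec("NCC", roi_edge_px=6)]
        geometry = [None] * len(dumping_series.frames)
        with pytest.raises(ValueError, match="geometry"):
            rq.region_timeseries(dumping_series.frames, specs, geometry, 5)


class TestNuclearConcentration:
    def test_volume_decay_faster_than_intensity_gives_transient_rise(self):
        t = np.linspace(0, 3, 20)
        totals = np.exp(-1.0 * t)
        volumes = np.exp(-1.6 * t)
        df = rq.nuclear_concentration_series(totals, volumes, t)
        conc = df["concentration"].to_numpy()
        assert np.all(np.diff(conc) > 0)  # exp((1.6-1.0) t) is increasing

    def test_equal_rates_constant_concentration(self):
        t = np.linspace(0, 3, 10)
        df = rq.nuclear_concentration_series(
            np.exp(-t), np.exp(-t), t
        )
        assert np.ptp(df["concentration"].to_numpy()) < 1e-12

    def test_zero_shrink_concentration_tracks_total(self):
        t = np.linspace(0, 3, 10)
        totals = np.exp(-0.8 * t)
        df = rq.nuclear_concentration_series(totals, np.ones_like(t), t)
        np.testing.assert_allclose(df["concentration"], totals)

    def test_vanished_nucleus_terminates_series(self):
        df = rq.nuclear_concentration_series(
            [3.0, 2.0, 1.0, 0.5], [2.0, 1.0, 0.0, 0.0]
        )
        assert len(df) == 2
        assert bool(df["terminated"].iloc[-1])

    def test_dumping_phantom_concentration_has_transient_rise(self, dumping_series):
        tr = dumping_series.truth
        conc = (tr["nuclear_total"] / tr["nuclear_volume_um3"]).to_numpy()
        # shrink rate (2.0/h) exceeds intensity loss (1.5/h): concentration
        # rises before the sub-voxel volume floor takes over
        assert conc[1] > conc[0]
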