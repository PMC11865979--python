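"""Preprocessing operators: autoscale, SNV, resampling, peaks, RT, mobility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemfuse.core import AxisGrid, Chromatogram, FeatureBlock, Plasmagram, ValidationError
from chemfuse.preprocess import (
    MobilityCalibration,
    autoscale_apply,
    autoscale_fit,
    detect_peaks,
    drift_to_K0,
    extract_rt,
    resample,
    snv,
    snv_block,
)
from chemfuse.synth import default_instrument, default_templates, generate_plasmagram


# ---------------------------------------------------------------------------
# Autoscaling
# ---------------------------------------------------------------------------

def test_autoscale_postconditions():
    rng = np.random.default_rng(0)
    block = FeatureBlock("x", rng.normal(5.0, 2.0, size=(20, 6)))
    model = autoscale_fit(block)
    out = autoscale_apply(block, model)
    assert np.allclose(out.matrix.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(out.matrix.std(axis=0, ddof=1), 1.0, atol=1e-12)
    assert any(p.startswith("autoscale") for p in out.provenance)


def test_autoscale_drops_near_zero_variance_columns():
    rng = np.random.default_rng(1)
    X = rng.normal(0.0, 1.0, size=(15, 4))
    X[:, 2] = 3.0 + rng.normal(0.0, 1e-6, size=15)  # ~constant column
    model = autoscale_fit(FeatureBlock("x", X))
    assert model.kept.tolist() == [True, True, False, True]
    out = autoscale_apply(FeatureBlock("x", X), model)
    assert out.matrix.shape == (15, 3)


def test_autoscale_apply_uses_training_statistics():
    rng = np.random.default_rng(2)
    train = FeatureBlock("x", rng.normal(size=(10, 3)))
    test = FeatureBlock("x", rng.normal(size=(4, 3)))
    model = autoscale_fit(train)
    out = autoscale_apply(test, model)
    expected = (test.matrix - model.means) / model.sds
    assert np.allclose(out.matrix, expected)


def test_autoscale_errors():
    with pytest.raises(ValidationError):
        autoscale_fit(FeatureBlock("x", np.ones((1, 3))))  # < 2 samples
    with pytest.raises(ValidationError):
        autoscale_fit(FeatureBlock("x", np.ones((5, 3))))  # all-constant
    with pytest.raises(ValidationError):
        autoscale_fit(FeatureBlock("x", np.random.default_rng(0).normal(size=(5, 3))),
                      rel_var_floor=1.5)
    model = autoscale_fit(FeatureBlock("x", np.random.default_rng(0).normal(size=(5, 3))))
    with pytest.raises(ValidationError):
        autoscale_apply(FeatureBlock("x", np.ones((2, 4))), model)  # width mismatch


# ---------------------------------------------------------------------------
# SNV
# ---------------------------------------------------------------------------

def test_snv_postconditions():
    x = np.array([1.0, 4.0, 2.0, 8.0])
    y = snv(x)
    assert abs(y.mean()) < 1e-12
    assert abs(y.std(ddof=1) - 1.0) < 1e-12


@settings(max_examples=50, deadline=None)
@given(
    values=st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40),
    a=st.floats(0.01, 100.0),
    b=st.floats(-50.0, 50.0),
)
def test_snv_idempotent_and_affine_invariant(values, a, b):
    x = np.asarray(values)
    if x.std(ddof=1) < 1e-6:
        return  # SNV undefined for (near-)constant rows
    y = snv(x)
    assert np.allclose(snv(y), y, atol=1e-9)          # idempotence
    assert np.allclose(snv(a * x + b), y, atol=1e-7)  # positive affine invariance


def test_snv_errors():
    with pytest.raises(ValidationError):
        snv(np.ones(5))  # constant
    with pytest.raises(ValidationError):
        snv(np.ones((2, 2)))  # not 1-D
    with pytest.raises(ValidationError):
        snv(np.array([1.0]))  # too short


def test_snv_block_rowwise():
    block = FeatureBlock("s", np.array([[1.0, 2.0, 3.0], [10.0, 0.0, 5.0]]))
    out = snv_block(block)
    for row_in, row_out in zip(block.matrix, out.matrix):
        assert np.allclose(row_out, snv(row_in))
    assert "snv" in out.provenance


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def test_resample_linear_exact_on_lines():
    src = AxisGrid(np.linspace(0.0, 10.0, 11), "s")
    dst = AxisGrid(np.linspace(0.5, 9.5, 19), "s")
    values = 3.0 * src.values + 1.0
    out = resample(values, src, dst)
    assert np.allclose(out, 3.0 * dst.values + 1.0)


def test_resample_refuses_extrapolation_and_unit_mix():
    src = AxisGrid(np.linspace(0.0, 10.0, 11), "s")
    with pytest.raises(ValidationError):
        resample(np.zeros(11), src, AxisGrid(np.linspace(-1.0, 5.0, 5), "s"))
    with pytest.raises(ValidationError):
        resample(np.zeros(11), src, AxisGrid(np.linspace(1.0, 5.0, 5), "ms"))
    with pytest.raises(ValidationError):
        resample(np.zeros(10), src, src)


# ---------------------------------------------------------------------------
# Mobility conversion and peak detection
# ---------------------------------------------------------------------------

def test_drift_to_K0_single_reference():
    calib = MobilityCalibration(reference_peak_K0=2.2, reference_drift_time=10.0)
    assert drift_to_K0(10.0, calib) == pytest.approx(2.2)
    # K0 inversely proportional to drift time
    assert drift_to_K0(20.0, calib) == pytest.approx(1.1)
    # round trip through the inverse used by the generator
    assert calib.drift_time_for(drift_to_K0(12.5, calib)) == pytest.approx(12.5)
    with pytest.raises(ValidationError):
        drift_to_K0(0.0, calib)
    with pytest.raises(ValidationError):
        MobilityCalibration(-1.0, 10.0)


def test_detect_peaks_finds_analyte_and_rip():
    instrument = default_instrument()
    plasma = generate_plasmagram(default_templates()["tatp"], 500.0, seed=5)
    peaks = detect_peaks(plasma, instrument.mobility_cal)
    K0s = [p.reduced_mobility for p in peaks]
    assert any(abs(k - 2.06) < 0.02 for k in K0s)   # TATP peak
    assert any(abs(k - 2.2) < 0.02 for k in K0s)    # reactant-ion peak
    assert all(p.intensity > 1.0 for p in peaks)


def test_detect_peaks_intensity_floor():
    grid = AxisGrid(np.linspace(5.0, 16.0, 200), "ms")
    current = 0.5 * np.exp(-0.5 * ((grid.values - 9.0) / 0.1) ** 2)  # below 1 nA
    plasma = Plasmagram(grid, current)
    calib = MobilityCalibration(2.2, 10.0)
    assert detect_peaks(plasma, calib) == []
    assert len(detect_peaks(plasma, calib, min_intensity=0.2)) == 1


# ---------------------------------------------------------------------------
# Retention-time extraction
# ---------------------------------------------------------------------------

def test_extract_rt_subgrid_apex():
    t = AxisGrid(np.arange(0.0, 120.0, 0.5), "s")
    for apex in (60.0, 60.17, 59.83):
        sig = np.exp(-0.5 * ((t.values - apex) / 1.5) ** 2)
        rt = extract_rt(Chromatogram(t, sig))
        # parabola-vertex refinement recovers the apex below the 0.5 s grid
        assert rt == pytest.approx(apex, abs=0.01)


def test_extract_rt_flat_chromatogram_rejected():
    t = AxisGrid(np.arange(0.0, 10.0, 0.5), "s")
    with pytest.raises(ValidationError):
        extract_rt(Chromatogram(t, np.ones(t.n)))


def test_extract_rt_boundary_maximum_falls_back_to_grid():
    t = AxisGrid(np.arange(0.0, 10.0, 0.5), "s")
    sig = np.linspace(0.0, 1.0, t.n)  # maximum at the last grid point
    assert extract_rt(Chromatogram(t, sig)) == pytest.approx(t.values[-1])
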