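import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osseowave.mechanobio import (
    Fate,
    Thresholds,
    Transport,
    classify_fate,
    classify_transport,
    distortion_flag,
    zone_fractions,
)

TH = Thresholds()


def reference_fate(s: float, g: float, th: Thresholds = TH) -> int:
    """Independent scalar truth-table implementation of the fate rules."""
    if abs(s) < th.osteo_min:
        return Fate.QUIESCENT
    if s < -th.chondro_max:
        return Fate.OVERLOAD
    if s > th.fibro_tension_min:
        return Fate.FIBROGENIC
    if g > th.shear_split:
        return Fate.FIBROGENIC if s > 0 else Fate.CHONDROGENIC
    # low shear
    if s < -th.osteo_compress_max:
        return Fate.CHONDROGENIC
    if s > th.osteo_max:
        return Fate.FIBROGENIC
    return Fate.OSTEOGENIC


@pytest.mark.parametrize(
    "sigma, shear, expected",
    [
        (-0.10e6, 0.01, Fate.OSTEOGENIC),    # moderate compression, low shear
        (+0.70e6, 0.01, Fate.FIBROGENIC),    # favorable fibrogenic tension
        (-1.00e6, 0.06, Fate.CHONDROGENIC),  # strong compression, high shear
        (-1e3, 0.0, Fate.QUIESCENT),         # below the activity floor
        (-3.0e6, 0.01, Fate.OVERLOAD),
    ],
)
def test_documented_fate_examples(sigma, shear, expected):
    assert classify_fate(np.array([sigma]), np.array([shear]))[0] == expected


class TestBoundaries:
    """Boundary membership: closed on the osteogenic side."""

    def test_compressive_osteogenic_ceiling(self):
        at = classify_fate(np.array([-0.15e6]), np.array([0.01]))[0]
        past = classify_fate(np.array([-0.15e6 - 1.0]), np.array([0.01]))[0]
        assert at == Fate.OSTEOGENIC
        assert past == Fate.CHONDROGENIC

    def test_activity_floor(self):
        assert classify_fate(np.array([-3e3]), np.array([0.0]))[0] == Fate.OSTEOGENIC
        assert classify_fate(np.array([-2.999e3]), np.array([0.0]))[0] == Fate.QUIESCENT

    def test_overload_threshold(self):
        assert classify_fate(np.array([-2e6]), np.array([0.06]))[0] == Fate.CHONDROGENIC
        assert classify_fate(np.array([-2.001e6]), np.array([0.0]))[0] == Fate.OVERLOAD

    def test_shear_split(self):
        low = classify_fate(np.array([-0.1e6]), np.array([0.05]))[0]
        high = classify_fate(np.array([-0.1e6]), np.array([0.0501]))[0]
        assert low == Fate.OSTEOGENIC
        assert high == Fate.CHONDROGENIC

    def test_configurable_compressive_ceiling(self):
        th = Thresholds(osteo_compress_max=0.2e6)
        out = classify_fate(np.array([-0.18e6]), np.array([0.01]), th)
        assert out[0] == Fate.OSTEOGENIC


def test_truth_table_oracle_agreement(rng):
    """Vectorized classifier agrees with an independently coded scalar
    truth table on 1e5 random points."""
    n = 100_000
    sigma = rng.uniform(-3e6, 3e6, n)
    # concentrate some mass near the thresholds
    sigma[::7] = rng.choice([-2e6, -0.15e6, -3e3, 3e3, 0.15e6], size=len(sigma[::7]))
    shear = rng.uniform(0, 0.12, n)
    got = classify_fate(sigma, shear)
    expected = np.array([reference_fate(s, g) for s, g in zip(sigma, shear)])
    np.testing.assert_array_equal(got, expected)


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_fate_partition_is_exhaustive(seed):
    rng = np.random.default_rng(seed)
    sigma = rng.uniform(-5e6, 5e6, 500)
    shear = rng.uniform(0, 0.2, 500)
    fates = classify_fate(sigma, shear)
    counts = np.bincount(fates, minlength=len(Fate))
    assert counts.sum() == 500


def test_raising_osteo_ceiling_grows_osteogenic_fraction(rng):
    sigma = rng.uniform(-3e6, 3e6, 5000)
    shear = rng.uniform(0, 0.1, 5000)
    lo = (classify_fate(sigma, shear, Thresholds()) == Fate.OSTEOGENIC).sum()
    hi_th = Thresholds(osteo_max=0.5e6, osteo_compress_max=0.5e6,
                       fibro_tension_min=0.5e6)
    hi = (classify_fate(sigma, shear, hi_th) == Fate.OSTEOGENIC).sum()
    assert hi >= lo


class TestTransport:
    @pytest.mark.parametrize(
        "P, expected",
        [
            (68e3, Transport.OPTIMAL),      # most favorable pressure
            (10e3, Transport.NONE),         # below the 20 kPa floor
            (3e6, Transport.NONE),          # above the 2 MPa ceiling
            (0.5e6, Transport.SUFFICIENT),
            (20e3, Transport.SUFFICIENT),
            (2e6, Transport.SUFFICIENT),
        ],
    )
    def test_pressure_bands(self, P, expected):
        assert classify_transport(np.array([P]))[0] == expected

    def test_optimal_band_is_factor_window(self):
        # default factor 2 around 68 kPa
        assert classify_transport(np.array([34e3]))[0] == Transport.OPTIMAL
        assert classify_transport(np.array([33e3]))[0] == Transport.SUFFICIENT
        assert classify_transport(np.array([136e3]))[0] == Transport.OPTIMAL


def test_distortion_band_flag():
    g = np.array([0.0004, 0.0005, 0.005, 0.011, 0.012])
    np.testing.assert_array_equal(
        distortion_flag(g), [False, True, True, True, False]
    )


class TestZoneFractions:
    def test_uniform_fate_gives_unit_fraction(self):
        fates = np.full((3, 10), int(Fate.OSTEOGENIC))
        tr = np.zeros((3, 10), dtype=int)
        rep = zone_fractions(fates, tr, np.arange(10))
        assert rep.fraction("osteogenic") == 1.0
        total = sum(rep.fraction(f.label) for f in Fate)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_constant_minority_fraction(self):
        fates = np.full((2, 150), int(Fate.OSTEOGENIC))
        fates[:, :30] = Fate.FIBROGENIC
        rep = zone_fractions(fates, np.zeros_like(fates), np.arange(150))
        assert rep.fraction("fibrogenic") == pytest.approx(0.2)

    def test_time_average_of_alternating_field(self):
        # half the samples at fraction 0.1, half at 0.3 -> mean 0.2
        n = 100
        fates = np.full((4, n), int(Fate.QUIESCENT))
        fates[0, :10] = fates[1, :10] = Fate.OSTEOGENIC
        fates[2, :30] = fates[3, :30] = Fate.OSTEOGENIC
        rep = zone_fractions(fates, np.zeros_like(fates), np.arange(n))
        assert rep.fraction("osteogenic") == pytest.approx(0.2)

    def test_reporting_floor(self):
        fates = np.full((1, 100), int(Fate.OSTEOGENIC))
        fates[0, :3] = Fate.FIBROGENIC
        rep = zone_fractions(fates, np.zeros_like(fates), np.arange(100))
        assert rep.fractions.loc["fibrogenic", "reported"] == "<5%"
        assert rep.fractions.loc["osteogenic", "reported"] == "97.0%"

    def test_empty_zone_rejected(self):
        with pytest.raises(ValueError, match="zone"):
            zone_fractions(np.zeros((1, 5)), np.zeros((1, 5)), np.array([], dtype=int))


def test_non_finite_inputs_rejected():
    with pytest.raises(ValueError):
        classify_fate(np.array([np.nan]), np.array([0.0]))
    with pytest.raises(ValueError):
        classify_transport(np.array([np.inf]))
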