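"""delta_BAF statistics, tracks, windows and the mosaic-fraction inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apcad.cbaf import (build_tracks, delta_baf, estimate_mosaic_fraction,
                        gain_delta, loss_delta, windowed_delta)
from apcad.simulate import KaryotypeEvent, SimConfig, simulate_biopsy, zero_noise
from apcad.categorize import categorize_frame

from conftest import single_chrom_case


def _clean(seed, events=(), chromosome="2"):
    return single_chrom_case(seed, events, chromosome, noise=False)


def test_build_tracks_counts_match_categorizer(clean_disomy_case):
    df, _ = clean_disomy_case
    tracks = build_tracks(df)
    counted = df[(df.subcategory != "EXCLUDED") & df.embryo_baf.notna()] \
        .groupby(["chromosome", "subcategory"]).size()
    assert len(tracks) == len(counted)
    for t in tracks:
        assert len(t) == counted[(t.chromosome, t.subcategory)]
        assert np.all(np.diff(t.positions_bp) > 0)


def test_simple_track_construction():
    df = pd.DataFrame({
        "chromosome": ["1"] * 3, "position_bp": [10, 20, 30],
        "subcategory": ["1A"] * 3, "embryo_baf": [0.4, 0.5, 0.6],
    })
    (track,) = build_tracks(df)
    assert (track.chromosome, track.subcategory, len(track)) == ("1", "1A", 3)


@pytest.mark.parametrize(
    "events,expected",
    [
        ((), 0.0),
        ((KaryotypeEvent("2", "gain_BPH_MI", "maternal"),), 1.0 / 3.0),
        ((KaryotypeEvent("2", "gain_SPH", "maternal"),), 1.0 / 3.0),
        ((KaryotypeEvent("2", "loss", "maternal"),), -1.0),
        ((KaryotypeEvent("2", "loss", "maternal", cell_fraction=0.5),), -1.0 / 3.0),
    ],
)
def test_delta_closed_forms_zero_noise(events, expected):
    """Noise-free delta_BAF equals the allele-counting closed form exactly."""
    df, _ = _clean(3, events)
    d = delta_baf(df, "2")
    assert d.delta_baf == pytest.approx(expected, abs=1e-12)


def test_delta_no_call_on_insufficient_snps():
    df, _ = _clean(4)
    d = delta_baf(df, "2", 1, 100_000)  # ~4 SNPs in 100 kb
    assert d.no_call and not np.isfinite(d.delta_baf)


def test_mosaic_round_trip_exact():
    """Simulated mixture delta inverts back to the cell fraction to 1e-12."""
    for f in np.arange(0.1, 1.01, 0.1):
        d = gain_delta(f)
        est = estimate_mosaic_fraction(d, "gain")
        assert est.fraction == pytest.approx(f, abs=1e-12)
        assert est.direction == "maternal_gain"
        d = -loss_delta(f)
        est = estimate_mosaic_fraction(d, "loss")
        assert est.fraction == pytest.approx(f, abs=1e-12)
        assert est.direction == "maternal_loss"
        # paternal mirror
        est = estimate_mosaic_fraction(-gain_delta(f, k=2), "gain", extra_doses=2)
        assert est.fraction == pytest.approx(f, abs=1e-12)
        assert est.direction == "paternal_gain"


def test_mosaic_inversion_examples():
    assert estimate_mosaic_fraction(1.0 / 3.0, "gain").fraction == pytest.approx(1.0)
    assert estimate_mosaic_fraction(-1.0, "loss").fraction == pytest.approx(1.0)
    assert estimate_mosaic_fraction(-1.0 / 3.0, "loss").fraction == pytest.approx(0.5)
    assert estimate_mosaic_fraction(0.0, "gain").fraction == 0.0


def test_mosaic_clamps_out_of_range_delta():
    est = estimate_mosaic_fraction(0.4, "gain")  # beyond the k=1 bound of 1/3
    assert est.clamped and est.fraction == pytest.approx(1.0)
    with pytest.raises(ValueError):
        estimate_mosaic_fraction(0.1, "duplication")


def test_gain_delta_bounded_by_one_third():
    f = np.linspace(0, 1, 101)
    assert np.all(gain_delta(f) <= 1.0 / 3.0 + 1e-15)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=25, max_size=60),
       st.lists(st.floats(0, 1), min_size=25, max_size=60))
def test_delta_bounds_property(a_vals, b_vals):
    """|delta_BAF| never exceeds 1 and the SE is finite and non-negative."""
    n = len(a_vals) + len(b_vals)
    df = pd.DataFrame({
        "chromosome": ["1"] * n,
        "position_bp": np.arange(1, n + 1),
        "subcategory": ["1A"] * len(a_vals) + ["1B"] * len(b_vals),
        "embryo_baf": a_vals + b_vals,
    })
    d = delta_baf(df, "1")
    assert -1.0 <= d.delta_baf <= 1.0
    assert d.se_delta >= 0.0


def test_windowed_delta_consistency_and_segment_signal():
    """Whole-chromosome window equals delta_baf; a deletion shows up only in
    the windows inside it."""
    df, _ = _clean(9)
    whole = windowed_delta(df, "2", window_snps=10 ** 6)
    assert len(whole) == 1
    assert whole[0].delta_baf == pytest.approx(delta_baf(df, "2").delta_baf)

    ev = (KaryotypeEvent("2", "loss", "maternal",
                         start_bp=60_000_000, end_bp=110_000_000),)
    df2, _ = _clean(10, ev)
    wins = [w for w in windowed_delta(df2, "2", window_snps=60, step_snps=60)
            if not w.no_call]
    inside = [w for w in wins if w.start_bp >= 62e6 and w.end_bp <= 108e6]
    outside = [w for w in wins if w.end_bp < 58e6 or w.start_bp > 112e6]
    assert inside and outside
    assert all(w.delta_baf == pytest.approx(-1.0, abs=1e-9) for w in inside)
    assert all(abs(w.delta_baf) < 1e-9 for w in outside)


def test_noisy_trisomy_delta_unbiased():
    """Mean delta over replicates of a full maternal trisomy is within
    2 standard errors of +1/3 at default noise."""
    vals = []
    for s in range(30):
        df, _ = single_chrom_case(100 + s, (KaryotypeEvent("2", "gain_SPH", "maternal"),))
        vals.append(delta_baf(df, "2").delta_baf)
    mean = np.mean(vals)
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(mean - 1.0 / 3.0) < 2 * se + 0.01


def test_delta_monotone_in_mosaic_fraction():
    """|delta| strictly increases with the simulated aneuploid fraction."""
    means = []
    for f in (0.2, 0.4, 0.6, 0.8, 1.0):
        vals = [delta_baf(single_chrom_case(
            200 + s + int(f * 10) * 37,
            (KaryotypeEvent("2", "loss", "maternal", cell_fraction=f),))[0], "2").delta_baf
            for s in range(4)]
        means.append(abs(np.mean(vals)))
    assert all(a < b for a, b in zip(means, means[1:]))
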