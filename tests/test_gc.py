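"""GC profiling and low-GC island calling, against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hgtscan as h
from hgtscan.gc import GCProfile, GCScanConfig, UndefinedValueError


def _profile(values, window=1000, step=1000, contig="c"):
    values = np.asarray(values, dtype=float)
    starts = np.arange(len(values)) * step
    cfg = GCScanConfig(window_bp=window, step_bp=step, min_island_bp=50_000)
    return GCProfile(contig, starts, values, cfg, contig_length=int(starts[-1]) + window)


def oracle_calls(values, window, step, threshold, min_island, max_gap):
    """Independent run-length enumeration of qualifying low-GC runs."""
    low = [v < threshold for v in values]
    runs, start, last = [], None, None
    for i, flag in enumerate(low):
        if flag:
            if start is None:
                start = i
            last = i
        elif start is not None and i - last > max_gap:
            runs.append((start, last))
            start = None
    if start is not None:
        runs.append((start, last))
    out = []
    trim_lo = (window - step) // 2
    trim_hi = (window - step) - trim_lo
    for i0, i1 in runs:
        s = i0 * step + trim_lo
        e = i1 * step + window - trim_hi
        if e - s >= min_island:
            out.append((s, e))
    return out


# -- gc_fraction -------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5), ("GCNNAT", 0.5)]
)
def test_gc_fraction(seq, expected):
    assert h.gc_fraction(seq) == expected


def test_gc_fraction_undefined():
    with pytest.raises(UndefinedValueError):
        h.gc_fraction("NNNN")


# -- gc_profile --------------------------------------------------------------


def test_profile_simple_windows():
    rec = h.GenomeRecord(id="r", sequence="AAAAGGGGCCCCTTTT")
    prof = h.gc_profile(rec, GCScanConfig(window_bp=4, step_bp=4, min_island_bp=1))
    assert list(prof.gc) == [0.0, 1.0, 1.0, 0.0]
    assert list(prof.window_starts) == [0, 4, 8, 12]


def test_profile_conservation():
    """Weighted mean over non-overlapping windows equals whole-record GC."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    rec = h.GenomeRecord(id="r", sequence=seq)
    cfg = GCScanConfig(window_bp=1000, step_bp=1000, min_island_bp=1)
    prof = h.gc_profile(rec, cfg)
    assert np.isclose(prof.gc.mean(), h.gc_fraction(seq))


def test_profile_binomial_bound():
    """Windows of an iid p=0.6 sequence stay within 5 binomial sd of 0.6."""
    rng = np.random.default_rng(1)
    seq = "".join(
        rng.choice(list("ACGT"), size=100_000, p=[0.2, 0.3, 0.3, 0.2])
    )
    prof = h.gc_profile(h.GenomeRecord(id="r", sequence=seq))
    sd = np.sqrt(0.6 * 0.4 / 10_000)
    assert np.all(np.abs(prof.gc - 0.6) < 5 * sd)


def test_profile_rejects_short_record():
    with pytest.raises(ValueError, match="shorter than window"):
        h.gc_profile(h.GenomeRecord(id="r", sequence="ACGT"))


def test_profile_circular_wraps():
    seq = "G" * 6000 + "A" * 6000
    rec = h.GenomeRecord(id="r", sequence=seq, circular=True)
    prof = h.gc_profile(rec, GCScanConfig(window_bp=4000, step_bp=2000, min_island_bp=1))
    # last window starts at 10000 and wraps into the leading G run
    assert prof.window_starts[-1] == 10_000
    assert prof.gc[-1] == 0.5


# -- call_low_gc_islands -----------------------------------------------------


def test_no_islands_when_all_high():
    prof = _profile([0.60] * 200)
    assert h.call_low_gc_islands(prof) == []


def test_single_block_island_boundaries():
    values = [0.60] * 100 + [0.50] * 80 + [0.60] * 100
    prof = _profile(values, window=1000, step=1000)
    (call,) = h.call_low_gc_islands(prof)
    truth = (100_000, 180_000)
    assert abs(call.start - truth[0]) <= 1000
    assert abs(call.end - truth[1]) <= 1000
    assert call.length_bp >= 50_000


def test_gap_tolerance_merges_across_spikes():
    values = [0.60] * 50 + [0.50] * 30 + [0.60, 0.60] + [0.50] * 30 + [0.60] * 50
    prof = _profile(values)
    calls = h.call_low_gc_islands(prof)
    assert len(calls) == 1  # the 2-window spike is tolerated


def test_three_windows_gap_splits_run():
    values = [0.60] * 10 + [0.50] * 60 + [0.60] * 3 + [0.50] * 60 + [0.60] * 10
    prof = _profile(values)
    calls = h.call_low_gc_islands(prof)
    assert len(calls) == 2


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    st.lists(st.sampled_from([0.45, 0.50, 0.54, 0.56, 0.60, 0.65]), min_size=60, max_size=400),
    st.sampled_from([0, 1, 2]),
)
def test_calls_match_runlength_oracle(values, max_gap):
    cfg = GCScanConfig(
        window_bp=1000, step_bp=1000, min_island_bp=10_000, max_gap_windows=max_gap
    )
    prof = _profile(values)
    calls = h.call_low_gc_islands(prof, cfg)
    expected = oracle_calls(values, 1000, 1000, 0.55, 10_000, max_gap)
    assert [(c.start, c.end) for c in calls] == expected


def test_monotonicity_in_threshold_and_min_length():
    rng = np.random.default_rng(5)
    values = rng.uniform(0.45, 0.65, size=500)
    base_cfg = GCScanConfig(window_bp=1000, step_bp=1000, min_island_bp=20_000)
    base = h.call_low_gc_islands(_profile(values), base_cfg)
    wider = h.call_low_gc_islands(
        _profile(values),
        GCScanConfig(window_bp=1000, step_bp=1000, gc_threshold=0.60, min_island_bp=20_000),
    )
    # raising the threshold can only grow or preserve each call
    for c in base:
        assert any(wc.start <= c.start and c.end <= wc.end for wc in wider)
    fewer = h.call_low_gc_islands(
        _profile(values),
        GCScanConfig(window_bp=1000, step_bp=1000, min_island_bp=60_000),
    )
    assert len(fewer) <= len(base)
    assert all(
        any(c.start == f.start and c.end == f.end for c in base) for f in fewer
    )


def test_calls_sorted_and_non_overlapping(ref_sim):
    calls = h.scan_genome(ref_sim.genome.records)
    for a, b in zip(calls, calls[1:]):
        assert a.end <= b.start


def test_fixture_islands_recovered(ref_sim):
    """The three planted 79/87/98-kb islands are each recovered with
    interval Jaccard >= 0.9 under the default scan settings."""
    calls = h.scan_genome(ref_sim.genome.records)
    truth = ref_sim.truth.islands
    assert len(calls) == len(truth) == 3
    for call, isl in zip(calls, truth):
        inter = max(0, min(call.end, isl.end) - max(call.start, isl.start))
        union = max(call.end, isl.end) - min(call.start, isl.start)
        assert inter / union >= 0.9
        assert call.mean_gc < 0.55
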