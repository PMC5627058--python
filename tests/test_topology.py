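"""Five-region segmentation, priority assignment, metagene binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meriptools as mt
from meriptools.topology import (
    CDS,
    FIVE_UTR,
    PRIORITY,
    START,
    STOP,
    THREE_UTR,
    assign_region,
    metagene,
    region_counts,
    segment,
)
from meriptools.transcriptome import TranscriptModel


def coding(u, c, w, gene="g1", tid="t1"):
    return TranscriptModel(gene, tid, "coding", u + c + w, u, c, w)


class FakePeak:
    def __init__(self, tx, start, end):
        self.transcript_id, self.start, self.end = tx, start, end


def oracle_segment(u, c, w):
    """Independent per-nucleotide labeller applying the same decided rules."""
    L = u + c + w
    labels = [FIVE_UTR] * u + [CDS] * c + [THREE_UTR] * w
    if c > 200:
        if u > 100:
            lo, hi = u - 100, u + 100
        else:
            lo, hi = 0, u + min(100, c // 2)
        for i in range(lo, hi):
            labels[i] = START
        if w > 100:
            lo, hi = u + c - 100, u + c + 100
        else:
            lo, hi = u + c - min(100, c // 2), L
        for i in range(lo, hi):
            labels[i] = STOP
    else:
        mid = u + c // 2
        lo = 0 if u <= 100 else u
        for i in range(lo, mid):
            labels[i] = START
        hi = L if w <= 100 else u + c
        for i in range(mid, hi):
            labels[i] = STOP
    return labels


class TestSegment:
    def test_long_everything_centred_windows(self):
        seg = segment(coding(300, 900, 500))
        assert seg.intervals == (
            (FIVE_UTR, 0, 200), (START, 200, 400), (CDS, 400, 1100),
            (STOP, 1100, 1300), (THREE_UTR, 1300, 1700),
        )

    def test_short_utr5_absorbed_into_start_region(self):
        seg = segment(coding(60, 900, 500))
        assert seg.region(FIVE_UTR) is None
        assert seg.region(START) == (0, 160)  # whole 5'UTR + 100 nt of CDS

    def test_short_cds_split_at_midpoint(self):
        seg = segment(coding(300, 150, 400))
        assert seg.region(START) == (300, 375)
        assert seg.region(STOP) == (375, 450)
        assert seg.region(FIVE_UTR) == (0, 300)
        assert seg.region(THREE_UTR) == (450, 850)
        assert seg.region(CDS) is None

    def test_lncrna_rejected(self):
        with pytest.raises(ValueError):
            segment(TranscriptModel("g1", "t1", "lncRNA", 500))

    @settings(derandomize=True, max_examples=300)
    @given(
        u=st.integers(min_value=1, max_value=400),
        c=st.integers(min_value=1, max_value=300).map(lambda x: 3 * x),
        w=st.integers(min_value=1, max_value=400),
    )
    def test_disjoint_cover_of_transcript(self, u, c, w):
        seg = segment(coding(u, c, w))
        cursor = 0
        seen = []
        for lab, s, e in seg.intervals:
            assert s == cursor and e > s
            cursor = e
            seen.append(lab)
        assert cursor == u + c + w
        assert seen == [lab for lab in (FIVE_UTR, START, CDS, STOP, THREE_UTR) if lab in seen]
        assert START in seen and STOP in seen

    @settings(derandomize=True, max_examples=300)
    @given(
        u=st.integers(min_value=1, max_value=400),
        c=st.integers(min_value=1, max_value=300).map(lambda x: 3 * x),
        w=st.integers(min_value=1, max_value=400),
    )
    def test_matches_per_nucleotide_oracle(self, u, c, w):
        seg = segment(coding(u, c, w))
        oracle = oracle_segment(u, c, w)
        for lab, s, e in seg.intervals:
            assert oracle[s:e] == [lab] * (e - s)


class TestAssignRegion:
    def test_single_region_overlap(self):
        seg = segment(coding(300, 900, 500))
        assert assign_region(FakePeak("t1", 1150, 1250), seg) == STOP

    def test_priority_stop_beats_start_and_cds(self):
        seg = segment(coding(300, 900, 500))
        assert assign_region(FakePeak("t1", 350, 1150), seg) == STOP

    def test_five_utr(self):
        seg = segment(coding(300, 900, 500))
        assert assign_region(FakePeak("t1", 50, 150), seg) == FIVE_UTR

    def test_out_of_bounds_rejected(self):
        seg = segment(coding(300, 900, 500))
        with pytest.raises(ValueError):
            assign_region(FakePeak("t1", 1600, 1800), seg)

    def test_matches_bruteforce_priority_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            u = int(rng.integers(1, 400))
            c = 3 * int(rng.integers(1, 300))
            w = int(rng.integers(1, 400))
            t = coding(u, c, w)
            seg = segment(t)
            s = int(rng.integers(0, t.length))
            e = int(rng.integers(s + 1, t.length + 1))
            oracle = oracle_segment(u, c, w)
            overlapped = set(oracle[s:e])
            expected = next(lab for lab in PRIORITY if lab in overlapped)
            assert assign_region(FakePeak("t1", s, e), seg) == expected


class TestMetagene:
    def test_single_peak_midpoint_half_cds(self):
        t = coding(300, 1000, 500)  # CDS [300, 1300)
        prof = metagene([FakePeak("t1", 750, 850)], [t])  # midpoint 800 = CDS midpoint
        assert prof.n_peaks == 1
        assert prof.bins[149] == pytest.approx(100.0)
        assert prof.bins.sum() == pytest.approx(100.0)

    def test_two_peaks_same_bin(self):
        t = coding(300, 1000, 500)
        peaks = [FakePeak("t1", 750, 850), FakePeak("t1", 740, 860)]
        prof = metagene(peaks, [t])
        assert prof.bins[149] == pytest.approx(100.0)

    def test_lncrna_profile_has_100_bins(self):
        t = TranscriptModel("g1", "t1", "lncRNA", 1000)
        prof = metagene([FakePeak("t1", 0, 100)], [t], biotype="lncRNA")
        assert len(prof.bins) == 100
        assert prof.bins.sum() == pytest.approx(100.0)

    def test_profile_invariant_to_transcript_scale(self):
        """A midpoint at a fixed fraction lands in the same bin whatever the
        transcript length."""
        for scale in (1, 3, 7):
            t = coding(100 * scale, 1000 * scale, 200 * scale, tid=f"t{scale}")
            mid = t.utr5_len + int(0.3 * t.cds_len)
            prof = metagene([FakePeak(f"t{scale}", mid - 10, mid + 10)], [t])
            assert prof.bins[100 + 29] == pytest.approx(100.0)

    def test_empty_profile_all_zero(self):
        prof = metagene([], [coding(300, 900, 300)])
        assert prof.n_peaks == 0 and prof.bins.sum() == 0


class TestRegionCounts:
    def test_empty_table(self):
        import pandas as pd

        out = region_counts(pd.DataFrame())
        assert (out["count"] == 0).all()

    def test_counts_conserved_and_percentages(self):
        import pandas as pd

        rows = (
            [{"region": STOP, "group": "common"}] * 3
            + [{"region": CDS, "group": "common"}]
            + [{"region": START, "group": "specific"}] * 2
        )
        out = region_counts(pd.DataFrame(rows))
        common = out[out["group"] == "common"]
        assert common["count"].sum() == 4
        assert common.set_index("region").loc[STOP, "percent"] == pytest.approx(75.0)
        spec = out[out["group"] == "specific"]
        assert spec.set_index("region").loc[START, "percent"] == pytest.approx(100.0)


class TestUtr5Filter:
    def test_all_long(self):
        models = [coding(200, 300, 100, gene=f"g{i}", tid=f"t{i}") for i in range(3)]
        assert mt.utr5_filter([f"g{i}" for i in range(3)], models) == 1.0

    def test_half_long(self):
        models = [coding(50, 300, 100, gene="g0", tid="t0"),
                  coding(150, 300, 100, gene="g1", tid="t1")]
        assert mt.utr5_filter(["g0", "g1"], models) == 0.5

    def test_exactly_100_excluded(self):
        models = [coding(100, 300, 100, gene="g0", tid="t0")]
        assert mt.utr5_filter(["g0"], models) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mt.utr5_filter([], [coding(100, 300, 100)])
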