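"""End extraction, metagene profiles, frame periodicity and the TSI."""

import numpy as np
import pandas as pd
import pytest

from ctrdseq.annotation_io import TranscriptModel
from ctrdseq.degradome_profiling import (FivePEndTrack, compute_tsi,
                                         extract_5p_ends, frame_periodicity,
                                         metagene_profile)
from ctrdseq.synthetic_data import SimulationConfig, simulate_5p_tracks


def _toy_transcript(utr5=60, n_codons=100, utr3=80, tid="t1"):
    cds = "ATG" + "GCC" * (n_codons - 2) + "TAA"
    seq = "A" * utr5 + cds + "A" * utr3
    return TranscriptModel(tid, tid.replace("t", "g"), seq, utr5,
                           utr5 + 3 * n_codons)


class TestExtract:
    def test_simple_tally(self):
        t = _toy_transcript()
        table = pd.DataFrame({"transcript_id": ["t1"] * 3, "start": [10] * 3,
                              "end": [11] * 3, "count": [1, 1, 1]})
        tracks, rep = extract_5p_ends(table, [t])
        assert tracks["t1"].counts[10] == 3
        assert tracks["t1"].total == 3
        assert rep.n_assigned == 3

    def test_empty_table_all_zero(self):
        t = _toy_transcript()
        table = pd.DataFrame(columns=["transcript_id", "start", "end", "count"])
        tracks, _ = extract_5p_ends(table, [t])
        assert tracks["t1"].total == 0

    def test_unknown_and_out_of_range_reported(self):
        t = _toy_transcript()
        table = pd.DataFrame({"transcript_id": ["tX", "t1"],
                              "start": [5, 10_000],
                              "end": [6, 10_001], "count": [2, 4]})
        tracks, rep = extract_5p_ends(table, [t])
        assert rep.unknown_transcripts == ["tX"]
        assert rep.n_out_of_range == 4
        assert tracks["t1"].total == 0

    def test_scattered_fixture_matches_brute_force(self, rng):
        t = _toy_transcript()
        pos = rng.integers(0, t.length, size=20)
        cnt = rng.integers(1, 5, size=20)
        table = pd.DataFrame({"transcript_id": "t1", "start": pos,
                              "end": pos + 1, "count": cnt})
        tracks, _ = extract_5p_ends(table, [t])
        brute = np.zeros(t.length, dtype=int)
        for p, c in zip(pos, cnt):  # independent line-by-line tally
            brute[p] += c
        assert (tracks["t1"].counts == brute).all()


class TestMetagene:
    def test_single_read_17nt_upstream_of_stop(self):
        t = _toy_transcript()
        counts = np.zeros(t.length, dtype=int)
        counts[t.stop_first_nt - 17] = 1
        prof = metagene_profile({"t1": FivePEndTrack("t1", counts)}, [t],
                                anchor="stop_codon", normalize="raw")
        nz = prof.offsets[prof.values > 0]
        assert nz.tolist() == [-17]

    def test_additivity_of_identical_tracks(self, rng):
        t1 = _toy_transcript(tid="t1")
        t2 = _toy_transcript(tid="t2")
        counts = rng.integers(0, 5, size=t1.length)
        single = metagene_profile({"t1": FivePEndTrack("t1", counts)}, [t1],
                                  normalize="raw")
        double = metagene_profile({"t1": FivePEndTrack("t1", counts),
                                   "t2": FivePEndTrack("t2", counts.copy())},
                                  [t1, t2], normalize="raw")
        assert np.allclose(double.values, 2 * single.values)

    def test_short_transcripts_excluded_not_padded(self):
        t_long = _toy_transcript(tid="t1")
        t_short = _toy_transcript(utr5=5, n_codons=10, utr3=5, tid="t2")
        tracks = {"t1": FivePEndTrack("t1", np.ones(t_long.length, dtype=int)),
                  "t2": FivePEndTrack("t2", np.ones(t_short.length, dtype=int))}
        prof = metagene_profile(tracks, [t_long, t_short], window_up=100,
                                window_down=50, normalize="raw")
        assert prof.n_transcripts == 1 and prof.n_excluded == 1

    def test_empty_inclusion_set_raises(self):
        t = _toy_transcript(utr5=5, n_codons=10, utr3=5)
        with pytest.raises(ValueError):
            metagene_profile({"t1": FivePEndTrack("t1", np.ones(t.length, int))},
                             [t], window_up=500, window_down=500)

    def test_rpm_scaling(self):
        t = _toy_transcript()
        counts = np.zeros(t.length, dtype=int)
        counts[t.cds_start] = 50
        raw = metagene_profile({"t1": FivePEndTrack("t1", counts)}, [t],
                               anchor="start_codon", window_up=50,
                               window_down=50, normalize="raw")
        rpm = metagene_profile({"t1": FivePEndTrack("t1", counts)}, [t],
                               anchor="start_codon", window_up=50,
                               window_down=50, normalize="rpm")
        assert np.allclose(rpm.values, raw.values / (50 / 1e6))


class TestFramePeriodicity:
    def test_pure_frame0(self):
        t = _toy_transcript()
        counts = np.zeros(t.length, dtype=int)
        counts[t.cds_start + 90:t.stop_first_nt - 90:3] = 5  # interior, frame 0
        f = frame_periodicity({"t1": FivePEndTrack("t1", counts)}, [t])
        assert f.tolist() == [1.0, 0.0, 0.0]

    def test_uniform_interior_is_balanced(self):
        t = _toy_transcript(n_codons=200)
        counts = np.ones(t.length, dtype=int)
        f = frame_periodicity({"t1": FivePEndTrack("t1", counts)}, [t])
        # interior length is a multiple of 3, so exact symmetry
        assert np.allclose(f, 1 / 3)

    def test_zero_interior_raises(self):
        t = _toy_transcript()
        counts = np.zeros(t.length, dtype=int)
        with pytest.raises(ValueError):
            frame_periodicity({"t1": FivePEndTrack("t1", counts)}, [t])

    def test_simulation_recovery(self):
        cfg = SimulationConfig(seed=21, n_transcripts=200,
                               frame_weights=(0.7, 0.2, 0.1),
                               mean_track_coverage=500)
        from ctrdseq.synthetic_data import generate_transcriptome
        ts = generate_transcriptome(cfg)
        tracks, _ = simulate_5p_tracks(ts, cfg)
        f = frame_periodicity(tracks, ts)
        assert np.abs(f - np.array([0.7, 0.2, 0.1])).max() < 0.03


class TestTSI:
    def test_uniform_track_gives_two(self):
        """Sum-numerator convention: uniform coverage c gives 2c/c = 2."""
        t = _toy_transcript()
        rec = compute_tsi(FivePEndTrack("t1", np.full(t.length, 7)), t)
        assert rec.defined and rec.tsi == pytest.approx(2.0)

    def test_boundary_ten_flank_one_gives_twenty(self):
        t = _toy_transcript()
        counts = np.ones(t.length, dtype=int)
        counts[t.stop_first_nt - 17] = 10
        counts[t.stop_first_nt - 16] = 10
        rec = compute_tsi(FivePEndTrack("t1", counts), t)
        assert rec.tsi == pytest.approx(20.0)
        assert rec.boundary_count == 20 and rec.flank_mean == 1.0

    def test_zero_flank_flagged_undefined(self):
        t = _toy_transcript()
        counts = np.zeros(t.length, dtype=int)
        counts[t.stop_first_nt - 17] = 9
        rec = compute_tsi(FivePEndTrack("t1", counts), t)
        assert not rec.defined and rec.tsi is None

    def test_scale_invariance(self, rng):
        t = _toy_transcript()
        counts = rng.integers(1, 20, size=t.length)
        a = compute_tsi(FivePEndTrack("t1", counts), t)
        b = compute_tsi(FivePEndTrack("t1", counts * 13), t)
        assert a.tsi == pytest.approx(b.tsi)

    def test_flank_must_fit(self):
        t = _toy_transcript(utr5=2, n_codons=12, utr3=2)
        with pytest.raises(ValueError):
            compute_tsi(FivePEndTrack("t1", np.ones(t.length, int)), t)

    def test_mean_tsi_monotone_in_boost(self):
        from ctrdseq.synthetic_data import generate_transcriptome
        means = []
        for boost in (1.0, 3.0, 10.0):
            cfg = SimulationConfig(seed=22, n_transcripts=100,
                                   frame_weights=(1 / 3, 1 / 3, 1 / 3),
                                   stop_boundary_boost=boost,
                                   mean_track_coverage=500)
            ts = generate_transcriptome(cfg)
            tracks, _ = simulate_5p_tracks(ts, cfg)
            vals = [compute_tsi(tracks[t.transcript_id], t).tsi for t in ts]
            means.append(np.mean([v for v in vals if v is not None]))
        assert means[0] < means[1] < means[2]
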