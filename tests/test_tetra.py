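"""Window statistics: counts, Markov expectations, z-scores, matrices,
and low-correlation region calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tetrascan as ts
from tetrascan.io import SequenceRecord, reverse_complement
from tetrascan.tetra import (
    Window,
    WindowSpec,
    _original_span,
    call_low_correlation_regions,
    kmer_index,
    kmer_string,
    window_scores,
    window_signature,
)

dna = st.text(alphabet="ACGT", min_size=10, max_size=300)


def naive_signature(seq):
    """Brute-force 256-loop oracle for expectations and z-scores."""
    bases = "ACGT"

    def count(s, k):
        out = {}
        for i in range(len(s) - k + 1):
            out[s[i : i + k]] = out.get(s[i : i + k], 0) + 1
        return out

    n4, n3, n2 = count(seq, 4), count(seq, 3), count(seq, 2)
    e, var, z = {}, {}, {}
    for a in bases:
        for b in bases:
            for c in bases:
                for d in bases:
                    t = a + b + c + d
                    core = n2.get(b + c, 0)
                    lead, trail = n3.get(a + b + c, 0), n3.get(b + c + d, 0)
                    if core == 0:
                        e[t] = var[t] = z[t] = 0.0
                        continue
                    e[t] = lead * trail / core
                    var[t] = e[t] * (core - lead) * (core - trail) / core**2
                    obs = n4.get(t, 0)
                    z[t] = (obs - e[t]) / var[t] ** 0.5 if var[t] > 0 and e[t] > 0 else 0.0
    return e, var, z


class TestFragmentation:
    @pytest.mark.parametrize(
        "length,mode,starts",
        [
            (500, "per_window_rc", [1, 101, 201]),
            (300, "per_window_rc", [1]),
            (500, "whole_sequence_rc", [1, 101, 201, 301, 401, 501, 601, 701]),
        ],
    )
    def test_window_starts(self, rng, length, mode, starts):
        rec = SequenceRecord(id="x", seq="".join(rng.choice(list("ACGT"), size=length)))
        windows = ts.fragment_sequence(rec, WindowSpec(extension_mode=mode))
        assert [w.start for w in windows] == starts
        assert all(w.end - w.start + 1 == 300 for w in windows)

    def test_too_short_fails(self, rng):
        rec = SequenceRecord(id="x", seq="".join(rng.choice(list("ACGT"), size=299)))
        with pytest.raises(ValueError, match="too short"):
            ts.fragment_sequence(rec, WindowSpec())

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            WindowSpec(window_length=5)
        with pytest.raises(ValueError):
            WindowSpec(step=400)
        with pytest.raises(ValueError):
            WindowSpec(extension_mode="both")


class TestCounting:
    @pytest.mark.parametrize(
        "seq,k,mode,expect",
        [
            ("AAAA", 4, None, {"AAAA": 1}),
            ("AAAAA", 4, None, {"AAAA": 2}),
            ("AAAA", 4, "per_window_rc", {"AAAA": 1, "TTTT": 1}),
            ("AANAA", 2, None, {"AA": 2}),
        ],
    )
    def test_examples(self, seq, k, mode, expect):
        counts = ts.count_kmers(seq, k, mode)
        nonzero = {kmer_string(i, k): int(c) for i, c in enumerate(counts) if c}
        assert nonzero == expect

    def test_bad_k(self):
        with pytest.raises(ValueError):
            ts.count_kmers("ACGTACGT", 5)

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="ACGTN", min_size=4, max_size=120))
    def test_conservation_with_ns(self, seq):
        """Total 4-mer count equals valid (N-free) positions, both strands."""
        counts = ts.count_kmers(seq, 4, "per_window_rc")
        valid = sum(
            1 for i in range(len(seq) - 3) if "N" not in seq[i : i + 4]
        )
        assert counts.sum() == 2 * valid


class TestMarkovZScores:
    def test_homopolymer_frozen_values(self):
        """Single-strand length-10 poly-A: E = 8*8/9, Z = -3/8 exactly."""
        n4 = ts.count_kmers("AAAAAAAAAA", 4)
        n3 = ts.count_kmers("AAAAAAAAAA", 3)
        n2 = ts.count_kmers("AAAAAAAAAA", 2)
        e = ts.expected_counts(n3, n2)
        z = ts.z_scores(n4, n3, n2)
        assert e[kmer_index("AAAA")] == pytest.approx(64 / 9, abs=1e-12)
        assert z[kmer_index("AAAA")] == pytest.approx(-0.375, abs=1e-12)

    def test_zero_core_dinucleotide_rule(self):
        """All 16 tetranucleotides sharing an absent core get E = 0, Z = 0."""
        seq = "ATATATATATATATAT"  # no CG dinucleotide anywhere
        n4, n3, n2 = (ts.count_kmers(seq, k) for k in (4, 3, 2))
        e = ts.expected_counts(n3, n2)
        z = ts.z_scores(n4, n3, n2)
        cg_core = [i for i in range(256) if kmer_string(i, 4)[1:3] == "CG"]
        assert np.all(e[cg_core] == 0) and np.all(z[cg_core] == 0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            n4, n3, n2 = (ts.count_kmers(seq, k) for k in (4, 3, 2))
            e = ts.expected_counts(n3, n2)
            z = ts.z_scores(n4, n3, n2)
            e_o, _, z_o = naive_signature(seq)
            for i in range(256):
                t = kmer_string(i, 4)
                assert e[i] == pytest.approx(e_o[t], abs=1e-12)
                assert z[i] == pytest.approx(z_o[t], abs=1e-12)

    def test_iid_expectation_approaches_uniform(self, rng):
        """On long uniform i.i.d. text, E for any tetranucleotide -> L/256."""
        L = 200_000
        seq = "".join(rng.choice(list("ACGT"), size=L))
        n4, n3, n2 = (ts.count_kmers(seq, k) for k in (4, 3, 2))
        e = ts.expected_counts(n3, n2)
        sigma = np.sqrt(L / 256)
        assert np.all(np.abs(e - L / 256) < 5 * sigma)


class TestPearson:
    def test_identical_and_negated(self, rng):
        z = rng.standard_normal(256)
        assert ts.pearson(z, z) == pytest.approx(1.0)
        assert ts.pearson(z, -z) == pytest.approx(-1.0)

    def test_against_two_pass_oracle(self):
        z1 = np.arange(1, 257, dtype=float)
        z2 = np.concatenate([np.arange(1, 256), [0.0]])
        n = 256
        sx, sy = z1.sum(), z2.sum()
        sxx, syy, sxy = (z1 * z1).sum(), (z2 * z2).sum(), (z1 * z2).sum()
        expected = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        assert ts.pearson(z1, z2) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_vector_warns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert ts.pearson(np.zeros(256), np.ones(256) * 2) == 0.0


class TestStrandSymmetry:
    def test_rc_window_same_signature(self, rng):
        """Per-window-RC counting makes a window and its reverse
        complement share one z-vector up to the reverse-complement
        permutation of components, so they correlate at exactly 1."""
        seq = "".join(rng.choice(list("ACGT"), size=300))
        w = Window("x", 0, 1, 300, seq)
        w_rc = Window("x", 0, 1, 300, reverse_complement(seq))
        z1 = window_signature(w, "per_window_rc").z
        z2 = window_signature(w_rc, "per_window_rc").z
        perm = [kmer_index(reverse_complement(kmer_string(i, 4))) for i in range(256)]
        assert np.allclose(z1, z2[perm], atol=1e-12)
        assert ts.pearson(z1, z2) == pytest.approx(1.0, abs=1e-9)


class TestCorrelationMatrix:
    def test_500bp_three_windows(self, rng):
        rec = SequenceRecord(id="x", seq="".join(rng.choice(list("ACGT"), size=500)))
        m = ts.correlation_matrix(rec)
        assert m.r.shape == (3, 3)
        assert np.allclose(np.diag(m.r), 1.0, atol=1e-9)

    def test_repeated_window_all_ones(self, rng):
        unit = "".join(rng.choice(list("ACGT"), size=100))
        rec = SequenceRecord(id="x", seq=unit * 7)
        m = ts.correlation_matrix(rec)
        assert np.allclose(m.r, 1.0, atol=1e-9)
        assert m.mean_r == pytest.approx(1.0)

    def test_matrix_properties_random_fragments(self, rng):
        for _ in range(10):
            rec = SequenceRecord(
                id="x", seq="".join(rng.choice(list("ACGT"), size=int(rng.integers(600, 1200))))
            )
            m = ts.correlation_matrix(rec)
            assert np.allclose(m.r, m.r.T, atol=1e-12)
            assert np.allclose(np.diag(m.r), 1.0, atol=1e-9)
            assert np.all(m.r >= -1.0) and np.all(m.r <= 1.0)
            iu = np.triu_indices(len(m.windows), k=1)
            assert m.mean_r == pytest.approx(float(m.r[iu].mean()))

    def test_too_few_windows_fails(self, rng):
        rec = SequenceRecord(id="x", seq="".join(rng.choice(list("ACGT"), size=300)))
        with pytest.raises(ValueError, match="window"):
            ts.correlation_matrix(rec)

    def test_implant_block_less_correlated(self, implanted_matrix, implanted_fragment):
        _, truth = implanted_fragment
        m = implanted_matrix
        mids = np.array([(w.start + w.end) / 2 for w in m.windows])
        inside = (mids >= truth.implant_start) & (mids <= truth.implant_end)
        host_block = m.r[np.ix_(~inside, ~inside)]
        cross_block = m.r[np.ix_(inside, ~inside)]
        host_mean = (host_block.sum() - np.trace(host_block)) / (
            host_block.shape[0] * (host_block.shape[0] - 1)
        )
        assert cross_block.mean() < host_mean

    def test_homogeneous_beats_two_source_mean_r(
        self, homogeneous_matrix, implanted_matrix
    ):
        assert homogeneous_matrix.mean_r > implanted_matrix.mean_r


def _constant_matrix(n=12, value=1.0):
    windows = [Window("x", i, 1 + 100 * i, 300 + 100 * i, "A" * 300) for i in range(n)]
    r = np.full((n, n), value)
    np.fill_diagonal(r, 1.0)
    return ts.CorrelationMatrix(
        seq_id="x", windows=windows, r=r, mean_r=value, sd_r=0.0,
        extension_mode="per_window_rc", seq_length=300 + 100 * (n - 1),
    )


class TestRegionCalling:
    def test_all_ones_matrix_no_calls(self):
        m = _constant_matrix()
        assert call_low_correlation_regions(m) == []
        assert call_low_correlation_regions(m, threshold=0.5, min_run=2) == []

    def test_implant_recovered_with_midpoint_threshold(
        self, host_model, implant_model
    ):
        """Implant spanning a handful of windows is recovered within one
        window of truth when thresholding midway between block levels."""
        rec, truth = ts.simulate_fragment(
            3000, host_model, implant=(implant_model, 501, 700), seed=3
        )
        m = ts.correlation_matrix(rec)
        scores, _ = window_scores(m)
        mids = np.array([(w.start + w.end) / 2 for w in m.windows])
        inside = (mids >= truth.implant_start) & (mids <= truth.implant_end)
        t = (scores[inside].mean() + scores[~inside].mean()) / 2
        regions = call_low_correlation_regions(m, threshold=t, min_run=2)
        assert len(regions) == 1
        truth_first, truth_last = np.where(inside)[0][[0, -1]]
        assert abs(regions[0].first_window - truth_first) <= 1
        assert abs(regions[0].last_window - truth_last) <= 1
        assert regions[0].mean_r_inside < regions[0].mean_r_outside

    def test_mask_covering_implant_suppresses_call(
        self, implanted_matrix, implanted_fragment
    ):
        _, truth = implanted_fragment
        mask = [
            ts.FeatureInterval(
                truth.seq_id, truth.implant_start, truth.implant_end, "rRNA", "m"
            )
        ]
        assert call_low_correlation_regions(implanted_matrix, mask=mask) == []

    def test_all_masked_fails(self, implanted_matrix, implanted_fragment):
        _, truth = implanted_fragment
        mask = [ts.FeatureInterval(truth.seq_id, 1, truth.length, "other", "all")]
        with pytest.raises(ValueError, match="masked"):
            call_low_correlation_regions(implanted_matrix, mask=mask)

    def test_threshold_range_validated(self, implanted_matrix):
        with pytest.raises(ValueError, match="threshold"):
            call_low_correlation_regions(implanted_matrix, threshold=1.5)


class TestOriginalSpan:
    @pytest.mark.parametrize(
        "start,end,L,expected",
        [
            (1, 300, 500, (1, 300)),          # forward half
            (701, 1000, 500, (1, 300)),       # mirrored half maps back
            (401, 700, 500, (301, 500)),      # junction window clamps at 3' end
        ],
    )
    def test_mapping(self, start, end, L, expected):
        assert _original_span(start, end, L) == expected
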