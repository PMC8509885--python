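"""Motif-window aggregation, binning, profiles, t-tests, correlations."""

import numpy as np
import pytest
from scipy import stats

from pymotif import (
    PositionProfile,
    ProteinRecord,
    TrackTable,
    bin_accessibility,
    correlate_table,
    motif_mean,
    paired_t_test,
    position_profile,
    scan,
    welch_t_test,
)

import pandas as pd


def one_hit(seq="AAPPAYAAAA"):
    rec = ProteinRecord("p1", seq)
    (hit,) = scan(rec)
    return rec, hit


class TestMotifMean:
    def test_constant_track(self):
        _, hit = one_hit()
        assert motif_mean(np.full(10, 0.3), hit).mean == pytest.approx(0.3)

    def test_hand_arithmetic(self):
        _, hit = one_hit()  # motif at [2, 6)
        track = np.zeros(10)
        track[2:6] = [0.1, 0.2, 0.3, 0.4]
        assert motif_mean(track, hit).mean == pytest.approx(0.25)

    def test_matches_brute_force_on_random_tracks(self, rng):
        _, hit = one_hit()
        for _ in range(50):
            track = rng.random(10)
            expected = sum(track[i] for i in range(hit.start, hit.end)) / 4
            assert motif_mean(track, hit).mean == pytest.approx(expected, abs=1e-12)

    def test_short_track_rejected(self):
        _, hit = one_hit()
        with pytest.raises(ValueError, match="out of range"):
            motif_mean(np.zeros(4), hit)


class TestBinAccessibility:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.20, "buried"),
            (0.60, "high"),
            (0.25, "moderate"),  # boundaries close on the moderate side
            (0.50, "moderate"),
            (0.249999, "buried"),
            (0.500001, "high"),
        ],
    )
    def test_threshold_partition(self, value, expected):
        assert bin_accessibility(value) == expected

    def test_planted_regimes_recovered(self, rng):
        """Buried/exposed cohorts far from the cuts bin correctly >= 99%."""
        from pymotif import ProteomeSpec, generate_proteome, generate_tracks

        records, gt = generate_proteome(ProteomeSpec(n=120, p_ppxy=1.0, p_lpxy=0.0, seed=11))
        correct = total = 0
        for regime, expected in (("buried", "buried"), ("exposed", "high")):
            table = generate_tracks(records, regime=regime, noise=0.05, seed=12)
            for rec in records:
                for hit in gt.hits[rec.identifier]:
                    total += 1
                    stat = motif_mean(table[rec.identifier], hit)
                    correct += bin_accessibility(stat.mean) == expected
        assert total >= 240
        assert correct / total >= 0.99


class TestPositionProfile:
    def test_identical_inputs_have_zero_sd(self):
        rec, hit = one_hit()
        table = TrackTable({"p1": np.linspace(0, 1, 10)})
        prof = position_profile(table, [hit, hit], flank=2)
        assert prof.window_length == 8
        np.testing.assert_allclose(prof.sds[prof.ns > 0], 0.0)

    def test_terminal_hit_clips_left_positions(self):
        rec = ProteinRecord("p1", "PPAYAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA")
        (hit,) = scan(rec)
        prof = position_profile(TrackTable({"p1": np.zeros(len(rec))}), [hit], flank=20)
        assert list(prof.ns[:20]) == [0] * 20
        assert prof.ns[20] == 1
        assert np.isnan(prof.means[0])

    def test_means_match_brute_force(self, rng):
        records, hits, tracks = [], [], {}
        for i in range(12):
            seq = "A" * int(rng.integers(10, 40)) + "PPAY" + "A" * int(rng.integers(0, 30))
            rec = ProteinRecord(f"p{i}", seq)
            records.append(rec)
            hits.extend(scan(rec, ))
            tracks[rec.identifier] = rng.random(len(seq))
        prof = position_profile(TrackTable(tracks), hits, flank=20)
        for c in range(prof.window_length):
            vals = []
            for h in hits:
                idx = h.start - 20 + c
                if 0 <= idx < len(tracks[h.protein_id]):
                    vals.append(tracks[h.protein_id][idx])
            assert prof.ns[c] == len(vals)
            if vals:
                assert prof.means[c] == pytest.approx(np.mean(vals), abs=1e-12)
                if len(vals) > 1:
                    assert prof.sds[c] == pytest.approx(np.std(vals, ddof=1), abs=1e-12)

    def test_permutation_invariance(self, rng):
        recs = [ProteinRecord(f"p{i}", "AAAAPPAYAAAA") for i in range(6)]
        hits = [h for r in recs for h in scan(r)]
        tracks = TrackTable({r.identifier: rng.random(12) for r in recs})
        fwd = position_profile(tracks, hits, flank=3)
        rev = position_profile(tracks, hits[::-1], flank=3)
        np.testing.assert_allclose(fwd.means, rev.means)
        np.testing.assert_allclose(fwd.ns, rev.ns)

    def test_missing_track_skipped_not_fatal(self):
        rec, hit = one_hit()
        other = ProteinRecord("p2", "AAPPAYAAAA")
        (hit2,) = scan(other)
        prof = position_profile(TrackTable({"p1": np.zeros(10)}), [hit, hit2], flank=1)
        assert prof.ns.max() == 1

    def test_no_usable_hits_rejected(self):
        _, hit = one_hit()
        with pytest.raises(ValueError):
            position_profile(TrackTable({}), [hit], flank=1)


def profile_from(means, ns=None):
    means = np.asarray(means, dtype=float)
    n = len(means)
    return PositionProfile(
        means=means,
        sds=np.zeros(n),
        ns=np.asarray(ns if ns is not None else np.ones(n, dtype=int)),
        flank=0,
        motif_length=n,
    )


class TestPairedT:
    def test_identical_profiles(self):
        a = profile_from([0.1, 0.5, 0.9])
        res = paired_t_test(a, profile_from([0.1, 0.5, 0.9]))
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)
        assert res.df == 2

    def test_textbook_toy_pairs(self):
        res = paired_t_test(profile_from([1, 2, 3]), profile_from([2, 4, 5]))
        # d = (-1, -2, -2): t = mean(d) / (sd(d)/sqrt(3)) = -5 exactly
        assert res.statistic == pytest.approx(-5.0, abs=1e-12)
        assert res.df == 2
        assert res.pvalue == pytest.approx(2 * stats.t.sf(5.0, 2), abs=1e-12)

    def test_constant_offset_sign_and_magnitude(self, rng):
        base = rng.random(44)
        noisy = base + 0.3 + rng.normal(0, 1e-6, 44)
        res = paired_t_test(profile_from(noisy), profile_from(base))
        assert res.statistic > 1e4  # |t| explodes as within-pair SD -> 0

    def test_unequal_windows_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test(profile_from([1, 2]), profile_from([1, 2, 3]))

    def test_textbook_formula_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 44))
            a, b = rng.random(n), rng.random(n)
            res = paired_t_test(profile_from(a), profile_from(b))
            d = a - b
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p = 2 * stats.t.sf(abs(t), n - 1)
            assert res.statistic == pytest.approx(t, abs=1e-9)
            assert res.pvalue == pytest.approx(p, abs=1e-9)


class TestWelchT:
    def test_identical_groups(self):
        res = welch_t_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0)
        assert res.kind == "welch"

    def test_separated_groups_tiny_p(self, rng):
        a = np.zeros(4) + rng.normal(0, 1e-3, 4)
        b = np.ones(4) + rng.normal(0, 1e-3, 4)
        assert welch_t_test(a, b).pvalue < 1e-4

    def test_df_bounded_by_pooled_df(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 15)
        assert welch_t_test(a, b).df <= len(a) + len(b) - 2

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_textbook_formula_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            na, nb = int(rng.integers(2, 40)), int(rng.integers(2, 40))
            a, b = rng.random(na), rng.random(nb)
            res = welch_t_test(a, b)
            sa, sb = a.var(ddof=1) / na, b.var(ddof=1) / nb
            t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
            df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
            p = 2 * stats.t.sf(abs(t), df)
            assert res.statistic == pytest.approx(t, abs=1e-9)
            assert res.df == pytest.approx(df, abs=1e-9)
            assert res.pvalue == pytest.approx(p, abs=1e-9)


class TestCorrelateTable:
    def test_self_and_negated_reference(self):
        df = pd.DataFrame({"ref": [1.0, 2, 3, 4], "same": [1.0, 2, 3, 4], "neg": [-1.0, -2, -3, -4]})
        rs = correlate_table(df, "ref")
        assert rs["same"] == pytest.approx(1.0)
        assert rs["neg"] == pytest.approx(-1.0)

    def test_constant_column_is_undefined(self):
        df = pd.DataFrame({"ref": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        assert np.isnan(correlate_table(df, "ref")["flat"])

    def test_matches_covariance_formula(self, rng):
        df = pd.DataFrame(rng.random((10, 4)), columns=["ref", "a", "b", "c"])
        rs = correlate_table(df, "ref")
        ref = df["ref"].to_numpy()
        for col in ("a", "b", "c"):
            x = df[col].to_numpy()
            expected = ((x - x.mean()) * (ref - ref.mean())).sum() / (
                np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((ref - ref.mean()) ** 2).sum())
            )
            assert rs[col] == pytest.approx(expected, abs=1e-12)

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"ref": [1.0, 2], "a": [3.0, 4]})
        with pytest.raises(ValueError, match=">= 3 rows"):
            correlate_table(df, "ref")
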