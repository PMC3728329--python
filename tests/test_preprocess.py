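"""Preprocessing: readers, background correction, quantile normalization,
median polish, and the IQR detection filter."""

import numpy as np
import pandas as pd
import pytest

import radresponse as rr
from radresponse.errors import DataError, FormatError, ParameterError
from radresponse.preprocess import _median_polish

from conftest import make_matrix


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def quantile_normalize_oracle(x):
    """Sort-average-restore reference implementation, ties averaged."""
    x = np.asarray(x, dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        restored = np.empty_like(ref)
        restored[order] = ref
        for v in np.unique(col):
            mask = col == v
            restored[mask] = restored[mask].mean()
        out[:, j] = restored
    return out


def iqr_oracle(row):
    """Linear-interpolation quartiles by explicit order statistics."""
    s = np.sort(np.asarray(row, dtype=float))
    n = len(s)

    def quantile(q):
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    return quantile(0.75) - quantile(0.25)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

class TestReadMatrix:
    def test_tsv_round_trip(self, tmp_path):
        m = make_matrix([[1.5, 2.0], [3.25, -4.0]])
        path = tmp_path / "m.tsv"
        rr.write_matrix(m, path)
        back = rr.read_matrix(path)
        pd.testing.assert_frame_equal(back.data, m.data, check_names=False)

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(FormatError):
            rr.read_matrix(path)

    @pytest.mark.parametrize(
        "content",
        [
            "id\ts1\ts2\ng1\t1.0\n",             # ragged row
            "id\ts1\ts2\ng1\t1.0\tx\n",          # non-numeric cell
            "id\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n",  # duplicate row id
        ],
    )
    def test_malformed_tsv(self, tmp_path, content):
        path = tmp_path / "bad.tsv"
        path.write_text(content)
        with pytest.raises(FormatError):
            rr.read_matrix(path)

    def test_series_matrix(self, tmp_path):
        content = (
            '!Series_title\t"synthetic fixture"\n'
            '!Sample_geo_accession\t"GSM1"\t"GSM2"\t"GSM3"\n'
            '!Sample_title\t"A rep1"\t"B rep1"\t"C rep1"\n'
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\t"GSM3"\n'
            '"ps1"\t5.1\t6.2\t7.3\n'
            '"ps2"\t4.0\t4.5\t5.0\n'
            "!series_matrix_table_end\n"
        )
        path = tmp_path / "series.txt"
        path.write_text(content)
        m = rr.read_matrix(path, format="series_matrix")
        assert m.shape == (2, 3)
        assert list(m.col_ids) == ["GSM1", "GSM2", "GSM3"]
        assert m.sample_metadata["Sample_title"] == ["A rep1", "B rep1", "C rep1"]
        assert m.data.loc["ps2", "GSM3"] == 5.0

    def test_series_matrix_sample_count_mismatch(self, tmp_path):
        content = (
            '!Sample_geo_accession\t"GSM1"\t"GSM2"\n'
            "!series_matrix_table_begin\n"
            "ID_REF\tGSM1\n"
            "ps1\t5.1\n"
            "!series_matrix_table_end\n"
        )
        path = tmp_path / "series.txt"
        path.write_text(content)
        with pytest.raises(FormatError):
            rr.read_matrix(path, format="series_matrix")


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

class TestBackgroundCorrect:
    def test_pure_signal_limit(self, rng):
        # exponential signal, essentially no normal noise: output ~ input
        signal = rng.exponential(200.0, size=(4000, 3)) + 1e-3
        m = make_matrix(signal, scale="raw")
        out = rr.background_correct(m)
        big = signal > np.quantile(signal, 0.25)
        rel = np.abs(out.values[big] - signal[big]) / signal[big]
        assert np.median(rel) < 0.25
        assert (out.values > 0).all()

    def test_output_positive_and_bounded(self, rng):
        raw = rng.normal(100, 10, size=(2000, 4)) + rng.exponential(150, (2000, 4))
        raw = np.clip(raw, 1e-3, None)
        out = rr.background_correct(make_matrix(raw, scale="raw"))
        assert (out.values > 0).all()
        # corrected signal never exceeds the observed intensity by more
        # than a noise-scale slack
        assert (out.values <= raw + 30.0).all()

    def test_mean_signal_recovered(self, rng):
        # known convolution: N(60, 8) background + Exp(alpha=250) signal
        n = 20000
        signal = rng.exponential(250.0, (n, 2))
        raw = signal + rng.normal(60.0, 8.0, (n, 2))
        raw = np.clip(raw, 1e-3, None)
        out = rr.background_correct(make_matrix(raw, scale="raw"))
        for j in range(2):
            assert out.values[:, j].mean() == pytest.approx(
                signal[:, j].mean(), rel=0.10
            )

    def test_zero_variance_column(self):
        m = make_matrix(np.full((50, 2), 7.0), scale="raw")
        with pytest.raises(DataError):
            rr.background_correct(m)

    def test_requires_raw_scale(self):
        with pytest.raises(ParameterError):
            rr.background_correct(make_matrix([[1.0, 2.0]], scale="log2"))


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0, 5.0])
        m = make_matrix(np.column_stack([col, col, col]))
        out = rr.quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_two_column_hand_example(self):
        m = make_matrix(np.column_stack([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        out = rr.quantile_normalize(m)
        expected = np.column_stack([[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])
        np.testing.assert_allclose(out.values, expected)

    def test_matches_oracle_random(self, rng):
        for trial in range(20):
            n = int(rng.integers(3, 40))
            k = int(rng.integers(2, 6))
            x = rng.normal(size=(n, k))
            if trial % 3 == 0:  # inject ties
                x = np.round(x, 1)
            out = rr.quantile_normalize(make_matrix(x))
            np.testing.assert_allclose(
                out.values, quantile_normalize_oracle(x), atol=1e-12
            )

    def test_columns_share_distribution(self, rng):
        x = rng.normal(size=(200, 5)) * rng.uniform(0.5, 3, 5) + rng.normal(0, 2, 5)
        out = rr.quantile_normalize(make_matrix(x)).values
        for stat in (np.mean, np.median, lambda v: np.subtract(*np.percentile(v, [75, 25]))):
            vals = [stat(out[:, j]) for j in range(5)]
            np.testing.assert_allclose(vals, vals[0], atol=1e-9)

    def test_idempotent(self, rng):
        x = rng.normal(size=(100, 4))
        once = rr.quantile_normalize(make_matrix(x))
        twice = rr.quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_rank_order_preserved(self, rng):
        x = rng.normal(size=(60, 3))
        out = rr.quantile_normalize(make_matrix(x)).values
        for j in range(3):
            assert (np.argsort(out[:, j]) == np.argsort(x[:, j])).all()

    def test_single_column_rejected(self):
        with pytest.raises(ParameterError):
            rr.quantile_normalize(make_matrix([[1.0], [2.0]]))


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------

class TestMedianPolish:
    def _additive(self, rng, nprobe=11, nsamp=15):
        probe = rng.normal(0, 1, nprobe)
        sample = rng.normal(7, 2, nsamp)
        return probe[:, None] + sample[None, :], sample

    def test_additive_exact(self, rng):
        block, sample = self._additive(rng)
        est = _median_polish(block.copy(), tol=1e-9, max_cycles=10)
        # recovered sample effects equal planted ones up to a constant
        np.testing.assert_allclose(est - est.mean(), sample - sample.mean(), atol=1e-9)

    def test_outlier_robustness(self, rng):
        block, _ = self._additive(rng)
        clean = _median_polish(block.copy(), tol=1e-9, max_cycles=10)
        dirty = block.copy()
        dirty[3, 7] += 50.0
        est = _median_polish(dirty, tol=1e-9, max_cycles=10)
        assert np.max(np.abs((est - est.mean()) - (clean - clean.mean()))) < 0.05

    def test_summarize_groups_and_single_probe_passthrough(self, rng):
        block, sample = self._additive(rng, nprobe=4, nsamp=5)
        rows = np.vstack([block, (sample + 1.0)[None, :]])
        ids = [f"a:{j}" for j in range(4)] + ["b:0"]
        m = rr.ExpressionMatrix(
            pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(5)])
        )
        pmap = pd.Series({f"a:{j}": "psA" for j in range(4)} | {"b:0": "psB"})
        out = rr.median_polish_summarize(m, pmap)
        assert list(out.row_ids) == ["psA", "psB"]
        np.testing.assert_allclose(out.data.loc["psB"], sample + 1.0)
        est = out.data.loc["psA"].to_numpy()
        np.testing.assert_allclose(est - est.mean(), sample - sample.mean(), atol=1e-9)

    def test_unmapped_probe_rejected(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(DataError):
            rr.median_polish_summarize(m, {"g0": "ps1"})

    def test_convergence_on_noisy_block(self, rng):
        block = rng.normal(size=(11, 15))
        est = _median_polish(block.copy(), tol=0.01, max_cycles=10)
        assert np.isfinite(est).all()


# ---------------------------------------------------------------------------
# IQR filter
# ---------------------------------------------------------------------------

class TestIqrFilter:
    def test_constant_row_removed(self):
        m = make_matrix([[5.0] * 6, [1, 2, 3, 4, 5, 6]])
        kept, removed = rr.iqr_filter(m)
        assert list(removed) == ["g0"]
        assert list(kept.row_ids) == ["g1"]

    def test_boundary_exactly_threshold_kept(self):
        # row engineered so IQR == 0.2 exactly under linear interpolation:
        # the rule is strictly "less than 0.2", so it must be kept
        row = [0.0, 0.0, 0.2, 0.2]  # q1=0.0, q3=0.2
        m = make_matrix([row])
        assert iqr_oracle(row) == pytest.approx(0.2, abs=1e-15)
        kept, removed = rr.iqr_filter(m, rr.FilterConfig(0.2))
        assert len(removed) == 0 and kept.shape[0] == 1

    def test_four_value_row_decided_by_oracle(self):
        row = [0.0, 0.1, 0.2, 0.3]  # q1=0.075, q3=0.225 under linear interpolation
        assert iqr_oracle(row) == pytest.approx(0.15, abs=1e-15)
        kept, removed = rr.iqr_filter(make_matrix([row]), rr.FilterConfig(0.2))
        assert list(removed) == ["g0"]

    def test_matches_oracle_random(self, rng):
        x = rng.normal(0, 0.15, size=(300, 8))
        m = make_matrix(x)
        kept, removed = rr.iqr_filter(m, rr.FilterConfig(0.2))
        for i, rid in enumerate(m.row_ids):
            expected_removed = iqr_oracle(x[i]) < 0.2
            assert (rid in set(removed)) == expected_removed

    def test_partition_and_zero_threshold(self, rng):
        x = rng.normal(size=(50, 5))
        x[7] = 3.0  # constant row
        m = make_matrix(x)
        kept, removed = rr.iqr_filter(m, rr.FilterConfig(0.0))
        assert set(kept.row_ids) | set(removed) == set(m.row_ids)
        assert set(kept.row_ids) & set(removed) == set()
        assert list(removed) == []  # IQR of the constant row is 0, not < 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            rr.FilterConfig(-0.1)
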