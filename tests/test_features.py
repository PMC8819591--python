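"""Gapped-dipeptide composition, ACC descriptors, and matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raacdip.features import (
    FeatureMatrix,
    GappedDipeptideSpec,
    acc_features,
    default_property_table,
    dipeptide_feature_names,
    extract_feature_matrix,
    gapped_dipeptide_counts,
    gapped_dipeptide_frequencies,
    parse_feature_name,
    standardize_property_table,
)
from raacdip.io_seq import STANDARD_AA, ProteinRecord
from raacdip.raac import default_scheme, parse_scheme

ALPHABET = default_scheme().representatives


# ---------------------------------------------------------------------------
# independent oracles


def naive_counts(seq, gap, alphabet):
    """Double-loop reference for gapped-dipeptide counting."""
    counts = {
        GappedDipeptideSpec(a, b, gap).name: 0 for a in alphabet for b in alphabet
    }
    for i in range(len(seq) - gap - 1):
        counts[GappedDipeptideSpec(seq[i], seq[i + gap + 1], gap).name] += 1
    return counts


def naive_acc(seq, props, maxlag):
    """Triple-loop reference for the lagged covariance descriptors."""
    profile = props.loc[list(seq)].to_numpy(dtype=float)
    L, p = profile.shape
    means = profile.mean(axis=0)
    out = {}
    names = list(props.columns)
    for j in range(p):
        for g in range(1, maxlag + 1):
            s = sum(
                (profile[i, j] - means[j]) * (profile[i + g, j] - means[j])
                for i in range(L - g)
            )
            out[f"AC.{names[j]}.lag{g}"] = s / (L - g)
    for j in range(p):
        for k in range(p):
            if j == k:
                continue
            for g in range(1, maxlag + 1):
                s = sum(
                    (profile[i, j] - means[j]) * (profile[i + g, k] - means[k])
                    for i in range(L - g)
                )
                out[f"CC.{names[j]}.{names[k]}.lag{g}"] = s / (L - g)
    return out


# ---------------------------------------------------------------------------
# feature-name parsing


class TestFeatureNames:
    @pytest.mark.parametrize(
        "name,first,second,gap",
        [
            ("FC", "F", "C", 0),
            ("F*C", "F", "C", 1),
            ("G**C", "G", "C", 2),
            ("FC*", "F", "C", 1),  # trailing-star alias
            ("GC**", "G", "C", 2),
            ("fc*", "F", "C", 1),
        ],
    )
    def test_parse_accepts_canonical_and_alias(self, name, first, second, gap):
        spec = parse_feature_name(name)
        assert (spec.first, spec.second, spec.gap) == (first, second, gap)

    @pytest.mark.parametrize("bad", ["F", "FCC", "F*C*", "*FC", "F-C", ""])
    def test_parse_rejects_malformed_names(self, bad):
        with pytest.raises(ValueError):
            parse_feature_name(bad)

    def test_canonical_name_has_stars_between(self):
        assert GappedDipeptideSpec("F", "C", 2).name == "F**C"


# ---------------------------------------------------------------------------
# gapped-dipeptide counts and frequencies


class TestGappedDipeptides:
    def test_reduced_motif_worked_example(self):
        counts = gapped_dipeptide_counts("VGGVGGGGGGGFGC", 1, ALPHABET)
        assert counts["F*C"] == 1
        assert counts["G*C"] == 0
        assert counts["G*G"] == 7
        assert sum(counts.values()) == 14 - 1 - 1
        assert counts == naive_counts("VGGVGGGGGGGFGC", 1, ALPHABET)

    def test_adjacent_pairs_direct_enumeration(self):
        counts = gapped_dipeptide_counts("GGG", 0, ALPHABET)
        assert counts["GG"] == 2
        assert sum(counts.values()) == 2

    def test_degenerate_length_gives_all_zeros(self):
        counts = gapped_dipeptide_counts("FC", 1, ALPHABET)
        assert all(v == 0 for v in counts.values())

    def test_frequency_worked_example(self):
        freqs = gapped_dipeptide_frequencies("VGGVGGGGGGGFGC", 1, ALPHABET)
        assert freqs["F*C"] == pytest.approx(1 / 12)

    def test_zero_denominator_convention(self):
        freqs = gapped_dipeptide_frequencies("GG", 2, ALPHABET)
        assert all(v == 0.0 for v in freqs.values())

    def test_counts_match_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(202)
        for _ in range(300):
            k = int(rng.integers(1, 21))
            alphabet = list(STANDARD_AA[:k])
            L = int(rng.integers(0, 51))
            gap = int(rng.integers(0, 4))
            seq = "".join(rng.choice(alphabet, size=L))
            assert gapped_dipeptide_counts(seq, gap, alphabet) == naive_counts(
                seq, gap, alphabet
            )

    @settings(deadline=None, max_examples=60)
    @given(
        seq=st.text(alphabet="GFVCW", min_size=0, max_size=60),
        gap=st.integers(min_value=0, max_value=3),
    )
    def test_count_partition_and_frequency_normalization(self, seq, gap):
        counts = gapped_dipeptide_counts(seq, gap, ALPHABET)
        total = sum(counts.values())
        assert all(v >= 0 for v in counts.values())
        assert total == max(0, len(seq) - gap - 1)
        fsum = sum(gapped_dipeptide_frequencies(seq, gap, ALPHABET).values())
        assert fsum == pytest.approx(1.0) or fsum == 0.0


# ---------------------------------------------------------------------------
# ACC


def one_property_table(**values):
    col = {ch: float(values.get(ch, 0.0)) for ch in STANDARD_AA}
    return pd.DataFrame({"p": col}, index=list(STANDARD_AA))


class TestACC:
    def test_homopolymer_gives_all_zeros(self):
        out = acc_features("A" * 30, default_property_table(), maxlag=2)
        assert all(v == pytest.approx(0.0) for v in out.values())

    def test_default_configuration_dimension(self):
        out = acc_features("ACDEFGHIK", default_property_table(), maxlag=2)
        assert len(out) == 18

    def test_hand_computed_lag1_autocovariance(self):
        # profile of "ACA" is (1, -1, 1): mean 1/3, deviations (2/3, -4/3, 2/3)
        props = one_property_table(A=1.0, C=-1.0)
        out = acc_features("ACA", props, maxlag=1)
        assert out["AC.p.lag1"] == pytest.approx(-8 / 9)

    def test_sequence_not_longer_than_maxlag_raises(self):
        with pytest.raises(ValueError, match="maxlag"):
            acc_features("AC", default_property_table(), maxlag=2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(321)
        props = default_property_table()
        for _ in range(200):
            L = int(rng.integers(4, 13))
            maxlag = int(rng.integers(1, min(3, L - 1) + 1))
            seq = "".join(rng.choice(list(STANDARD_AA), size=L))
            got = acc_features(seq, props, maxlag)
            want = naive_acc(seq, props, maxlag)
            assert got.keys() == want.keys()
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-10, abs=1e-12)


def test_property_table_is_standardized():
    table = default_property_table()
    assert list(table.index) == list(STANDARD_AA)
    assert np.allclose(table.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(table.std(axis=0, ddof=0), 1.0, atol=1e-12)


def test_constant_property_column_rejected():
    with pytest.raises(ValueError, match="constant"):
        standardize_property_table(one_property_table())


# ---------------------------------------------------------------------------
# matrix assembly


class TestExtractFeatureMatrix:
    def test_default_configuration_has_93_columns(self, dataset7):
        matrix = extract_feature_matrix(dataset7.records[:5])
        assert matrix.n_features == 93

    def test_dipeptide_block_comes_first(self, dataset7):
        matrix = extract_feature_matrix(dataset7.records[:3])
        names = matrix.feature_names
        expected = dipeptide_feature_names(ALPHABET, (0, 1, 2))
        assert names[:75] == expected
        assert all(n.startswith(("AC.", "CC.")) for n in names[75:])
        assert len(names[75:]) == 18

    def test_degenerate_single_cluster_scheme(self):
        scheme = parse_scheme(STANDARD_AA)
        records = [ProteinRecord("a", "MKVL"), ProteinRecord("b", "CC")]
        matrix = extract_feature_matrix(
            records, scheme=scheme, gaps=(0,), include_acc=False
        )
        assert matrix.n_features == 1
        assert np.allclose(matrix.X, 1.0)

    @pytest.mark.parametrize("k,gaps,p,maxlag", [(5, (0, 1, 2), 3, 2), (2, (0,), 2, 3)])
    def test_column_count_formula(self, k, gaps, p, maxlag):
        if k == 5:
            scheme = default_scheme()
        else:
            # two clusters: C alone vs everything else
            rest = "".join(ch for ch in STANDARD_AA if ch != "C")
            scheme = parse_scheme(f"{rest}-C")
        props = default_property_table().iloc[:, :p]
        records = [ProteinRecord("a", "ACDEFGHIKLMNP")]
        matrix = extract_feature_matrix(
            records, scheme=scheme, gaps=gaps, props=props, maxlag=maxlag
        )
        assert matrix.n_features == k * k * len(gaps) + p * maxlag + p * (p - 1) * maxlag

    def test_count_mode_yields_integers(self, dataset7):
        matrix = extract_feature_matrix(
            dataset7.records[:4], values="count", include_acc=False
        )
        assert np.allclose(matrix.X, np.round(matrix.X))

    def test_labels_are_carried(self, dataset7):
        matrix = extract_feature_matrix(dataset7.records[:5] + dataset7.records[-5:])
        assert matrix.labels is not None
        assert sorted(matrix.labels.unique()) == [0, 1]

    def test_tsv_round_trip(self, tmp_path, dataset7):
        matrix = extract_feature_matrix(dataset7.records[:6])
        path = tmp_path / "features.tsv"
        matrix.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        assert back.feature_names == matrix.feature_names
        assert np.allclose(back.X, matrix.X)
        assert (back.y == matrix.y).all()

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError, match="records"):
            extract_feature_matrix([])
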