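import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbep.features import (
    DIPEPTIDE_DIM,
    WindowConfig,
    dipeptide_composition,
    encode_residues,
    load_scales,
    normalize_pssm,
    window_encode,
)
from cbep.io import (
    AntigenRecord,
    DisorderProfile,
    ProfileSet,
    PssmProfile,
    SecondaryStructureProfile,
)


def make_profiles(rng, L):
    probs = rng.dirichlet((2, 2, 2), size=L)
    return ProfileSet(
        pssm=PssmProfile(scores=rng.randint(-8, 9, size=(L, 20))),
        ss2=SecondaryStructureProfile(probs=probs),
        disorder=DisorderProfile(status=rng.randint(0, 2, size=L)),
    )


class TestLogisticNormalization:
    def test_midpoint(self):
        assert normalize_pssm(np.array([0]))[0] == 0.5

    def test_known_value(self):
        # independent arithmetic: 1/(1+e^-2)
        np.testing.assert_allclose(normalize_pssm(np.array([2]))[0], 0.8807970779, atol=1e-9)

    def test_open_unit_interval(self, rng):
        x = rng.randint(-30, 31, size=200)
        f = normalize_pssm(x)
        assert ((f > 0) & (f < 1)).all()
        # monotone in the raw score
        assert (np.diff(normalize_pssm(np.arange(-10, 11))) > 0).all()


class TestWindowEncode:
    def test_pad_width(self):
        assert WindowConfig(9).pad == 4
        assert WindowConfig(11).pad == 5

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            WindowConfig(10)

    def test_window_of_one_is_identity(self, rng):
        table = rng.normal(size=(7, 4))
        np.testing.assert_array_equal(window_encode(table, WindowConfig(1)), table)

    def test_pssm_window_width(self, rng):
        out = window_encode(rng.normal(size=(15, 20)), WindowConfig(11))
        assert out.shape == (15, 220)

    def test_terminal_windows_padded(self, rng):
        table = rng.normal(size=(6, 2))
        out = window_encode(table, WindowConfig(5), pad_value=0.0)
        # first residue: two pad rows then rows 0..2
        np.testing.assert_array_equal(out[0, :4], np.zeros(4))
        np.testing.assert_array_equal(out[0, 4:], table[:3].ravel())

    def test_oversized_window_allowed(self, rng):
        table = rng.normal(size=(3, 2))
        out = window_encode(table, WindowConfig(9))
        assert out.shape == (3, 18)

    def test_reversal_symmetry(self, rng):
        # window of residue i on the chain equals the position-reversed
        # window of residue L-1-i on the reversed chain
        table = rng.normal(size=(9, 3))
        N = 5
        fwd = window_encode(table, WindowConfig(N))
        rev = window_encode(table[::-1], WindowConfig(N))
        L = len(table)
        for i in range(L):
            win = fwd[i].reshape(N, 3)
            win_rev = rev[L - 1 - i].reshape(N, 3)[::-1]
            np.testing.assert_array_equal(win, win_rev)


class TestDipeptideComposition:
    def test_vector_length(self):
        assert dipeptide_composition("MKV").shape == (DIPEPTIDE_DIM,)

    def test_aa_pair(self):
        v = dipeptide_composition("AA")
        assert v[0] == 1.0 and v[:20].sum() == 1.0
        assert v[20] == 1.0 and v[20:].sum() == 1.0  # dipeptide 'AA'

    def test_aca_hand_enumeration(self):
        # brute force: pairs of "ACA" are AC and CA, one each of 2
        v = dipeptide_composition("ACA")
        a, c = 0, 1  # alphabetical indices of A, C
        np.testing.assert_allclose(v[a], 2 / 3)
        np.testing.assert_allclose(v[c], 1 / 3)
        np.testing.assert_allclose(v[20 + a * 20 + c], 0.5)  # AC
        np.testing.assert_allclose(v[20 + c * 20 + a], 0.5)  # CA
        assert v[20:].sum() == pytest.approx(1.0)

    def test_unknown_residue_skipped_in_pairs(self):
        # "AXA": pairs AX and XA both contain X, so no countable pair
        v = dipeptide_composition("AXA")
        assert v[20:].sum() == 0.0
        assert v[0] == 1.0  # A frequency over standard residues

    def test_single_residue_has_zero_dipeptide_part(self):
        v = dipeptide_composition("W")
        assert v[20:].sum() == 0.0 and v[:20].sum() == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dipeptide_composition("")

    def test_dipeptide_part_sums_to_one(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        assert dipeptide_composition(seq)[20:].sum() == pytest.approx(1.0)


class TestScales:
    def test_minmax_normalized(self):
        scales = load_scales()
        assert scales.table.min(axis=0).tolist() == [0.0] * 6
        assert scales.table.max(axis=0).tolist() == [1.0] * 6

    def test_unknown_residue_zero(self):
        enc = load_scales().encode("AXA")
        assert (enc[1] == 0).all() and (enc[0] == enc[2]).all()


@pytest.fixture(scope="module")
def encoded():
    rng = np.random.RandomState(3)
    L = 25
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
    record = AntigenRecord(id="t", sequence=seq)
    return encode_residues(record, make_profiles(rng, L))


class TestEncodeResidues:
    def test_total_width_750(self, encoded):
        assert encoded.values.shape[1] == 750

    def test_block_widths(self, encoded):
        widths = {name: encoded.block(name).shape[1]
                  for name, _ in encoded.block_layout}
        assert widths == {
            "evolutionary": 220, "secondary": 33, "disorder": 11,
            "physicochemical": 66, "dipeptide": 420,
        }

    def test_dipeptide_block_constant_across_residues(self, encoded):
        block = encoded.block("dipeptide")
        assert (block == block[0]).all()

    def test_evolutionary_block_range(self, encoded):
        evo = encoded.block("evolutionary")
        assert (((evo > 0) & (evo < 1)) | (evo == 0)).all()
        # the center window offset (columns 100:120 at N=11) is never padding
        center = evo[:, 100:120]
        assert ((center > 0) & (center < 1)).all()

    def test_disorder_block_binary(self, encoded):
        assert np.isin(encoded.block("disorder"), (0.0, 1.0)).all()

    def test_profile_length_mismatch_named(self):
        rng = np.random.RandomState(0)
        record = AntigenRecord(id="t", sequence="ACDEFGHIKL")
        profiles = make_profiles(rng, 9)
        with pytest.raises(ValueError, match="evolutionary"):
            encode_residues(record, profiles)

    @given(
        n=st.sampled_from([1, 3, 5, 7, 9, 11, 13]),
        L=st.integers(min_value=5, max_value=25),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_width_identity_any_odd_window(self, n, L, seed):
        rng = np.random.RandomState(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
        record = AntigenRecord(id="t", sequence=seq)
        fm = encode_residues(record, make_profiles(rng, L), cfg=WindowConfig(n))
        assert fm.values.shape == (L, 30 * n + 420)
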