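import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peptraits import physchem as pc
from peptraits import synthetic_data as sd
from peptraits.peptide_io import Peptide, PeptideError

AA = sorted("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="module")
def scale():
    return pc.load_hydrophobicity()


class TestWindowHydrophobicity:
    def test_homopolymer_equals_scale_value(self, scale):
        p = Peptide("a", "A" * 20)
        assert pc.max_window_hydrophobicity(p, scale) == pytest.approx(scale["A"])

    def test_single_window_is_its_mean(self, scale):
        seq = "GIGKFLHSA"
        p = Peptide("x", seq)
        expected = sum(scale[aa] for aa in seq) / 9
        assert pc.max_window_hydrophobicity(p, scale) == pytest.approx(expected)

    def test_matches_exhaustive_scan(self, scale):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(AA, size=40))
        p = Peptide("x", seq)
        brute = max(
            sum(scale[aa] for aa in seq[s : s + 9]) / 9 for s in range(len(seq) - 8)
        )
        assert pc.max_window_hydrophobicity(p, scale) == pytest.approx(brute)

    def test_too_short_errors(self, scale):
        with pytest.raises(PeptideError):
            pc.max_window_hydrophobicity(Peptide("s", "ACDEF"), scale)


class TestNetCharge:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGGGGGGGGGGG", 0),
            ("KKRRDDEEGGGG", 0),
            ("GIGKFLHSAKKFGKAFVGEIMNS", 3),  # magainin II: 4 K, 0 R, 0 D, 1 E
            ("KRKRKR", 6),
            ("DEDE", -4),
            ("HHHH", 0),  # His neutral at pH 7.4
        ],
    )
    def test_known_charges(self, seq, expected):
        assert pc.net_charge(seq) == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from(AA), min_size=1, max_size=30),
        st.lists(st.sampled_from(AA), min_size=1, max_size=30),
    )
    def test_additive_over_concatenation(self, a, b):
        sa, sb = "".join(a), "".join(b)
        assert pc.net_charge(sa + sb) == pc.net_charge(sa) + pc.net_charge(sb)


class TestHydrophobicMoment:
    def test_homopolymer_moment_vanishes_over_full_turns(self, scale):
        # 18 residues x 100 deg = 5 full turns: unit vectors cancel
        m = pc.mean_hydrophobic_moment("L" * 18, scale)
        assert m == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_vector_sum(self, scale):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(AA, size=15))
        delta = math.radians(100)
        mx = sum(scale[aa] * math.cos(n * delta) for n, aa in enumerate(seq))
        my = sum(scale[aa] * math.sin(n * delta) for n, aa in enumerate(seq))
        expected = math.hypot(mx, my) / len(seq)
        assert pc.mean_hydrophobic_moment(seq, scale) == pytest.approx(expected)

    def test_periodic_design_beats_scrambles(self, scale):
        design = sd.designed_amphiphilic(18, 5, seed=0)
        m0 = pc.mean_hydrophobic_moment(design.sequence, scale)
        beaten = sum(
            m0 > pc.mean_hydrophobic_moment(sd.scramble(design, seed=s).sequence, scale)
            for s in range(100)
        )
        assert beaten >= 95

    def test_not_invariant_to_scale_offset(self, scale):
        seq = "GIGKFLHSA"
        shifted = {aa: h + 1.0 for aa, h in scale.items()}
        assert pc.mean_hydrophobic_moment(seq, scale) != pytest.approx(
            pc.mean_hydrophobic_moment(seq, shifted)
        )

    def test_short_segment_errors(self, scale):
        with pytest.raises(PeptideError):
            pc.mean_hydrophobic_moment("A", scale)


class TestFindHelix:
    def test_peptide_shorter_than_min_len_gives_none(self, scale):
        assert pc.find_amphiphilic_helix(Peptide("s", "ACDEFGHI"), scale) is None

    def test_homopolymer_never_qualifies(self, scale):
        p = Peptide("l", "L" * 40)
        assert pc.find_amphiphilic_helix(p, scale) is None

    def test_designed_peptide_detected_with_known_charge(self, scale):
        p = sd.designed_amphiphilic(18, 5, seed=1)
        helix = pc.find_amphiphilic_helix(p, scale)
        assert helix is not None
        assert helix.length >= 9
        assert helix.net_charge == 5

    def test_ties_break_to_most_n_terminal(self, scale):
        # two identical amphiphilic copies separated by a long glycine spacer:
        # equal-length qualifying windows, the N-terminal one must win
        motif = sd.designed_amphiphilic(12, 3, seed=2).sequence
        p = Peptide("twin", motif + "G" * 15 + motif)
        m_motif = pc.mean_hydrophobic_moment(motif, scale)
        crit = pc.HelixCriterion(moment_threshold=m_motif - 1e-9)
        helix = pc.find_amphiphilic_helix(p, scale, crit)
        assert helix is not None
        assert helix.start == 0 and helix.length >= 12

    def test_lowering_threshold_never_shortens_helix(self, scale, random_set):
        for p in random_set[:15]:
            strict = pc.find_amphiphilic_helix(p, scale, pc.HelixCriterion(moment_threshold=0.45))
            loose = pc.find_amphiphilic_helix(p, scale, pc.HelixCriterion(moment_threshold=0.30))
            if strict is not None:
                assert loose is not None and loose.length >= strict.length

    def test_scrambling_destroys_amphiphilicity(self, scale):
        """Designed periodic peptides lose their helix (or shorten it) on scrambling."""
        design = sd.designed_amphiphilic(21, 5, seed=3)
        helix = pc.find_amphiphilic_helix(design, scale)
        assert helix is not None
        destroyed = 0
        for s in range(100):
            scr = pc.find_amphiphilic_helix(sd.scramble(design, seed=s), scale)
            if scr is None or scr.length < helix.length:
                destroyed += 1
        assert destroyed >= 90


class TestAmphiphilicFraction:
    def test_no_helix_is_zero(self):
        assert pc.amphiphilic_fraction(Peptide("x", "A" * 20), None) == 0.0

    def test_full_coverage_is_one(self):
        p = Peptide("x", "A" * 20)
        h = pc.AmphiphilicHelix(0, 20, 1.0, 0)
        assert pc.amphiphilic_fraction(p, h) == 1.0

    def test_partial_coverage(self):
        p = Peptide("x", "A" * 45)
        h = pc.AmphiphilicHelix(5, 23, 1.0, 0)
        assert pc.amphiphilic_fraction(p, h) == pytest.approx(18 / 45)


class TestFeatureTable:
    def test_columns_and_missing_helix_handling(self, random_set):
        table = pc.feature_table(random_set[:20])
        expected = {
            "length", "max_hydrophobicity", "net_charge", "helix_start",
            "helix_end", "helix_len", "helix_net_charge", "helix_fraction",
            "helix_moment",
        }
        assert expected <= set(table.columns)
        no_helix = table["helix_len"].isna()
        assert (table.loc[no_helix, "helix_fraction"] == 0).all()

    def test_reported_coordinates_are_one_based_inclusive(self, scale):
        p = sd.designed_amphiphilic(18, 5, seed=1)
        helix = pc.find_amphiphilic_helix(p, scale)
        s, e = helix.report_coords()
        assert s >= 1 and e <= len(p)
        assert e - s + 1 == helix.length
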