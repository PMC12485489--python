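"""Mode tree, signature/density rules, smoothing and labels."""

import itertools

import pytest
from conftest import reference_smooth

from barbedwire.mode_classifier import (
    Mode,
    assign_mode,
    high_outlier_density,
    make_label,
    signature_outliers,
    smooth,
)
from barbedwire.validation_flags import (
    CIS_NONPRO,
    CIS_PRO,
    TRANS,
    TWISTED,
    ValidationFlags,
)

B, P, N = Mode.BARBED_WIRE, Mode.PSEUDOSTRUCTURE, Mode.NEAR_PREDICTIVE


class TestModeTree:
    """The decision tree: pLDDT, then packing, then outliers."""

    EXPECTED = {
        # (low_plddt, packed, outliers) -> mode
        (False, True, False): Mode.PREDICTIVE,
        (False, True, True): Mode.PREDICTIVE,
        (False, False, False): Mode.UNPACKED_HIGH_PLDDT,
        (False, False, True): Mode.UNPACKED_HIGH_PLDDT,
        (True, True, False): Mode.NEAR_PREDICTIVE,
        (True, True, True): Mode.UNPHYSICAL,
        (True, False, False): Mode.PSEUDOSTRUCTURE,
        (True, False, True): Mode.BARBED_WIRE,
    }

    @pytest.mark.parametrize("plddt", [30.0, 69.9, 70.0, 90.0])
    @pytest.mark.parametrize("packed", [True, False])
    @pytest.mark.parametrize("outliers", [True, False])
    def test_exhaustive_decision_table(self, plddt, packed, outliers):
        low = plddt < 70.0
        assert (
            assign_mode(plddt, packed, outliers, False)
            is self.EXPECTED[(low, packed, outliers)]
        )
        # signature and density are interchangeable in the tree
        assert (
            assign_mode(plddt, packed, False, outliers)
            is self.EXPECTED[(low, packed, outliers)]
        )

    def test_boundary_is_inclusive(self):
        assert assign_mode(70.0, True, False, False) is Mode.PREDICTIVE
        assert assign_mode(69.9, True, False, False) is Mode.NEAR_PREDICTIVE


def flags(**kwargs) -> ValidationFlags:
    f = ValidationFlags(omega_state=TRANS)
    for key, value in kwargs.items():
        setattr(f, key, value)
    return f


class TestSignatureOutliers:
    def run(self, flag_list, low=None, packed=None, breaks=None):
        n = len(flag_list)
        return signature_outliers(
            flag_list,
            low if low is not None else [True] * n,
            packed if packed is not None else [False] * n,
            breaks if breaks is not None else [False] * n,
        )

    def test_upper_right_rama_is_always_signature(self):
        out = self.run(
            [flags(rama_upper_right=True, rama_outlier=True), flags()],
            low=[False, False],
            packed=[True, True],
        )
        assert out == [True, False]

    def test_twisted_bond_marks_both_residues(self):
        # the bond stored on residue 1 marks residues 0 and 1, not 2
        out = self.run([flags(), flags(omega_state=TWISTED), flags()])
        assert out == [True, True, False]

    def test_cis_nonpro_marks_both_residues_even_when_packed(self):
        out = self.run(
            [flags(), flags(omega_state=CIS_NONPRO), flags()],
            low=[False] * 3,
            packed=[True] * 3,
        )
        assert out == [True, True, False]

    def test_cnca_outlier_marks_both_residues(self):
        out = self.run([flags(), flags(cnca_outlier=True, bond_geom_outlier=True)])
        assert out == [True, True]

    def test_bond_mark_does_not_cross_chain_break(self):
        out = self.run(
            [flags(), flags(omega_state=TWISTED)], breaks=[False, True]
        )
        assert out == [False, False]

    def test_ca_outlier_contextual(self):
        # permitted in predictive (packed, high-pLDDT) regions
        assert self.run(
            [flags(ca_geom_outlier=True)], low=[False], packed=[True]
        ) == [False]
        assert self.run(
            [flags(ca_geom_outlier=True)], low=[True], packed=[True]
        ) == [False]
        assert self.run(
            [flags(ca_geom_outlier=True)], low=[True], packed=[False]
        ) == [True]

    def test_cis_pro_contextual(self):
        # legitimate at high confidence; signature only in low unpacked regions
        assert self.run(
            [flags(omega_state=CIS_PRO)], low=[False], packed=[True]
        ) == [False]
        assert self.run(
            [flags(omega_state=CIS_PRO)], low=[True], packed=[False]
        ) == [True]


class TestHighOutlierDensity:
    def run(self, flag_list, breaks=None):
        return high_outlier_density(
            flag_list, breaks if breaks is not None else [False] * len(flag_list)
        )

    def test_two_criteria_required(self):
        # 2 twisted + 2 bond outliers in the window -> criteria 1 and 3
        window = [
            flags(omega_state=TWISTED, bond_geom_outlier=True),
            flags(omega_state=TWISTED, bond_geom_outlier=True),
            flags(),
        ]
        assert self.run(window)[1] is True

    def test_one_criterion_insufficient(self):
        window = [flags(omega_state=TWISTED), flags(omega_state=TWISTED), flags()]
        assert self.run(window)[1] is False

    def test_band_plus_ca_criteria(self):
        window = [
            flags(high_psi_band=True, ca_geom_outlier=True),
            flags(high_psi_band=True, rama_outlier=True, ca_geom_outlier=True),
            flags(high_psi_band=True),
        ]
        assert self.run(window)[1] is True

    def test_band_without_rama_outlier_does_not_count(self):
        window = [
            flags(high_psi_band=True, ca_geom_outlier=True),
            flags(high_psi_band=True, ca_geom_outlier=True),
            flags(high_psi_band=True),
        ]
        # criterion 2 holds (2 CA outliers) but criterion 4 fails: one
        # criterion only
        assert self.run(window)[1] is False

    def test_window_truncated_at_terminus(self):
        # two-residue chain: the terminal window is the available residues
        pair = [
            flags(high_psi_band=True, rama_outlier=True, omega_state=TWISTED,
                  bond_geom_outlier=True),
            flags(high_psi_band=True, omega_state=TWISTED, bond_geom_outlier=True),
        ]
        assert self.run(pair) == [True, True]

    def test_window_does_not_cross_break(self):
        triple = [
            flags(omega_state=TWISTED, bond_geom_outlier=True),
            flags(),
            flags(omega_state=TWISTED, bond_geom_outlier=True),
        ]
        # residue 1's window normally sees both neighbors (2 twisted, 2 bond)
        assert self.run(triple)[1] is True
        assert self.run(triple, breaks=[False, False, True])[1] is False


class TestSmoothing:
    def smooth_seq(self, seq):
        return smooth(list(seq), [False] * len(seq))

    def test_pseudostructure_absorbed_by_barbed_wire(self):
        assert self.smooth_seq([B, B, P, B, B]) == [B, B, B, B, B]

    def test_pseudostructure_absorbed_by_near_predictive(self):
        assert self.smooth_seq([N, P, P, N]) == [N, N, N, N]

    def test_second_pass_absorbs_barbed_wire(self):
        assert self.smooth_seq([P, B, B, P]) == [P, P, P, P]

    def test_terminal_runs_not_smoothed(self):
        assert self.smooth_seq([P, B, B, B]) == [P, B, B, B]
        assert self.smooth_seq([B, B, P]) == [B, B, P]

    def test_mixed_flanks_not_smoothed(self):
        assert self.smooth_seq([B, P, N]) == [B, P, N]

    def test_three_long_runs_not_smoothed(self):
        assert self.smooth_seq([B, P, P, P, B]) == [B, P, P, P, B]

    def test_chain_break_blocks_smoothing(self):
        modes = [B, B, P, B, B]
        assert smooth(modes, [False, False, True, False, False]) == modes

    def test_other_modes_never_change(self):
        seq = [Mode.PREDICTIVE, Mode.UNPHYSICAL, Mode.UNPACKED_HIGH_PLDDT, B, P, N]
        assert self.smooth_seq(seq) == seq

    @pytest.mark.parametrize("length", range(1, 9))
    def test_exhaustive_equality_with_reference(self, length):
        """All mode strings over {barbed wire, pseudostructure,
        near-predictive} match the independent two-pass reference."""
        for seq in itertools.product((B, P, N), repeat=length):
            got = self.smooth_seq(seq)
            assert got == reference_smooth(seq), f"mismatch on {seq}"
            # idempotence
            assert self.smooth_seq(got) == got


class TestLabels:
    def test_near_predictive_typical(self):
        assert make_label(flags(), True, True) == "L-----"

    def test_pseudostructure_typical(self):
        assert make_label(flags(), True, False) == "Lp----"

    def test_full_label_composition(self):
        f = flags(
            rama_outlier=True,
            omega_state=TWISTED,
            bond_geom_outlier=True,
        )
        assert make_label(f, True, False) == "Lpro-g"
        f.ca_geom_outlier = True
        assert make_label(f, True, False) == "Lprocg"

    def test_high_confidence_packed_clean(self):
        assert make_label(flags(), False, True) == "------"

    def test_cis_pro_sets_omega_position(self):
        assert make_label(flags(omega_state=CIS_PRO), True, False)[3] == "o"
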