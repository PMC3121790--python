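"""Anti-SD hybridization energetics, classification and the energy histogram."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import brute_scan
from sdscan.hybridization import (
    EnergyModelParams,
    SDClass,
    classify_sd,
    energy_distribution,
    scan_asd,
    sd_prevalence,
    SDCall,
)
from sdscan._thermo import stack_table


def cu_window(motif: str, lead: int = 8) -> str:
    """21-nt C/U-background window with a single embedded site."""
    bg = "CUCUCUCUCUCUCUCUCUCUC"
    w = bg[:lead] + motif + bg[lead + len(motif) :]
    return w[:21]


class TestScan:
    @pytest.mark.parametrize(
        "motif, expected",
        [
            ("GGAG", -3.60),  # GG/CC + GA/CU + AG/UC + init
            ("AGGA", -3.60),
            ("GAGG", -3.60),
            ("AGGAGG", -8.94),  # five stacks -13.03 + 4.09
            ("AGGAG", -5.68),
            ("AGG", -1.25),
        ],
    )
    def test_site_energies(self, motif, expected):
        assert scan_asd(cu_window(motif)).dg == pytest.approx(expected, abs=1e-9)

    def test_tetramer_degeneracy_exact(self):
        es = [scan_asd(cu_window(m)).dg for m in ("GAGG", "AGGA", "GGAG")]
        assert max(es) - min(es) < 1e-9

    def test_cu_only_window_is_no_duplex(self):
        res = scan_asd("CUCUCUCUCUCUCUCUCUCUC")
        assert not res.duplex and math.isinf(res.dg)
        assert classify_sd(res.dg, "strict") is SDClass.SD_MINUS
        assert classify_sd(res.dg, "relaxed") is SDClass.SD_MINUS

    def test_helix_location_reported(self):
        res = scan_asd(cu_window("AGGAGG"))
        lo, hi = res.helix_span
        assert cu_window("AGGAGG")[lo : hi + 1] == "AGGAGG"
        assert sum(res.paired_mask) == 6

    def test_dna_lowercase_accepted(self):
        assert scan_asd("ctctctctGGAGctctctctc").dg == pytest.approx(-3.60, abs=1e-9)

    def test_monotone_under_watson_crick_extension(self):
        # growing the complementary site never raises the energy
        prev = 0.0
        for m in ("GGA", "GGAG", "GGAGG", "AGGAGG"):
            dg = scan_asd(cu_window(m)).dg
            assert dg < prev
            prev = dg

    def test_brute_force_equivalence_short_windows(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            w = "".join(rng.choice(list("ACGU"), rng.integers(4, 13)))
            got = scan_asd(w).dg
            want = brute_scan(w, "CCUCCU")
            assert got == want or abs(got - want) < 1e-9

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            scan_asd("A")

    def test_stack_table_symmetry(self):
        t = stack_table()
        for (top, bottom), dg in t.items():
            assert t[(bottom[1] + bottom[0], top[1] + top[0])] == dg

    def test_dangles_unsupported(self):
        with pytest.raises(ValueError):
            EnergyModelParams(use_dangles=True)


class TestClassification:
    @pytest.mark.parametrize(
        "energy, scheme, expected",
        [
            (-5.0, "strict", SDClass.SD_PLUS),
            (-2.0, "strict", SDClass.EXCLUDED),
            (0.5, "strict", SDClass.SD_MINUS),
            (-4.4, "strict", SDClass.EXCLUDED),  # boundary values excluded
            (0.0, "strict", SDClass.EXCLUDED),
            (-0.5, "relaxed", SDClass.SD_PLUS),
            (0.0, "relaxed", SDClass.SD_PLUS),
            (0.5, "relaxed", SDClass.SD_MINUS),
        ],
    )
    def test_thresholds(self, energy, scheme, expected):
        assert classify_sd(energy, scheme) is expected

    @given(st.floats(-30, 30, allow_nan=False))
    def test_strict_partition(self, e):
        calls = [classify_sd(e, "strict")]
        assert len(calls) == 1 and calls[0] in SDClass


class TestDistribution:
    def test_single_value_single_peak(self):
        d = energy_distribution([-3.6] * 50, bin_width=0.5)
        assert len(d.peaks) == 1
        assert d.peaks[0] == pytest.approx(-3.6, abs=0.5)

    def test_two_site_mixture_two_peaks(self):
        es = [scan_asd(cu_window("GGAG")).dg] * 40 + [
            scan_asd(cu_window("AGGAGG")).dg
        ] * 40
        d = energy_distribution(es, bin_width=0.2)
        assert len(d.peaks) == 2
        assert d.peaks[0] == pytest.approx(-8.94, abs=0.2)
        assert d.peaks[1] == pytest.approx(-3.60, abs=0.2)

    def test_four_class_panel(self):
        """AGGAG / tetramer / trimer / no-SD panel: the three sited classes
        appear as ordered density peaks and the no-SD class fills the
        dedicated no-duplex category."""
        rng = np.random.default_rng(0)
        energies = []
        for _ in range(30):
            energies.append(scan_asd(cu_window("AGGAG")).dg)
            energies.append(scan_asd(cu_window(rng.choice(["GAGG", "AGGA", "GGAG"]))).dg)
            energies.append(scan_asd(cu_window(rng.choice(["AGG", "GGA"]))).dg)
            energies.append(scan_asd("CUCUCUCUCUCUCUCUCUCUC").dg)
        d = energy_distribution(energies, bin_width=1.0)
        assert d.no_duplex_fraction == pytest.approx(0.25)
        assert len(d.peaks) == 3
        assert d.peaks[0] < d.peaks[1] < d.peaks[2]
        assert d.density.sum() + d.no_duplex_fraction == pytest.approx(1.0)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            energy_distribution([-1.0], bin_width=0)


class TestPrevalence:
    def test_fraction(self):
        calls = [SDCall(f"g{i}", -1.0, SDClass.SD_PLUS, "relaxed") for i in range(796)]
        calls += [SDCall(f"h{i}", 1.0, SDClass.SD_MINUS, "relaxed") for i in range(204)]
        assert sd_prevalence(calls) == pytest.approx(0.796)

    def test_all_minus(self):
        calls = [SDCall("g", 1.0, SDClass.SD_MINUS, "relaxed")]
        assert sd_prevalence(calls) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sd_prevalence([])
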