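import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import peptide_mass
from rippmine import ms

AA = "ACDEFGHIKLMNPQRSTVWY"

peptide_strategy = st.text(alphabet=AA, min_size=1, max_size=30)


class TestMonoisotopicMass:
    def test_gg_free_acid(self):
        p = ms.Peptide("GG")
        # elemental oracle: 2 x (C2H3NO) + H2O
        assert ms.monoisotopic_mass(p) == pytest.approx(132.0535, abs=1e-4)
        assert ms.monoisotopic_mass(p) == pytest.approx(peptide_mass("GG"), abs=1e-6)

    def test_ring_delta_is_two_hydrogens(self):
        p = ms.Peptide("TVGGTVGG")
        unmod = ms.monoisotopic_mass(p)
        mod = ms.monoisotopic_mass(p, [ms.ModificationEvent(1)])
        assert unmod - mod == pytest.approx(2 * 1.0078250, abs=1e-6)

    def test_label_delta_13c5_15n(self):
        p = ms.Peptide("TVGG")
        labeled = ms.Peptide("TVGG", labels=((1, "13C5_15N"),))
        delta = ms.monoisotopic_mass(labeled) - ms.monoisotopic_mass(p)
        assert delta == pytest.approx(6.013810, abs=1e-5)

    def test_mod_on_non_val_rejected(self):
        p = ms.Peptide("TVGG")
        with pytest.raises(ValueError, match="not Val"):
            ms.monoisotopic_mass(p, [ms.ModificationEvent(0)])

    def test_amide_adjustment(self):
        free = ms.monoisotopic_mass(ms.Peptide("MKWV"))
        amide = ms.monoisotopic_mass(ms.Peptide("MKWV", c_terminus="amide"))
        assert free - amide == pytest.approx(0.98402, abs=1e-4)

    @given(peptide_strategy, st.booleans())
    @settings(max_examples=100, deadline=None)
    def test_elemental_oracle(self, residues, amide):
        p = ms.Peptide(residues, c_terminus="amide" if amide else "free_acid")
        assert ms.monoisotopic_mass(p) == pytest.approx(
            peptide_mass(residues, amide=amide), abs=1e-4
        )

    @given(peptide_strategy, peptide_strategy)
    @settings(max_examples=50, deadline=None)
    def test_additivity(self, a, b):
        total = ms.monoisotopic_mass(ms.Peptide(a + b))
        parts = ms.monoisotopic_mass(ms.Peptide(a)) + ms.monoisotopic_mass(ms.Peptide(b))
        assert total == pytest.approx(parts - ms.WATER, abs=1e-4)


class TestMz:
    def test_zero_mass_single_charge_is_proton(self):
        assert ms.mz(0.0, 1) == pytest.approx(1.0072765)

    def test_strictly_decreasing_in_z(self):
        vals = [ms.mz(2434.2383, z) for z in range(1, 6)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_formula(self):
        assert ms.mz(2434.2383, 2) == pytest.approx((2434.2383 + 2 * 1.0072765) / 2)


class TestModificationSeries:
    def test_paper_predicted_products(self):
        series = ms.modification_series(1218.1337, z=2, n_max=3)
        assert series[0] == 1218.1337
        assert series[1] == pytest.approx(1217.1259, abs=2e-4)
        assert series[2] == pytest.approx(1216.1180, abs=2e-4)
        assert series[3] == pytest.approx(1215.1102, abs=2e-4)

    def test_step_is_exactly_two_h_over_z(self):
        for z in (1, 2, 3):
            series = ms.modification_series(1000.0, z=z, n_max=4)
            steps = {round(a - b, 9) for a, b in zip(series, series[1:])}
            assert steps == {round(2 * 1.0078250319 / z, 9)}

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            ms.modification_series(1000.0, z=0, n_max=1)
        with pytest.raises(ValueError):
            ms.modification_series(1000.0, z=1, n_max=-1)


class TestPpmError:
    @pytest.mark.parametrize(
        "observed,predicted,expected",
        [
            (1218.1376, 1218.1337, 3.2),
            (1217.1238, 1217.1259, 1.7),
            (1216.1166, 1216.1180, 1.1),
            (1215.1069, 1215.1102, 2.7),
        ],
    )
    def test_printed_values_under_truncation(self, observed, predicted, expected):
        truncated, _full = ms.ppm_error(observed, predicted)
        assert truncated == pytest.approx(expected, abs=1e-9)

    def test_identity_is_zero(self):
        assert ms.ppm_error(1218.0, 1218.0)[0] == 0.0

    @given(
        st.floats(100.0, 3000.0),
        st.floats(1e-4, 0.01),
        st.floats(0.5, 10.0),
        st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_scaling_invariance(self, predicted, delta, scale, negate):
        observed = predicted + (-delta if negate else delta)
        _, full1 = ms.ppm_error(observed, predicted)
        _, full2 = ms.ppm_error(observed * scale, predicted * scale)
        assert full1 == pytest.approx(full2, rel=1e-6)


class TestFragmentLadder:
    def test_b1_of_gv(self):
        ladder = dict(
            ((s.series, s.index), m) for s, m in ms.fragment_ladder(ms.Peptide("GVGG"), series="b")
        )
        assert ladder[("b", 1)] == pytest.approx(58.0287, abs=1e-4)

    def test_full_y_equals_protonated_mass(self):
        for cterm in ("free_acid", "amide"):
            p = ms.Peptide("MWTVGGTVGG", c_terminus=cterm)
            ladder = dict((s.index, m) for s, m in ms.fragment_ladder(p, series="y"))
            assert ladder[len(p)] == pytest.approx(
                ms.mz(ms.monoisotopic_mass(p), 1), abs=1e-6
            )

    def test_series_telescoping(self):
        p = ms.Peptide("MWTVGGTVGGKL", c_terminus="amide")
        b = dict((s.index, m) for s, m in ms.fragment_ladder(p, series="b"))
        y = dict((s.index, m) for s, m in ms.fragment_ladder(p, series="y"))
        total = ms.mz(ms.monoisotopic_mass(p), 1) + ms.MASS_PROTON
        for i in range(1, len(p)):
            assert b[i] + y[len(p) - i] == pytest.approx(total, abs=1e-4)

    def test_modified_y_fragments_shift_only_when_containing_site(self):
        p = ms.Peptide("MW" + "TVGG" * 4, c_terminus="amide")
        site = 7  # Val of the second repeat
        unmod = ms.fragment_ladder(p, series="y")
        mod = ms.fragment_ladder(p, mods=[ms.ModificationEvent(site)], series="y")
        n = len(p)
        for (su, mu), (sm, mm) in zip(unmod, mod):
            j = su.index
            contains = n - j <= site
            if contains:
                assert mu - mm == pytest.approx(2 * 1.0078250, abs=1e-6)
                assert sm.n_mods_contained == 1
            else:
                assert mu == mm
                assert sm.n_mods_contained == 0

    def test_labels_do_not_change_ladder_structure(self):
        p = ms.Peptide("TVGGTVGG")
        lab = ms.Peptide("TVGGTVGG", labels=((1, "13C5_15N"), (5, "13C5_15N")))
        plain = ms.fragment_ladder(p, series="b")
        labeled = ms.fragment_ladder(lab, series="b")
        assert [s.index for s, _ in plain] == [s.index for s, _ in labeled]
        assert all(ml >= mp for (_, mp), (_, ml) in zip(plain, labeled))

    def test_internal_fragments_exclude_termini(self):
        p = ms.Peptide("MWTVGG")
        specs = [s for s, _ in ms.fragment_ladder(p, series="internal_by")]
        assert all(s.start >= 1 and s.end <= len(p) - 1 for s in specs)

    def test_internal_fragments_carry_mod_only_with_val(self):
        p = ms.Peptide("MWTVGG")
        mod = dict(
            ((s.start, s.end), m)
            for s, m in ms.fragment_ladder(p, mods=[ms.ModificationEvent(3)], series="internal_by")
        )
        plain = dict(
            ((s.start, s.end), m) for s, m in ms.fragment_ladder(p, series="internal_by")
        )
        for key in plain:
            contains_val = key[0] <= 3 < key[1]
            if contains_val:
                assert plain[key] - mod[key] == pytest.approx(2 * 1.0078250, abs=1e-6)
            else:
                assert plain[key] == mod[key]


class TestLocalization:
    PEP = ms.Peptide("MW" + "TVGG" * 4, c_terminus="amide")

    def test_noiseless_unique_assignment(self):
        from rippmine.synthetic import make_ladder

        site = self.PEP.val_sites()[1]
        observed = make_ladder(self.PEP, [site], series="y", noise_ppm=0.0)
        res = ms.localize_modifications(self.PEP, observed)
        assert res.unique == frozenset({site})
        assert not res.mixture

    def test_mixture_flag_for_contradictory_ions(self):
        site = self.PEP.val_sites()[0]
        y_mod = dict(
            (s.index, (s, m))
            for s, m in ms.fragment_ladder(
                self.PEP, mods=[ms.ModificationEvent(site)], series="y"
            )
        )
        y_unmod = dict(
            (s.index, (s, m)) for s, m in ms.fragment_ladder(self.PEP, series="y")
        )
        n = len(self.PEP)
        j = n - site + 2  # a y-ion spanning the first Val
        observed = [y_mod[j], y_unmod[j - 1]]
        # y_j shifted but the shorter fragment unshifted is fine; the true
        # contradiction: same-span ions both shifted and unshifted
        observed = [y_mod[j], (y_unmod[j][0], y_unmod[j][1])]
        res = ms.localize_modifications(self.PEP, observed)
        assert res.mixture
        assert res.assignments == []

    def test_no_assignment_reports_conflict(self):
        spec = ms.IonSpec("y", index=4, z=1)
        res = ms.localize_modifications(self.PEP, [(spec, 5000.0)])
        assert res.assignments == []
        assert not res.mixture
        assert res.conflict == spec

    def test_noisy_recovery_smoke(self):
        from rippmine.synthetic import make_ladder

        recovered = 0
        for seed in range(10):
            rng = random.Random(seed)
            site = rng.choice(self.PEP.val_sites())
            observed = make_ladder(self.PEP, [site], series="y", noise_ppm=5.0, seed=seed)
            res = ms.localize_modifications(self.PEP, observed, tol_ppm=25.0)
            if res.unique == frozenset({site}):
                recovered += 1
        assert recovered >= 9
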