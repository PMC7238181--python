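"""Hansen-parameter arithmetic, group-contribution estimation and screening."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filadose.hsp import (
    GroupContributionTable,
    HansenParameters,
    Material,
    ScreenThresholds,
    estimate_hsp_from_groups,
    load_group_table,
    ra_distance,
    screen_combinations,
    total_hsp,
)

# snap near-zero components to zero so squared differences cannot underflow
_component = st.floats(0, 50, allow_nan=False).map(lambda v: 0.0 if v < 1e-6 else v)
triples = st.tuples(_component, _component, _component)


class TestTotalHsp:
    @pytest.mark.parametrize(
        "triple, expected, tol",
        [
            ((16.6, 2.4, 7.4), 18.3, 0.05),  # nifedipine, tabulated components
            ((0.0, 0.0, 0.0), 0.0, 1e-12),
            ((3.0, 4.0, 0.0), 5.0, 1e-12),
        ],
    )
    def test_known_values(self, triple, expected, tol):
        assert total_hsp(*triple) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("bad", [(-1, 2, 3), (1, float("nan"), 3), (1, 2, float("inf"))])
    def test_rejects_invalid_components(self, bad):
        with pytest.raises(ValueError):
            total_hsp(*bad)

    @given(triples, st.floats(0.01, 10))
    @settings(max_examples=50, derandomize=True)
    def test_scales_linearly(self, triple, c):
        scaled = total_hsp(*(c * x for x in triple))
        assert scaled == pytest.approx(c * total_hsp(*triple), rel=1e-9, abs=1e-9)

    def test_delta_t_consistent_with_components(self):
        hsp = HansenParameters(15.8, 8.8, 19.4)
        assert hsp.delta_t**2 == pytest.approx(
            hsp.delta_d**2 + hsp.delta_p**2 + hsp.delta_h**2, rel=1e-9
        )


class TestRaDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((16.6, 2.4, 7.4), (15.8, 8.8, 19.4), 13.7),  # drug vs ethanol
            ((16.6, 2.4, 7.4), (15.8, 5.3, 7.2), 3.3),  # drug vs ethyl acetate
        ],
    )
    def test_tabulated_pairs(self, a, b, expected):
        assert ra_distance(HansenParameters(*a), HansenParameters(*b)) == pytest.approx(
            expected, abs=0.05
        )

    def test_dispersion_term_weighted_four_fold(self):
        a, b = HansenParameters(10, 5, 5), HansenParameters(11, 5, 5)
        assert ra_distance(a, b) == pytest.approx(2.0, abs=1e-12)

    @given(triples, triples, triples)
    @settings(max_examples=100, derandomize=True)
    def test_is_a_metric(self, ta, tb, tc):
        a, b, c = (HansenParameters(*t) for t in (ta, tb, tc))
        assert ra_distance(a, b) == pytest.approx(ra_distance(b, a), rel=1e-12)
        assert ra_distance(a, a) == 0.0
        assert ra_distance(a, c) <= ra_distance(a, b) + ra_distance(b, c) + 1e-9
        if ta != tb:
            assert ra_distance(a, b) > 0


class TestReferenceTableConsistency:
    """The printed component triples reproduce the printed drug-distance column."""

    RA_TO_DRUG = {
        "ethanol": 13.7,
        "ethyl_acetate": 3.3,
        "PVA": 18.4,
        "HS": 18.3,
        "PLA": 8.6,
        "TPU": 8.1,
    }
    TOTALS = {"NFD": 18.3, "ethanol": 26.5, "PVA": 28.9, "HS": 29.0, "PLA": 21.9, "TPU": 20.8}

    def test_ra_to_drug_column(self, materials):
        drug = materials["NFD"]
        for name, expected in self.RA_TO_DRUG.items():
            assert ra_distance(drug.hsp, materials[name].hsp) == pytest.approx(
                expected, abs=0.05
            ), name

    def test_totals(self, materials):
        for name, expected in self.TOTALS.items():
            assert materials[name].hsp.delta_t == pytest.approx(expected, abs=0.05), name


class TestGroupContribution:
    def test_ethanol_against_hand_summation(self):
        # independent hand summation over the bundled rows CH3/CH2/OH:
        # F_d = 420+270+210 = 900; F_p^2 sum = 500^2; E_h = 20000;
        # V = 33.5+16.1+10.0 = 59.6
        est = estimate_hsp_from_groups([("CH3", 1), ("CH2", 1), ("OH", 1)])
        assert est.delta_d == pytest.approx(900 / 59.6, rel=1e-12)
        assert est.delta_p == pytest.approx(500 / 59.6, rel=1e-12)
        assert est.delta_h == pytest.approx(math.sqrt(20000 / 59.6), rel=1e-12)
        assert est.source == "group_contribution"
        # frozen values for the record
        assert (est.delta_d, est.delta_p, est.delta_h) == pytest.approx(
            (15.1007, 8.3893, 18.3186), abs=5e-4
        )

    def test_apolar_group_gives_zero_polar_and_hbond(self):
        est = estimate_hsp_from_groups([("CH2", 3)])
        assert est.delta_p == 0.0 and est.delta_h == 0.0

    def test_empty_group_list_rejected(self):
        with pytest.raises(ValueError):
            estimate_hsp_from_groups([])

    def test_unknown_group_named_in_error(self):
        with pytest.raises(KeyError, match="SiO2"):
            estimate_hsp_from_groups([("CH3", 1), ("SiO2", 2)])

    def test_molar_volume_override(self):
        base = estimate_hsp_from_groups([("CH3", 1), ("OH", 1)])
        overridden = estimate_hsp_from_groups(
            [("CH3", 1), ("OH", 1)], molar_volume_override=100.0
        )
        assert overridden.delta_d == pytest.approx(630 / 100.0, rel=1e-12)
        assert overridden.delta_d != base.delta_d

    def test_table_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            GroupContributionTable({"X": (100.0, 0.0, 0.0, -1.0)})

    def test_bundled_table_loads(self):
        table = load_group_table()
        assert "OH" in table and "CH3" in table


class TestScreening:
    def test_reference_ranking_puts_ethanol_pva_and_hs_first(self, screen_results):
        top_two = {(r.solvent, r.filament) for r in screen_results[:2]}
        assert top_two == {("ethanol", "PVA"), ("ethanol", "HS")}
        ethanol_ranks = [
            i for i, r in enumerate(screen_results) if r.solvent == "ethanol"
        ]
        acetate_ranks = [
            i for i, r in enumerate(screen_results) if r.solvent == "ethyl_acetate"
        ]
        # every ethyl-acetate pair fails the drug-solvent criterion (Ra 3.3 < 10)
        assert all(r.verdict != "favoured" for r in screen_results if r.solvent == "ethyl_acetate")
        assert min(ethanol_ranks) < min(acetate_ranks)

    def test_matches_exhaustive_pairwise_oracle(self, materials, screen_results):
        for r in screen_results:
            assert r.ra_drug_solvent == pytest.approx(
                ra_distance(materials["NFD"].hsp, materials[r.solvent].hsp), rel=1e-12
            )
            assert r.ra_solvent_filament == pytest.approx(
                ra_distance(materials[r.solvent].hsp, materials[r.filament].hsp),
                rel=1e-12,
            )
            assert r.ra_drug_filament == pytest.approx(
                ra_distance(materials["NFD"].hsp, materials[r.filament].hsp), rel=1e-12
            )

    def test_solvent_identical_to_drug_is_rejected(self, materials):
        twin = Material(name="twin", role="solvent", hsp=materials["NFD"].hsp)
        results = screen_combinations(materials["NFD"], [twin], [materials["PVA"]])
        assert results[0].ra_drug_solvent == 0.0
        assert results[0].verdict == "rejected"

    def test_deterministic_total_order(self, materials):
        solvents = [materials["ethanol"], materials["ethyl_acetate"]]
        filaments = [materials[f] for f in ("PVA", "HS", "PLA", "TPU")]
        first = screen_combinations(materials["NFD"], solvents, filaments)
        second = screen_combinations(
            materials["NFD"], solvents[::-1], filaments[::-1]
        )
        assert first == second

    def test_empty_inputs_rejected(self, materials):
        with pytest.raises(ValueError):
            screen_combinations(materials["NFD"], [], [materials["PVA"]])

    def test_custom_thresholds_change_verdict(self, materials):
        strict = ScreenThresholds(t_high=20.0)
        results = screen_combinations(
            materials["NFD"], [materials["ethanol"]], [materials["PVA"]], strict
        )
        assert results[0].verdict != "favoured"
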