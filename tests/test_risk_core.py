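"""Unit and property tests for the deterministic dose/risk arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oralrisk import risk_core as rc
from oralrisk.risk_core import (
    ConcentrationRecord,
    ExposureFactors,
    Metal,
    Pathway,
    RfDTable,
    RiskRecord,
)


def factors(bw=25.0, food=548.0, water=1104.0, soil=41.0, **kw):
    return ExposureFactors(
        body_weight=bw,
        intake={Pathway.food: food, Pathway.water: water, Pathway.soil: soil},
        **kw,
    )


positive = st.floats(min_value=1e-3, max_value=1e4, allow_nan=False)


class TestAverageDailyDose:
    @pytest.mark.parametrize(
        "metal, pathway, conc, expected",
        [
            # soil Pb: 72.58 mg/kg * 41 mg/day * 1e-6 / 25 kg
            (Metal.Pb, Pathway.soil, 72.58, 1.190312e-4),
            # water As: 1.41 ng/mL (== ug/L) * 1104 mL/day -> mg/day / 25 kg
            (Metal.As, Pathway.water, 1.41, 6.22656e-5),
            # food Mn: 0.47 mg/kg * 548 g/day / 25 kg
            (Metal.Mn, Pathway.food, 0.47, 0.47 * 0.548 / 25),
        ],
    )
    def test_hand_computed_doses(self, metal, pathway, conc, expected):
        add = rc.average_daily_dose(ConcentrationRecord(metal, pathway, conc), factors())
        assert add == pytest.approx(expected, rel=1e-6)

    def test_zero_concentration_gives_zero_dose(self):
        for pathway in Pathway:
            add = rc.average_daily_dose(
                ConcentrationRecord(Metal.Cd, pathway, 0.0), factors()
            )
            assert add == 0.0

    def test_nonpositive_body_weight_rejected(self):
        with pytest.raises(ValueError, match="body weight"):
            factors(bw=0.0)
        with pytest.raises(ValueError, match="body weight"):
            factors(bw=-3.0)

    def test_missing_intake_rate_rejected(self):
        f = ExposureFactors(body_weight=25.0, intake={Pathway.food: 548.0})
        with pytest.raises(ValueError, match="intake"):
            rc.average_daily_dose(
                ConcentrationRecord(Metal.Pb, Pathway.soil, 72.58), f
            )

    @pytest.mark.parametrize("ed", [1.0, 6.0, 10.0])
    def test_dose_independent_of_exposure_duration(self, ed):
        """With EF=365 and AT=ED*365 the time factor cancels exactly."""
        conc = ConcentrationRecord(Metal.Pb, Pathway.soil, 72.58)
        base = rc.average_daily_dose(conc, factors())
        assert rc.average_daily_dose(conc, factors(exposure_duration=ed)) == base

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(c=positive, ingr=positive, bw=positive, a=st.floats(min_value=0.1, max_value=10))
    def test_linearity_in_concentration_intake_and_inverse_body_weight(
        self, c, ingr, bw, a
    ):
        def add(c_, ingr_, bw_):
            return rc.average_daily_dose(
                ConcentrationRecord(Metal.Cr, Pathway.soil, c_),
                factors(bw=bw_, soil=ingr_),
            )

        base = add(c, ingr, bw)
        assert add(a * c, ingr, bw) == pytest.approx(a * base, rel=1e-12)
        assert add(c, a * ingr, bw) == pytest.approx(a * base, rel=1e-12)
        assert add(c, ingr, a * bw) == pytest.approx(base / a, rel=1e-12)


class TestHazardQuotientAndIndices:
    def test_hq_is_dose_over_reference_dose(self, rfd_table):
        # soil Cr hand calculation; same order of magnitude as the published
        # cohort soil-Cr median HQ (7.8e-5)
        add = rc.average_daily_dose(
            ConcentrationRecord(Metal.Cr, Pathway.soil, 73.65), factors()
        )
        hq = rc.hazard_quotient(add, Metal.Cr, Pathway.soil, rfd_table)
        assert hq == pytest.approx(8.0524e-5, rel=1e-4)
        assert np.log10(hq) == pytest.approx(np.log10(7.8e-5), abs=0.3)

    def test_hq_identity_when_dose_equals_rfd(self, rfd_table):
        assert rc.hazard_quotient(0.0014, Metal.Pb, Pathway.soil, rfd_table) == 1.0

    def test_soil_pb_hq(self, rfd_table):
        hq = rc.hazard_quotient(1.190312e-4, Metal.Pb, Pathway.soil, rfd_table)
        assert hq == pytest.approx(8.502e-2, rel=1e-3)

    def test_missing_rfd_entry_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            RfDTable({(Metal.Pb, Pathway.soil): 0.0014})

    @pytest.mark.parametrize(
        "components, exact, printed",
        [
            ([1.2, 8.2e-3, 9.9e-2], 1.3072, 1.3),  # Pb median pathway HQs
            ([5.8e-2, 2.9e-1, 3.0e-2], 0.378, 0.38),  # As median pathway HQs
            ([0.0, 0.0, 0.0], 0.0, 0.0),
        ],
    )
    def test_hazard_index_sums_pathways(self, components, exact, printed):
        hi = rc.hazard_index(components)
        assert hi == pytest.approx(exact, abs=1e-4)
        assert rc.round_sig(hi, 2) == pytest.approx(printed)

    @pytest.mark.parametrize(
        "components, printed",
        [
            ([1.5, 3.1e-1, 1.3e-1], 1.9),  # per-pathway total HIs at the median
            ([3.9, 4.2e-1, 4.3e-1], 4.8),  # and at the 95th percentile
        ],
    )
    def test_total_hazard_index_sums_metals(self, components, printed):
        assert rc.round_sig(rc.total_hazard_index(components), 2) == pytest.approx(printed)

    def test_single_element_total_is_identity(self):
        assert rc.total_hazard_index([0.42]) == 0.42

    def test_empty_sums_rejected(self):
        with pytest.raises(ValueError):
            rc.hazard_index([])
        with pytest.raises(ValueError):
            rc.total_hazard_index([])

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=8))
    def test_indices_permutation_invariant_and_additive(self, hqs):
        hi = rc.hazard_index(hqs)
        assert rc.hazard_index(hqs[::-1]) == pytest.approx(hi, rel=1e-12)
        assert rc.total_hazard_index([hi, 0.0]) == pytest.approx(hi, rel=1e-12)


class TestContributionFractions:
    def test_single_nonzero_pathway_takes_all(self):
        assert rc.contribution_fractions({"food": 3.0, "soil": 0.0}) == {
            "food": 1.0,
            "soil": 0.0,
        }

    def test_forced_arithmetic(self):
        fr = rc.contribution_fractions({"food": 9.0, "water": 0.5, "soil": 0.5})
        assert fr == {"food": 0.9, "water": 0.05, "soil": 0.05}

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rc.contribution_fractions({"food": 0.0, "soil": 0.0})

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=6).filter(
            lambda v: sum(v) > 0
        )
    )
    def test_fractions_normalised(self, values):
        fr = rc.contribution_fractions(dict(enumerate(values)))
        assert abs(sum(fr.values()) - 1.0) < 1e-12
        assert all(0 <= f <= 1 for f in fr.values())


class TestRoundSig:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (1.307, 1.3),
            (0.378, 0.38),
            (4.75, 4.8),  # half rounds away from zero
            (-4.75, -4.8),
            (8.5022e-2, 8.5e-2),
            (0.0, 0.0),
            (1.94, 1.9),
        ],
    )
    def test_two_significant_figures(self, x, expected):
        assert rc.round_sig(x, 2) == pytest.approx(expected)


def _records(child_hqs):
    """child_hqs: {child: {(metal, pathway): hq}} with unit RfD (add == hq)."""
    out = []
    for child, cells in child_hqs.items():
        for (m, p), hq in cells.items():
            out.append(RiskRecord(child, m, p, add=hq, hq=hq))
    return out


class TestRiskTable:
    def test_single_child_degenerates_to_deterministic_pipeline(self):
        recs = _records({"c1": {(Metal.Pb, Pathway.soil): 0.085, (Metal.Pb, Pathway.food): 1.2}})
        summary = rc.risk_table(recs)
        for pct in (5, 50, 95):
            assert summary.value(Metal.Pb, Pathway.soil, pct) == pytest.approx(0.085)
            assert summary.value(Metal.Pb, "Sum", pct) == pytest.approx(1.285)

    def test_median_of_three_children(self):
        recs = _records(
            {f"c{i}": {(Metal.Pb, Pathway.soil): hq} for i, hq in enumerate([0.1, 0.2, 0.3])}
        )
        assert rc.risk_table(recs).value(Metal.Pb, Pathway.soil, 50) == pytest.approx(0.2)

    def test_percentile_of_sums_not_sum_of_percentiles(self):
        # two children with per-metal HQs (1,2) and (3,4): the per-child
        # totals are 3 and 7, so the Total median must be median{3,7} = 5
        recs = _records(
            {
                "c1": {(Metal.Pb, Pathway.soil): 1.0, (Metal.Cd, Pathway.soil): 2.0},
                "c2": {(Metal.Pb, Pathway.soil): 3.0, (Metal.Cd, Pathway.soil): 4.0},
            }
        )
        summary = rc.risk_table(recs)
        assert summary.value("Total", Pathway.soil, 50) == pytest.approx(5.0)
        assert summary.value("Total", "Sum", 50) == pytest.approx(5.0)

    def test_matches_brute_force_enumeration_on_small_cohorts(self):
        """Every cell equals a percentile of explicitly enumerated per-child sums."""
        rng = np.random.default_rng(7)
        for n_children in (1, 2, 3, 4):
            hqs = {
                f"c{i}": {
                    (m, p): float(rng.uniform(0, 2))
                    for m in Metal
                    for p in Pathway
                }
                for i in range(n_children)
            }
            summary = rc.risk_table(_records(hqs))
            for pct in (5, 50, 95):
                for m in Metal:
                    per_child = [sum(hqs[c][(m, p)] for p in Pathway) for c in hqs]
                    assert summary.value(m, "Sum", pct) == pytest.approx(
                        np.percentile(per_child, pct), rel=1e-12
                    )
                totals = [
                    sum(hqs[c][(m, p)] for m in Metal for p in Pathway) for c in hqs
                ]
                assert summary.value("Total", "Sum", pct) == pytest.approx(
                    np.percentile(totals, pct), rel=1e-12
                )

    def test_percentiles_monotone(self):
        rng = np.random.default_rng(11)
        recs = _records(
            {
                f"c{i}": {(m, p): float(rng.lognormal()) for m in Metal for p in Pathway}
                for i in range(20)
            }
        )
        table = rc.risk_table(recs).table
        for metal in table.index:
            for pathway in ("food", "water", "soil", "Sum"):
                p5, p50, p95 = (table.loc[metal, (q, pathway)] for q in (5, 50, 95))
                assert p5 <= p50 <= p95

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            rc.risk_table([])
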