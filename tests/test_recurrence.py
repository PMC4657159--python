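"""Risk-genotype frequencies, attributable excess and first-degree incidence,
with the kinship pipeline as the independent oracle for the closed forms."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyherit.kinship import (
    hwe_distribution,
    offspring_distribution,
    sibling_distribution,
)
from polyherit.recurrence import (
    attributable_excess,
    combined_incidence,
    first_degree_incidence,
    population_risk_genotype_freq,
    relative_risk_genotype_freq,
)

WORKED = dict(P=0.01, u=0.0039, p=3.9e-05)


@pytest.mark.parametrize("p, model, expected, tol", [
    (3.9e-05, "AD", 7.79985e-05, 5e-11),   # carriers: 1 - (1-p)^2, 6 s.f.
    (0.5, "AR", 0.25, 1e-15),              # homozygotes: p^2
    (0.0, "AD", 0.0, 0.0),
    (0.0, "AR", 0.0, 0.0),
])
def test_population_risk_genotype_freq(p, model, expected, tol):
    assert population_risk_genotype_freq(p, model) == pytest.approx(
        expected, abs=tol)


def test_unknown_model_rejected():
    with pytest.raises(ValueError):
        population_risk_genotype_freq(0.1, "XL")


def test_offspring_carrier_freq_worked_example():
    y = relative_risk_genotype_freq(0.0039, 3.9e-05, "AD", "offspring")
    assert y == pytest.approx(0.00393885, abs=5e-9)  # reference is 6 s.f.


def test_null_association_reduces_to_population_freq():
    for model in ("AD", "AR"):
        for relative in ("offspring", "sibling"):
            y = relative_risk_genotype_freq(0.1, 0.1, model, relative)
            assert y == pytest.approx(
                population_risk_genotype_freq(0.1, model), abs=1e-15)


@given(u=st.floats(0.0, 1.0), p=st.floats(0.0, 1.0))
def test_closed_forms_match_kinship_pipeline(u, p):
    """Y1 closed forms equal: proband at HWE(u) pushed through the
    sibling/offspring distributions, collapsed to carrier or homozygote
    mass."""
    proband = hwe_distribution(u)
    for relative, kin in (("sibling", sibling_distribution),
                          ("offspring", offspring_distribution)):
        dist = kin(proband, p)
        assert relative_risk_genotype_freq(u, p, "AD", relative) == \
            pytest.approx(dist.carrier_mass(), abs=1e-12)
        assert relative_risk_genotype_freq(u, p, "AR", relative) == \
            pytest.approx(dist.homozygote_mass(), abs=1e-12)


@given(u=st.floats(0.001, 0.999), p=st.floats(0.001, 0.999))
def test_amgm_orderings(u, p):
    """Dominant model: offspring carrier frequency >= sibling's (equality iff
    v = q); recessive model: the ordering reverses (equality iff u = p)."""
    ad_off = relative_risk_genotype_freq(u, p, "AD", "offspring")
    ad_sib = relative_risk_genotype_freq(u, p, "AD", "sibling")
    assert ad_off >= ad_sib - 1e-12
    ar_off = relative_risk_genotype_freq(u, p, "AR", "offspring")
    ar_sib = relative_risk_genotype_freq(u, p, "AR", "sibling")
    assert ar_sib >= ar_off - 1e-12
    if abs(u - p) > 1e-6:
        assert ad_off > ad_sib
        assert ar_sib > ar_off


def test_amgm_equality_at_u_equals_p():
    assert relative_risk_genotype_freq(0.3, 0.3, "AD", "offspring") == \
        pytest.approx(relative_risk_genotype_freq(0.3, 0.3, "AD", "sibling"),
                      abs=1e-15)


class TestAttributableExcess:
    def test_worked_example(self):
        excess = attributable_excess(model="AD", relative="offspring", **WORKED)
        assert excess == pytest.approx(0.0019112, abs=1e-7)

    @pytest.mark.parametrize("model", ["AD", "AR"])
    def test_null_association_adds_nothing(self, model):
        assert attributable_excess(0.01, 0.1, 0.1, model, "offspring") == 0.0

    def test_undefined_for_absent_allele(self):
        with pytest.raises(ValueError):
            attributable_excess(0.01, 0.1, 0.0, "AD", "offspring")

    def test_strictly_increasing_in_case_frequency(self):
        values = [attributable_excess(0.01, u, 1e-4, "AD", "offspring")
                  for u in (2e-4, 1e-3, 5e-3, 2e-2)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_genotype_convention_closed_form_ad(self):
        # (f1 - f0)(Y1 - X1) collapses to P (1 - v^2/q^2)(Y1/X1 - 1)
        P, u, p = 0.1, 0.15, 0.05
        q, v = 1.0 - p, 1.0 - u
        X1 = population_risk_genotype_freq(p, "AD")
        Y1 = relative_risk_genotype_freq(u, p, "AD", "offspring")
        expected = P * (1.0 - v * v / (q * q)) * (Y1 / X1 - 1.0)
        assert attributable_excess(P, u, p, "AD", "offspring",
                                   "genotype") == pytest.approx(expected,
                                                                abs=1e-15)

    def test_genotype_convention_exceeds_allele_convention(self):
        ge = attributable_excess(0.1, 0.15, 0.05, "AD", "offspring", "genotype")
        al = attributable_excess(0.1, 0.15, 0.05, "AD", "offspring", "allele")
        assert ge > al > 0.0


class TestFirstDegreeIncidence:
    def test_worked_example_packaging(self):
        result = first_degree_incidence(model="AD", relative="offspring",
                                        **WORKED)
        assert result.Q == pytest.approx(0.0119112, abs=1e-6)
        assert result.Q == result.excess + WORKED["P"]
        assert result.X1 <= result.Y1

    def test_or_one_gives_prevalence(self):
        result = first_degree_incidence(0.05, 0.2, 0.2, "AD", "offspring")
        assert result.Q == 0.05

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="saturat"):
            first_degree_incidence(0.5, 0.999, 0.001, "AD", "offspring")


class TestCombinedIncidence:
    def test_single_component_equals_first_degree(self):
        single = first_degree_incidence(model="AD", relative="offspring",
                                        **WORKED)
        combined = combined_incidence(
            WORKED["P"], [(WORKED["u"], WORKED["p"], "AD")], "offspring")
        assert combined == pytest.approx(single.Q, abs=1e-15)

    def test_null_components_leave_prevalence(self):
        q = combined_incidence(0.01, [(0.2, 0.2, "AD"), (0.1, 0.1, "AR")])
        assert q == 0.01

    def test_four_cnv_excesses_add(self):
        P = 0.01
        freqs = [3.9e-05, 3.5e-05, 1.6e-05, 1.2e-05]
        components = [(p / P, p, "AD") for p in freqs]
        combined = combined_incidence(P, components, "offspring")
        total = P + sum(
            attributable_excess(P, p / P, p, "AD", "offspring") for p in freqs)
        assert combined == pytest.approx(total, abs=1e-15)
        assert combined > P
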