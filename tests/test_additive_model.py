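"""Dose-equivalence additive surface: k factor, equivalent doses,
predicted-additive ED50 and its delta-method uncertainty."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from loewe.additive_model import (
    AdditiveSurface,
    CombinationDesign,
    additive_effect,
    b_equivalent,
    k_factor,
    make_surface,
    predicted_ed50,
    predicted_ed50_se,
)
from loewe.dose_response import HillParams, hill_effect


def test_k_matches_direct_transcription(mech_surface):
    # E_B=85, E_A=79, C_A=20, q=1.5 at a=7
    a = 7.0
    expected = (85.0 / 79.0) * (1.0 + (20.0 / a) ** 1.5) - 1.0
    assert k_factor(mech_surface, a) == pytest.approx(expected, rel=1e-12)


@given(a=st.floats(0.01, 1e5))
def test_k_exceeds_maxima_ratio_bound(mech_surface, a):
    assert k_factor(mech_surface, a) > 85.0 / 79.0 - 1.0


def test_k_limits(mech_surface):
    assert k_factor(mech_surface, 0.0) == np.inf
    assert b_equivalent(mech_surface, 0.0) == 0.0
    # equal maxima: k -> 0+ as a grows, so the B-equivalent dose diverges
    eq = AdditiveSurface(
        params_a=HillParams(emax=80, ed50=20, hill=1.5),
        params_b=HillParams(emax=80, ed50=14, hill=2.6),
    )
    assert k_factor(eq, 1e8) == pytest.approx(0.0, abs=1e-8)
    assert b_equivalent(eq, 1e8) > 1e4


@given(a=st.floats(0.05, 5e3))
def test_dose_equivalence_identity(mech_surface, a):
    """hill(B, b_eq(a)) == hill(A, a): the defining property of b_eq."""
    beq = b_equivalent(mech_surface, a)
    assert hill_effect(mech_surface.params_b, beq) == pytest.approx(
        hill_effect(mech_surface.params_a, a), rel=1e-9
    )


def test_symmetric_half_max_maps_to_half_max():
    s = AdditiveSurface(
        params_a=HillParams(emax=60, ed50=20, hill=1.8),
        params_b=HillParams(emax=60, ed50=9, hill=1.8),
    )
    assert b_equivalent(s, 20.0) == pytest.approx(9.0, rel=1e-10)


def test_b_equivalent_agrees_with_root_finder_oracle(acetone_surface):
    a = 10.0
    target = hill_effect(acetone_surface.params_a, a)
    oracle = brentq(
        lambda b: hill_effect(acetone_surface.params_b, b) - target, 1e-9, 1e6,
        xtol=1e-12,
    )
    assert b_equivalent(acetone_surface, a) == pytest.approx(oracle, rel=1e-8)


def test_additive_effect_scalar_oracle(mech_surface):
    # independent transcription of the composite formula at a=b=7
    a = b = 7.0
    k = (85.0 / 79.0) * (1.0 + (20.0 / a) ** 1.5) - 1.0
    beq = 14.0 / k ** (1.0 / 2.6)
    expected = 85.0 * (b + beq) ** 2.6 / (14.0**2.6 + (b + beq) ** 2.6)
    assert additive_effect(mech_surface, a, b) == pytest.approx(expected, rel=1e-12)


def test_reduces_to_single_drug_curves(mech_surface):
    # a=0: drug B's own Hill curve, exactly
    assert additive_effect(mech_surface, 0.0, 14.0) == pytest.approx(42.5, rel=1e-9)
    # b=0: drug A's effect through dose equivalence
    for a in (2.0, 7.0, 20.0, 150.0):
        assert additive_effect(mech_surface, a, 0.0) == pytest.approx(
            hill_effect(mech_surface.params_a, a), rel=1e-9
        )
    assert additive_effect(mech_surface, 0.0, 0.0) == 0.0


@given(
    a1=st.floats(0, 300), a2=st.floats(0, 300),
    b1=st.floats(0, 300), b2=st.floats(0, 300),
)
def test_additive_effect_monotone_in_both_doses(mech_surface, a1, a2, b1, b2):
    alo, ahi = sorted((a1, a2))
    blo, bhi = sorted((b1, b2))
    if (alo, blo) == (ahi, bhi) or (alo == 0 and blo == 0):
        return
    assert additive_effect(mech_surface, alo, blo) <= additive_effect(
        mech_surface, ahi, bhi
    ) + 1e-9


def test_supremum_on_ray_is_eb(mech_surface):
    assert additive_effect(mech_surface, 5e5, 5e5) == pytest.approx(85.0, rel=1e-2)


def test_sham_combination_reproduces_single_drug():
    """Combining a drug with itself is the drug: Loewe self-consistency."""
    drug = HillParams(emax=85, ed50=14, hill=2.6)
    for frac in (0.3, 0.5, 0.8):
        surf = AdditiveSurface(
            params_a=HillParams(emax=85, ed50=14, hill=2.6),
            params_b=drug,
            design=CombinationDesign(frac_a=frac, frac_b=1 - frac),
        )
        for total in (3.0, 14.0, 40.0):
            assert additive_effect(
                surf, frac * total, (1 - frac) * total
            ) == pytest.approx(hill_effect(drug, total), rel=1e-9)


def test_sham_combination_ed50_is_common_ed50():
    drug = HillParams(emax=85, ed50=14, hill=2.6, dof=10)
    surf = AdditiveSurface(
        params_a=HillParams(emax=85, ed50=14, hill=2.6, dof=10), params_b=drug
    )
    assert predicted_ed50(surf).ed50 == pytest.approx(14.0, rel=1e-8)


def test_role_assignment_by_emax_then_ed50(thc_mech, cbd_mech):
    s1 = make_surface(thc_mech, cbd_mech)
    s2 = make_surface(cbd_mech, thc_mech)
    assert s1.params_b is thc_mech and s2.params_b is thc_mech
    # tie on emax: more potent drug (smaller ED50) becomes B
    x = HillParams(emax=80, ed50=25, hill=1.2)
    y = HillParams(emax=80, ed50=10, hill=2.0)
    assert make_surface(x, y).params_b is y


def test_predicted_ed50_invariant_under_relabeling(thc_mech, cbd_mech):
    e1 = predicted_ed50(make_surface(thc_mech, cbd_mech)).ed50
    e2 = predicted_ed50(make_surface(cbd_mech, thc_mech)).ed50
    assert e1 == pytest.approx(e2, rel=1e-12)


def test_surface_rejects_inverted_roles(thc_mech, cbd_mech):
    with pytest.raises(ValueError):
        AdditiveSurface(params_a=thc_mech, params_b=cbd_mech)
    # but an explicitly fixed convention is admitted
    forced = AdditiveSurface(params_a=thc_mech, params_b=cbd_mech,
                             check_roles=False)
    assert forced.params_b is cbd_mech


def test_printed_k_orientation_violates_dose_equivalence(cbd_mech, thc_mech):
    surf = AdditiveSurface(params_a=cbd_mech, params_b=thc_mech, printed_k=True)
    a = 7.0
    beq = b_equivalent(surf, a)
    assert hill_effect(thc_mech, beq) != pytest.approx(
        hill_effect(cbd_mech, a), rel=1e-3
    )


def test_predicted_ed50_reproduces_published_values(mech_surface, acetone_surface):
    assert predicted_ed50(mech_surface).ed50 == pytest.approx(14.0, abs=1.6)
    assert predicted_ed50(acetone_surface).ed50 == pytest.approx(20.0, abs=2.1)


def test_effect_level_is_half_composite_maximum(mech_surface):
    pred = predicted_ed50(mech_surface)
    assert pred.effect_level == pytest.approx(42.5)
    assert additive_effect(
        mech_surface, 0.5 * pred.ed50, 0.5 * pred.ed50
    ) == pytest.approx(42.5, rel=1e-8)


# ---------------------------------------------------------------------------
# delta-method SE


def test_zero_covariance_gives_zero_se(cbd_mech, thc_mech):
    a = HillParams(emax=79, ed50=20, hill=1.5)  # cov defaults to zeros
    b = HillParams(emax=85, ed50=14, hill=2.6)
    surf = AdditiveSurface(params_a=a, params_b=b)
    assert predicted_ed50_se(surf) == 0.0


def test_se_robust_to_gradient_step_size(mech_surface):
    se1 = predicted_ed50_se(mech_surface, rel_step=1e-4)
    se2 = predicted_ed50_se(mech_surface, rel_step=1e-6)
    assert se1 == pytest.approx(se2, rel=1e-4)


@pytest.mark.parametrize("surface_name", ["mech_surface", "acetone_surface"])
def test_se_matches_monte_carlo_propagation(surface_name, request, rng):
    """First-order propagation vs brute-force resampling of the fits."""
    surface = request.getfixturevalue(surface_name)
    delta_se = predicted_ed50_se(surface)
    A, B = surface.params_a, surface.params_b
    Sigma = np.zeros((6, 6))
    Sigma[:3, :3], Sigma[3:, 3:] = A.cov, B.cov
    theta0 = np.array([A.emax, A.ed50, A.hill, B.emax, B.ed50, B.hill])
    draws = rng.multivariate_normal(theta0, Sigma, size=10_000)
    vals = []
    for th in draws:
        if np.any(th <= 0) or th[3] <= th[0]:
            continue
        surf = AdditiveSurface(
            params_a=HillParams(emax=th[0], ed50=th[1], hill=th[2]),
            params_b=HillParams(emax=th[3], ed50=th[4], hill=th[5]),
        )
        vals.append(predicted_ed50(surf, with_se=False).ed50)
    mc_se = np.std(vals)
    assert delta_se == pytest.approx(mc_se, rel=0.10)


def test_design_validation():
    with pytest.raises(ValueError):
        CombinationDesign(frac_a=0.7, frac_b=0.4)
    with pytest.raises(ValueError):
        CombinationDesign(frac_a=0.0, frac_b=1.0)
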