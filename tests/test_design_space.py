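import numpy as np
import pytest

from cmlpipe.design_space import (
    Regulation,
    RegulationScheme,
    FIG_ARCHITECTURE,
    enumerate_schemes,
    count_schemes,
    negative_regulations,
    build_ssystems,
    solve_ssystem,
    check_consistency_and_stability,
    filter_models,
    map_design_space,
    _ComboEvaluator,
    _scheme_verdict,
)


@pytest.fixture(scope="module")
def evaluator():
    return _ComboEvaluator(seed=0)


# -- enumeration -----------------------------------------------------------


def test_full_enumeration_count():
    assert count_schemes() == 9**5 == 59_049


def test_negative_p0_constraint_count():
    constraints = {"p0": negative_regulations()}
    assert count_schemes(constraints) == 4 * 9**4 == 26_244
    schemes = list(enumerate_schemes(constraints))
    assert len(schemes) == 26_244
    assert all(s.p0.sign == -1 for s in schemes)


def test_selected_class_count():
    constraints = {
        "p0": [Regulation("P", -1)],
        "q1": [Regulation("TDm", -1)],
    }
    assert count_schemes(constraints) == 9**3 == 729
    assert sum(1 for _ in enumerate_schemes(constraints)) == 729


def test_contradictory_constraints_error():
    with pytest.raises(ValueError):
        list(enumerate_schemes({"p0": []}))
    with pytest.raises(ValueError):
        list(enumerate_schemes({"nope": [Regulation()]}))


def test_scheme_encoding_roundtrip():
    for scheme in (FIG_ARCHITECTURE, RegulationScheme()):
        assert RegulationScheme.decode(scheme.encode()) == scheme


# -- S-system construction -------------------------------------------------


def test_ssystem_count_unregulated():
    # per equation: S 1x1, P 2x2, TDl 1x1, TDm 1x3 -> 12 combinations,
    # no regime branches
    assert len(build_ssystems(RegulationScheme())) == 12


@pytest.mark.parametrize(
    "scheme, expected",
    [
        (RegulationScheme(p0=Regulation("P", -1)), 12 * 2),
        (
            RegulationScheme(p0=Regulation("P", -1), q1=Regulation("TDm", -1)),
            12 * 4,
        ),
        (FIG_ARCHITECTURE, 12 * 2**5),
    ],
)
def test_ssystem_count_product_rule(scheme, expected):
    assert len(build_ssystems(scheme)) == expected


def test_hill_branches_approximate_factor():
    # the two regime branches bracket the Hill factor within a factor 2
    # inside their regimes
    p0_max, gamma = 0.8, 1e-5
    for P, branch in [(1e3, "lo"), (1e7, "hi")]:
        full = p0_max / (1 + gamma * P)
        approx = p0_max if branch == "lo" else p0_max / (gamma * P)
        assert 0.5 < approx / full < 2.0


# -- solving and checks ----------------------------------------------------


PARAMS = {
    "p0_max": 0.8,
    "p1_max": 0.3,
    "q1_max": 0.4,
    "eta1_max": 0.05,
    "eta2_max": 0.5,
    "g_p0": 1e-5,
    "g_p1": 1e-9,
    "g_q1": 1e-9,
    "g_eta1": 1e-9,
    "g_eta2": 1e-9,
    "d_l": 0.02,
    "d_m": 0.03,
}


def _canonical_ssystem():
    """The balancing S-system of the p0 <- P negative core model."""
    scheme = RegulationScheme(p0=Regulation("P", -1))
    for ssys in build_ssystems(scheme):
        branches = {br.quantity: br.kind for br in ssys.branches}
        doms = [(s.label, k.label) for s, k in ssys.dominant]
        if branches["p0"] == "hi" and doms[1] == ("2*eta1*S", "eta2*P") and doms[3][1] == "d_m*TDm":
            return ssys
    raise AssertionError("canonical S-system not found")


def test_solve_ssystem_balances_exactly():
    ssys = _canonical_ssystem()
    eq = solve_ssystem(ssys, PARAMS)
    assert eq is not None and np.all(eq > 0)
    # substituting back: dominant source equals dominant sink per equation
    from cmlpipe.design_space import _log_params

    logp = _log_params(PARAMS)
    x = np.log(eq)
    for src, snk in ssys.dominant:
        assert src.log_value(logp, x) == pytest.approx(
            snk.log_value(logp, x), abs=1e-10
        )


def test_solve_ssystem_closed_form_progenitor():
    # stem balance on the hi branch: 2 p0_max / (g P) = 1
    ssys = _canonical_ssystem()
    eq = solve_ssystem(ssys, PARAMS)
    assert eq[1] == pytest.approx(2 * PARAMS["p0_max"] / PARAMS["g_p0"], rel=1e-10)


def test_solve_ssystem_matches_numeric_root():
    # brute-force oracle: generic root finder on the same power-law ODE
    from scipy.optimize import root

    ssys = _canonical_ssystem()
    eq = solve_ssystem(ssys, PARAMS)
    from cmlpipe.design_space import _log_params

    logp = _log_params(PARAMS)

    def power_law_rhs(logx):
        out = []
        for src, snk in ssys.dominant:
            out.append(src.log_value(logp, logx) - snk.log_value(logp, logx))
        return out

    sol = root(power_law_rhs, np.log(eq) + 0.37, method="hybr")
    assert sol.success
    assert np.allclose(np.exp(sol.x), eq, rtol=1e-8)


def test_consistency_fails_outside_regime():
    ssys = _canonical_ssystem()
    # make the regime condition g P > 1 fail at the balance point by
    # pushing the gain down: P-bar = 2 p0_max / g, so g P-bar = 2 p0_max
    # always holds; instead evaluate at a state inside the wrong regime
    eq = solve_ssystem(ssys, PARAMS)
    wrong = eq.copy()
    wrong[1] = 0.1 / PARAMS["g_p0"]  # g P = 0.1 << 1
    consistent, _stable = check_consistency_and_stability(ssys, wrong, PARAMS)
    assert not consistent


def test_canonical_ssystem_consistent_and_stable():
    ssys = _canonical_ssystem()
    eq = solve_ssystem(ssys, PARAMS)
    consistent, stable = check_consistency_and_stability(ssys, eq, PARAMS)
    assert consistent and stable


# -- model screening -------------------------------------------------------


def test_unregulated_scheme_rejected(evaluator):
    assert not _scheme_verdict(RegulationScheme(), evaluator).accepted


@pytest.mark.parametrize("source", ["S", "P", "TDl", "TDm"])
def test_negative_p0_core_accepted(evaluator, source):
    scheme = RegulationScheme(p0=Regulation(source, -1))
    assert _scheme_verdict(scheme, evaluator).accepted


@pytest.mark.parametrize("source", ["S", "P", "TDl", "TDm"])
def test_positive_p0_core_rejected(evaluator, source):
    scheme = RegulationScheme(p0=Regulation(source, +1))
    assert not _scheme_verdict(scheme, evaluator).accepted


def test_fig_architecture_accepted(evaluator):
    verdict = _scheme_verdict(FIG_ARCHITECTURE, evaluator)
    assert verdict.accepted
    assert verdict.p0_class == "P"


def test_no_p0_regulation_always_rejected(evaluator):
    # without p0 regulation no S-system balances the stem equation
    rng = np.random.default_rng(1)
    schemes = list(enumerate_schemes({"p0": [Regulation()]}))
    for i in rng.choice(len(schemes), 25, replace=False):
        assert not _scheme_verdict(schemes[i], evaluator).accepted


def test_filter_models_class_summary(evaluator):
    # one decorated representative per class plus rejects
    schemes = [
        RegulationScheme(p0=Regulation(src, -1), eta2=Regulation("S", -1))
        for src in ("S", "P", "TDl", "TDm")
    ] + [RegulationScheme(), RegulationScheme(p0=Regulation("P", +1))]
    verdicts, summary = filter_models(schemes, evaluator=evaluator)
    accepted = [v for v in verdicts if v.accepted]
    assert len(accepted) == 4
    assert set(summary["p0_class"]) == {"S", "P", "TDl", "TDm"}
    assert (summary["n_accepted"] == 1).all()


def test_stability_verdict_matches_integration_oracle(evaluator):
    # for accepted schemes, the full Hill model started near the
    # confirmed equilibrium converges back to it
    from cmlpipe.design_space import (
        build_ssystems,
        _full_model_rhs,
    )
    from scipy.integrate import solve_ivp

    rng = np.random.default_rng(2)
    schemes = list(enumerate_schemes({"p0": negative_regulations()}))
    checked = 0
    for i in rng.choice(len(schemes), 40, replace=False):
        scheme = schemes[i]
        for ssys in build_ssystems(scheme):
            witnesses = evaluator.stable_witnesses(ssys)
            if not witnesses or len(witnesses) < evaluator.MIN_WITNESSES:
                continue
            idx, eq = witnesses[0]
            prm = {k: float(np.exp(v[idx])) for k, v in evaluator.logp.items()}
            from cmlpipe.design_space import _full_model_confirms

            if not _full_model_confirms(scheme, prm, np.asarray(eq)):
                continue
            # perturb and integrate the full model
            from scipy.optimize import root

            sol = root(
                lambda ly: _full_model_rhs(scheme, prm, np.exp(ly)),
                np.log(np.asarray(eq)),
                method="hybr",
            )
            if not sol.success:
                continue
            full_eq = np.exp(sol.x)
            y0 = full_eq * 1.05
            res = solve_ivp(
                lambda t, y: _full_model_rhs(scheme, prm, y),
                (0, 1e5),
                y0,
                method="LSODA",
                rtol=1e-8,
            )
            assert res.success
            assert np.allclose(res.y[:, -1], full_eq, rtol=0.05)
            checked += 1
            break
        if checked >= 20:
            break
    assert checked >= 10


# -- design-space map ------------------------------------------------------


@pytest.fixture(scope="module")
def region_map(ref_patient_module):
    g1 = np.geomspace(1e-6, 3e-4, 7)
    g3 = np.geomspace(1e-5, 3e-2, 7)
    return map_design_space(ref_patient_module, g1, g3), g1, g3


@pytest.fixture(scope="module")
def ref_patient_module():
    from cmlpipe.cohort import reference_patient

    return reference_patient()[0]


def test_map_labels_piecewise_constant(region_map):
    df, g1, g3 = region_map
    # interior regions form contiguous blocks: each region's grid cells
    # touch at least one neighbour with the same label (on a 7x7 grid)
    pivot = df.pivot(index="gamma1", columns="gamma3", values="region")
    grid = pivot.to_numpy()
    for (i, j), region in np.ndenumerate(grid):
        if region <= 0:
            continue
        neighbours = []
        if i > 0:
            neighbours.append(grid[i - 1, j])
        if i < grid.shape[0] - 1:
            neighbours.append(grid[i + 1, j])
        if j > 0:
            neighbours.append(grid[i, j - 1])
        if j < grid.shape[1] - 1:
            neighbours.append(grid[i, j + 1])
        lone = all(n != region for n in neighbours)
        assert not lone or (grid == region).sum() == 1


def test_map_has_multiple_regions_and_kinds(region_map):
    df, _g1, _g3 = region_map
    interior = df[df["region"] > 0]
    assert interior["region"].nunique() >= 2
    assert set(interior["kind"]) <= {"node", "spiral"}
    assert "spiral" in set(interior["kind"])


def test_map_label_stable_under_small_perturbation(region_map, ref_patient_module):
    df, _g1, _g3 = region_map
    interior = df[df["region"] > 0]
    row = interior.iloc[len(interior) // 2]
    base = map_design_space(
        ref_patient_module, [row.gamma1], [row.gamma3]
    ).iloc[0]
    for f1 in (0.9, 1.1):
        for f3 in (0.9, 1.1):
            shifted = map_design_space(
                ref_patient_module, [row.gamma1 * f1], [row.gamma3 * f3]
            ).iloc[0]
            assert shifted.signature == base.signature
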