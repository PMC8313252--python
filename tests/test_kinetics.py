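"""Master-equation kinetics: rate matrix, conservation, flux DP."""

import numpy as np
import pytest

from phytascreen.kinetics import (
    SPECIES_ORDER,
    CommunityModel,
    EnzymeModel,
    build_rate_matrix,
    class_flux,
    class_profile,
    pathway_flux,
    simulate_timecourse,
)
from phytascreen.profiles import PI_POOL

INSP6 = frozenset({1, 2, 3, 4, 5, 6})
I6 = SPECIES_ORDER.index(INSP6)


def uniform_enzyme(k=1.0):
    return EnzymeModel("uniform", "GENERIC", (1 / 6,) * 6, k)


def test_rate_matrix_single_uniform_enzyme():
    c = CommunityModel(enzymes=[(uniform_enzyme(), 1.0)])
    q = build_rate_matrix(c)
    assert q[I6, I6] == pytest.approx(-1.0)
    # columns sum to zero absent sorption (probability flows downward)
    assert np.allclose(q.sum(axis=0), 0.0, atol=1e-12)


def test_rate_matrix_sorption_only():
    c = CommunityModel(enzymes=[], sorption_rate=0.7)
    q = build_rate_matrix(c)
    expected = np.zeros_like(q)
    expected[I6, I6] = -0.7
    assert np.allclose(q, expected)


def test_rate_matrix_lag_suppresses_enzymes_early():
    c = CommunityModel(
        enzymes=[(uniform_enzyme(), 1.0)], sorption_rate=0.5, t_lag=5.0, tau=0.25
    )
    q_early = build_rate_matrix(c, t=0.0)
    assert q_early[I6, I6] == pytest.approx(-0.5, abs=1e-6)
    q_late = build_rate_matrix(c, t=10.0)
    assert q_late[I6, I6] == pytest.approx(-1.5, abs=1e-6)


def test_time_zero_returns_initial_state():
    c = CommunityModel(enzymes=[(uniform_enzyme(), 1.0)])
    x0 = np.zeros(64)
    x0[I6] = 2.5
    tc = simulate_timecourse(c, x0, [0, 1])
    assert np.allclose(tc.abundance[0], x0)


def test_uniform_enzyme_exponential_decay_closed_form():
    c = CommunityModel(enzymes=[(uniform_enzyme(1.0), 1.0)])
    t = [0, 0.25, 0.5, 1.0, 2.0, 4.0]
    tc = simulate_timecourse(c, {"InsP6": 1.0}, t)
    assert np.allclose(tc.abundance[:, I6], np.exp(-np.asarray(t)), atol=1e-9)


def test_everything_reaches_free_inositol_and_pi():
    c = CommunityModel(enzymes=[(uniform_enzyme(2.0), 1.0)])
    tc = simulate_timecourse(c, {"InsP6": 1.0}, [0, 50.0])
    i0 = SPECIES_ORDER.index(frozenset())
    assert tc.abundance[-1, i0] == pytest.approx(1.0, abs=1e-6)
    assert tc.pi_pool[-1] == pytest.approx(6.0, abs=1e-6)


def test_sorption_only_no_intermediates_no_pi():
    c = CommunityModel(enzymes=[], sorption_rate=1.0)
    tc = simulate_timecourse(c, {"InsP6": 1.0}, [0, 1, 3])
    assert np.allclose(tc.abundance[:, I6], np.exp(-np.array([0, 1, 3])), atol=1e-9)
    others = np.delete(tc.abundance, I6, axis=1)
    assert np.allclose(others, 0.0, atol=1e-12)
    assert np.allclose(tc.pi_pool, 0.0, atol=1e-12)
    assert tc.sorbed_pool[-1] == pytest.approx(1 - np.exp(-3), abs=1e-9)


def test_scale_invariance_weights_vs_rate():
    w = (0.3, 0.05, 0.9, 0.2, 0.1, 1.5)
    a = EnzymeModel("a", "GENERIC", w, 1.0)
    b = EnzymeModel("b", "GENERIC", tuple(2 * x for x in w), 0.5)
    t = [0, 0.5, 1, 2]
    ta = simulate_timecourse(CommunityModel(enzymes=[(a, 1.0)]), {"InsP6": 1.0}, t)
    tb = simulate_timecourse(CommunityModel(enzymes=[(b, 1.0)]), {"InsP6": 1.0}, t)
    assert np.allclose(ta.abundance, tb.abundance, atol=1e-10)


def test_insp6_nonincreasing_pi_nondecreasing():
    rng = np.random.default_rng(7)
    e = EnzymeModel("r", "GENERIC", tuple(rng.uniform(0, 2, 6)), 0.8)
    c = CommunityModel(enzymes=[(e, 1.0)], sorption_rate=0.2)
    tc = simulate_timecourse(c, {"InsP6": 1.0}, np.linspace(0, 4, 33))
    assert np.all(np.diff(tc.abundance[:, I6]) <= 1e-12)
    assert np.all(np.diff(tc.pi_pool) >= -1e-12)


def test_conservation_on_random_communities():
    """Inositol and phosphate bookkeeping closes on 100 random communities."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        n_enz = rng.integers(1, 4)
        enzymes = [
            (
                EnzymeModel(f"e{i}", "GENERIC", tuple(rng.uniform(0, 3, 6)), rng.uniform(0.05, 2)),
                rng.uniform(0.1, 2),
            )
            for i in range(n_enz)
        ]
        c = CommunityModel(
            enzymes=enzymes,
            sorption_rate=rng.uniform(0, 1),
            pi_uptake_rate=rng.uniform(0, 2),
            t_lag=float(rng.choice([0.0, rng.uniform(0.5, 2)])),
        )
        x0 = rng.uniform(0, 1, 64)
        tc = simulate_timecourse(c, x0, np.linspace(0, 2, 9))
        assert np.all(tc.abundance >= -1e-9)
        ino = tc.total_inositol()
        phos = tc.total_phosphate()
        assert np.allclose(ino, ino[0], rtol=1e-6)
        assert np.allclose(phos, phos[0], rtol=1e-6)


def test_rk4_agrees_with_matrix_exponential():
    e = EnzymeModel("e", "GENERIC", (0.4, 0.1, 1.2, 0.3, 0.6, 0.9), 1.0)
    c = CommunityModel(enzymes=[(e, 1.0)], sorption_rate=0.3, pi_uptake_rate=0.5, t_lag=1.0)
    t = [0, 0.5, 1.0, 2.0]
    a = simulate_timecourse(c, {"InsP6": 1.0}, t, method="expm", max_step=0.005)
    b = simulate_timecourse(c, {"InsP6": 1.0}, t, method="rk4", rk4_step=0.001)
    assert np.allclose(a.abundance, b.abundance, atol=1e-6)
    assert np.allclose(a.pi_pool, b.pi_pool, atol=1e-6)


def test_grid_validation():
    c = CommunityModel(enzymes=[(uniform_enzyme(), 1.0)])
    with pytest.raises(ValueError):
        simulate_timecourse(c, {"InsP6": 1.0}, [0, 1, 1])
    with pytest.raises(ValueError):
        simulate_timecourse(c, {"InsP6": 1.0}, [1, 2])
    with pytest.raises(ValueError):
        simulate_timecourse(c, -np.ones(64), [0, 1])


def test_pathway_flux_uniform_enzyme_symmetry():
    f = pathway_flux(uniform_enzyme())
    for s in SPECIES_ORDER:
        if len(s) == 5:
            assert f[s] == pytest.approx(1 / 6)
    shares = class_flux(uniform_enzyme())
    assert shares["InsP5 [1/3-OH]"] == pytest.approx(1 / 3)
    assert shares["InsP5 [4/6-OH]"] == pytest.approx(1 / 3)
    assert shares["InsP5 [2-OH]"] == pytest.approx(1 / 6)
    assert shares["InsP5 [5-OH]"] == pytest.approx(1 / 6)


def test_pathway_flux_level_sums_to_one():
    rng = np.random.default_rng(3)
    for _ in range(10):
        e = EnzymeModel("r", "GENERIC", tuple(rng.uniform(0.01, 2, 6)), 1.0)
        f = pathway_flux(e)
        for level in range(7):
            total = sum(v for s, v in f.items() if len(s) == level)
            assert total == pytest.approx(1.0, abs=1e-12)


def test_pathway_flux_rejects_all_zero_weights():
    e = EnzymeModel("z", "GENERIC", (0.0,) * 5 + (1.0,), 1.0)
    dead = EnzymeModel.__new__(EnzymeModel)  # bypass validation to probe the op
    object.__setattr__(dead, "name", "dead")
    object.__setattr__(dead, "class_label", "GENERIC")
    object.__setattr__(dead, "weights", (0.0,) * 6)
    object.__setattr__(dead, "k", 1.0)
    with pytest.raises(ValueError):
        pathway_flux(dead)
    # terminal products: zero weight at remaining positions strands flux
    f = pathway_flux(e)
    assert f[frozenset({1, 2, 3, 4, 5})] == pytest.approx(1.0)
    assert sum(v for s, v in f.items() if len(s) == 4) == pytest.approx(0.0)


def test_timecourse_throughput_matches_flux_dp():
    """ODE cumulative throughput equals the DP pathway flux (oracle pair)."""
    rng = np.random.default_rng(11)
    e = EnzymeModel("r", "GENERIC", tuple(rng.uniform(0.2, 1.5, 6)), 1.0)
    c = CommunityModel(enzymes=[(e, 1.0)])
    grid = np.linspace(0, 60, 6001)
    tc = simulate_timecourse(c, {"InsP6": 1.0}, grid)
    f = pathway_flux(e)
    for j, s in enumerate(SPECIES_ORDER):
        if len(s) in (0, 6):
            continue
        out_rate = e.k * sum(e.w(p) for p in s)
        throughput = out_rate * np.trapezoid(tc.abundance[:, j], grid)
        assert throughput == pytest.approx(f[s], abs=1e-4)


def test_class_profile_aggregation_and_pi_pooling():
    c = CommunityModel(enzymes=[(uniform_enzyme(1.0), 1.0)])
    tc = simulate_timecourse(c, {"InsP6": 1.0}, np.linspace(0, 2, 21))
    prof = class_profile(tc, 1.0)
    miss4 = SPECIES_ORDER.index(frozenset({1, 2, 3, 5, 6}))
    miss6 = SPECIES_ORDER.index(frozenset({1, 2, 3, 4, 5}))
    x = tc.at(1.0)
    assert prof["InsP5 [4/6-OH]"] == pytest.approx(x[miss4] + x[miss6])
    assert prof[PI_POOL] >= tc.pi_at(1.0)  # InsP1 pools with Pi
    norm = class_profile(tc, 1.0, normalize=True)
    assert norm.total(include_pi=False) == pytest.approx(1.0)


def test_initial_state_splits_pairs_racemically():
    c = CommunityModel(enzymes=[(uniform_enzyme(), 1.0)])
    tc = simulate_timecourse(c, {"InsP5 [1/3-OH]": 1.0}, [0, 0.1])
    a = tc.abundance[0, SPECIES_ORDER.index(frozenset({2, 3, 4, 5, 6}))]
    b = tc.abundance[0, SPECIES_ORDER.index(frozenset({1, 2, 4, 5, 6}))]
    assert a == pytest.approx(0.5) and b == pytest.approx(0.5)


def test_timecourse_export_columns(tmp_path):
    c = CommunityModel(enzymes=[(uniform_enzyme(), 1.0)])
    tc = simulate_timecourse(c, {"InsP6": 1.0}, [0, 1])
    df = tc.to_frame()
    assert df.shape[1] == 1 + 64 + 3
    assert {"time_days", "Ins(1,2,3,4,5,6)P6", "Pi", "sorbed"} <= set(df.columns)
    tc.write(tmp_path / "tc.tsv")
    assert (tmp_path / "tc.tsv").exists()
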