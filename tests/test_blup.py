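import numpy as np
import pandas as pd
import pytest

from conftest import small_sim_config
from durmap.blup import (
    BlupSet,
    blups_to_table,
    fit_augmented_reml,
    read_blup_table,
    solve_blups,
    write_blup_table,
)
from durmap.io import TrialData
from durmap.simulate import generate_collection, generate_trial


def henderson_mme(y, X, Zs, variances):
    """Independent oracle: Henderson's mixed-model equations.

    Solves [X'X/s2e  X'Z/s2e; Z'X/s2e  Z'Z/s2e + D^-1] [b; u] =
    [X'y; Z'y]/s2e over all random factors jointly, a different
    computational route than the V-inverse conditional mean.
    """
    s2e = variances[3]
    active = [(Z, s2) for Z, s2 in zip(Zs, variances[:3]) if s2 > 0]
    Z = np.hstack([Z for Z, _ in active]) if active else np.zeros((y.size, 0))
    dinv = np.concatenate([[1.0 / s2] * Z_.shape[1] for Z_, s2 in active]) \
        if active else np.zeros(0)
    p, q = X.shape[1], Z.shape[1]
    lhs = np.zeros((p + q, p + q))
    lhs[:p, :p] = X.T @ X / s2e
    lhs[:p, p:] = X.T @ Z / s2e
    lhs[p:, :p] = Z.T @ X / s2e
    lhs[p:, p:] = Z.T @ Z / s2e + np.diag(dinv)
    rhs = np.concatenate([X.T @ y, Z.T @ y]) / s2e
    sol = np.linalg.solve(lhs, rhs)
    return sol[:p], sol[p:]


def test_blup_shrinkage_closed_form():
    """One observation per accession, equal variances: shrinkage 0.5."""
    rng = np.random.default_rng(0)
    n = 12
    y = rng.normal(10.0, 2.0, n)
    X = np.ones((n, 1))
    Za = np.eye(n)
    Zr = np.zeros((n, 1))
    Zc = np.zeros((n, 1))
    variances = np.array([0.0, 0.0, 1.0, 1.0])  # s2_acc = s2_e
    beta, u, _ = solve_blups(y, X, [Zr, Zc, Za], variances)
    mu = y.mean()
    np.testing.assert_allclose(beta[0], mu, rtol=1e-10)
    np.testing.assert_allclose(u, 0.5 * (y - mu), rtol=1e-8)


def test_blups_match_henderson_oracle():
    """Mixed-model solutions agree with Henderson's equations to 1e-8."""
    rng = np.random.default_rng(1)
    for trial_no in range(3):
        n = 30
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        def indic(k):
            lev = rng.integers(0, k, n)
            Z = np.zeros((n, k))
            Z[np.arange(n), lev] = 1.0
            return Z
        Zs = [indic(5), indic(4), indic(10)]
        variances = np.array([0.3, 0.2, 1.1, 0.7])
        y = rng.normal(size=n)
        beta, u, _ = solve_blups(y, X, Zs, variances)
        beta_o, u_o = henderson_mme(y, X, Zs, variances)
        np.testing.assert_allclose(beta, beta_o, atol=1e-8)
        np.testing.assert_allclose(u, u_o[-10:], atol=1e-8)


def test_noise_free_limit_recovers_genetic_values():
    """With vanishing non-genetic variance BLUPs equal true values."""
    cfg = small_sim_config(
        seed=4, sigma2_row=1e-10, sigma2_col=1e-10, sigma2_e=1e-10,
        sigma2_sub_env=0.0,
    )
    ds, led = generate_collection(cfg)
    trial = generate_trial(ds, cfg, led)
    _, bl = fit_augmented_reml(trial, "plant_height", "C")
    truth = cfg.env_means["C"] + led.genetic_values["plant_height"]
    np.testing.assert_allclose(
        bl.predicted.reindex(truth.index), truth, atol=1e-4
    )


def test_reml_equivariance_under_affine_response():
    cfg = small_sim_config(seed=6)
    ds, led = generate_collection(cfg)
    trial = generate_trial(ds, cfg, led)
    vc0, bl0 = fit_augmented_reml(trial, "plant_height", "C")

    shifted = TrialData(records=trial.records.assign(
        value=trial.records["value"].astype(float) + 100.0),
        check_ids=trial.check_ids)
    vc1, bl1 = fit_augmented_reml(shifted, "plant_height", "C")
    assert bl1.intercept == pytest.approx(bl0.intercept + 100.0, abs=1e-4)
    for k, v in vc0.as_dict().items():
        assert vc1.as_dict()[k] == pytest.approx(v, rel=1e-4, abs=1e-8)

    scaled = TrialData(records=trial.records.assign(
        value=trial.records["value"].astype(float) * 3.0),
        check_ids=trial.check_ids)
    vc3, _ = fit_augmented_reml(scaled, "plant_height", "C")
    for k, v in vc0.as_dict().items():
        assert vc3.as_dict()[k] == pytest.approx(9.0 * v, rel=1e-3, abs=1e-8)


def test_accession_effects_centered():
    cfg = small_sim_config(seed=8)
    ds, led = generate_collection(cfg)
    trial = generate_trial(ds, cfg, led)
    _, bl = fit_augmented_reml(trial, "plant_height", "N")
    assert abs(bl.effects.mean()) < 1e-6 * max(bl.effects.std(), 1e-12) + 1e-8


def test_constant_trait_returns_zero_components():
    rows = []
    k = 0
    for r in range(4):
        for c in range(4):
            entry = ["chk1", "chk2"][k % 2] if (r + c) % 3 == 0 else f"a{k}"
            rows.append(dict(environment="C", row=r, col=c, entry=entry,
                             is_check=entry.startswith("chk"),
                             trait="t", value=5.0))
            k += 1
    trial = TrialData(records=pd.DataFrame(rows), check_ids=["chk1", "chk2"])
    vc, bl = fit_augmented_reml(trial, "t", "C")
    assert vc.converged
    assert all(v == 0.0 for v in vc.as_dict().values())
    assert (bl.predicted == bl.predicted.iloc[0]).all()


def test_blups_to_table_shape_and_duplicates():
    def mk(trait, env, accs, vals):
        return BlupSet(trait=trait, environment=env, intercept=0.0,
                       effects=pd.Series(vals, index=accs),
                       pev=pd.Series(0.1, index=accs),
                       check_effects=pd.Series(dtype=float))

    sets = [mk("t", "C", ["a", "b", "c"], [1.0, 2.0, 3.0]),
            mk("t", "N", ["a", "b", "c"], [4.0, 5.0, 6.0])]
    table = blups_to_table(sets)
    assert table.shape == (3, 2)
    assert table.notna().sum().sum() == 6
    with pytest.raises(ValueError, match="duplicate"):
        blups_to_table(sets + [sets[0]])

    # accession absent from one environment -> NA cell
    sets2 = [mk("t", "C", ["a", "b", "c"], [1.0, 2.0, 3.0]),
             mk("t", "S08", ["a", "b"], [4.0, 5.0])]
    table2 = blups_to_table(sets2)
    assert np.isnan(table2.loc["c", ("t", "S08")])


def test_blup_table_roundtrip_six_significant_digits(tmp_path):
    rng = np.random.default_rng(9)
    accs = [f"a{i}" for i in range(5)]
    sets = [BlupSet(trait="t", environment=e, intercept=0.0,
                    effects=pd.Series(rng.normal(100, 10, 5), index=accs),
                    pev=pd.Series(0.1, index=accs),
                    check_effects=pd.Series(dtype=float))
            for e in ("C", "N")]
    table = blups_to_table(sets)
    write_blup_table(table, tmp_path / "blups.tsv")
    back = read_blup_table(tmp_path / "blups.tsv")
    np.testing.assert_allclose(back.to_numpy(), table.to_numpy(), rtol=1e-5)
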