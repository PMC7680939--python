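"""Site-regression decomposition, polygon winners and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metgain.errors import ValidationError
from metgain.met import MetSpec, fit_met
from metgain.simulate import SimConfig, simulate_series
from metgain.sreg import (
    BiplotResult,
    GxETable,
    environment_correlations,
    me_blup_correlations,
    sreg_decompose,
    which_won_where,
)


def _rank2_table(g=12, e=6, seed=0):
    rng = np.random.default_rng(seed)
    a1, b1 = rng.normal(size=g), rng.normal(size=e)
    a2, b2 = rng.normal(size=g), rng.normal(size=e)
    M = np.outer(a1, b1) + np.outer(a2, b2)
    return GxETable(pd.DataFrame(
        M, index=[f"G{i}" for i in range(g)], columns=[f"E{j}" for j in range(e)]
    ))


def test_rank2_table_explains_everything():
    result = sreg_decompose(_rank2_table(), scaling="centered")
    assert result.pct_explained_12 == pytest.approx(100.0, abs=1e-9)


def test_identical_genotype_rows_score_at_origin():
    M = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (5, 1)),
                     index=list("abcde"), columns=["E1", "E2", "E3"])
    # add one distinct genotype so centering is non-trivial
    M.loc["f"] = [2.0, 3.0, 4.0]
    result = sreg_decompose(GxETable(M), scaling="centered")
    first_five = result.genotype_scores.loc[list("abcde")]
    assert np.allclose(first_five.to_numpy() - first_five.to_numpy()[0], 0.0)


def test_svd_reconstruction_and_total_ss():
    rng = np.random.default_rng(4)
    M = pd.DataFrame(rng.normal(5.0, 1.0, (20, 8)))
    M.index = [f"G{i}" for i in range(20)]
    M.columns = [f"E{j}" for j in range(8)]
    table = GxETable(M)
    result = sreg_decompose(table, scaling="standardized")
    Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    total_ss = float((Z.to_numpy() ** 2).sum())
    assert np.sum(result.singular_values**2) == pytest.approx(total_ss, abs=1e-9)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    assert np.allclose(U * s @ Vt, Z.to_numpy(), atol=1e-10)


def test_centering_removes_environment_constants():
    table = _rank2_table(seed=5)
    shifted = GxETable(table.values + np.arange(table.values.shape[1]))
    r1 = sreg_decompose(table, scaling="centered")
    r2 = sreg_decompose(shifted, scaling="centered")
    np.testing.assert_allclose(
        r1.genotype_scores.to_numpy(), r2.genotype_scores.to_numpy(), atol=1e-9
    )


def test_zero_variance_environment_rejected():
    M = _rank2_table().values.copy()
    M["E0"] = 3.14
    with pytest.raises(ValidationError, match="E0"):
        sreg_decompose(GxETable(M), scaling="standardized")


def test_which_won_where_simple_geometry():
    scores_g = pd.DataFrame(
        [[1, 1], [1, -1], [-1, 1], [-1, -1]],
        index=["g++", "g+-", "g-+", "g--"], columns=["PC1", "PC2"],
        dtype=float,
    )
    scores_e = pd.DataFrame([[0.5, 0.5]], index=["E"], columns=["PC1", "PC2"])
    result = BiplotResult(scores_g, scores_e, np.array([1.0]), 100.0, [], {})
    vertices, winners = which_won_where(result)
    assert set(vertices) == {"g++", "g+-", "g-+", "g--"}
    assert winners["E"] == "g++"


def test_winner_agrees_with_rank2_reconstruction():
    """On an exactly rank-2 table the sector winner equals the argmax of the
    reconstructed cell values."""
    table = _rank2_table(seed=8)
    result = sreg_decompose(table, scaling="centered")
    Z = table.values - table.values.mean(axis=0)
    for env, winner in result.sector_winners.items():
        best = Z[env].idxmax()
        # argmax over ALL genotypes; winner is a hull vertex, so they agree
        assert winner == best


def test_collinear_scores_raise_degenerate_error():
    scores_g = pd.DataFrame([[0, 0], [1, 1], [2, 2]], index=list("abc"),
                            columns=["PC1", "PC2"], dtype=float)
    scores_e = pd.DataFrame([[1, 0]], index=["E"], columns=["PC1", "PC2"])
    result = BiplotResult(scores_g, scores_e, np.array([1.0]), 100.0, [], {})
    with pytest.raises(ValidationError):
        which_won_where(result)


def test_environment_correlation_identities():
    rng = np.random.default_rng(1)
    x = rng.normal(size=12)
    resid = rng.normal(size=12)
    resid -= resid.mean()
    x_c = x - x.mean()
    resid -= (resid @ x_c) / (x_c @ x_c) * x_c  # orthogonalize
    M = pd.DataFrame({"A": x, "Adup": x, "B": resid + 3.0})
    M.index = [f"G{i}" for i in range(12)]
    r, p = environment_correlations(GxETable(M))
    assert r.loc["A", "Adup"] == pytest.approx(1.0)
    assert p.loc["A", "Adup"] < 1e-12
    assert r.loc["A", "B"] == pytest.approx(0.0, abs=1e-10)


def test_correlation_p_matches_t_distribution():
    """n = 10 pairs with r ~ 0.4: p equals the closed-form t test."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        x = rng.normal(size=10)
        y = 0.4 * x + rng.normal(size=10)
        M = pd.DataFrame({"A": x, "B": y}, index=[f"G{i}" for i in range(10)])
        M["C"] = rng.normal(size=10)
        r, p = environment_correlations(GxETable(M))
        rr = r.loc["A", "B"]
        t = rr * np.sqrt((10 - 2) / (1 - rr**2))
        p_manual = 2 * stats.t.sf(abs(t), df=8)
        assert p.loc["A", "B"] == pytest.approx(p_manual, abs=1e-10)


def test_too_few_common_genotypes_flagged_missing():
    M = pd.DataFrame({"A": [1.0, 2.0, np.nan, np.nan],
                      "B": [np.nan, np.nan, 1.0, 2.0],
                      "C": [1.0, 2.0, 3.0, 4.0]},
                     index=list("wxyz"))
    r, p = environment_correlations(GxETable(M))
    assert np.isnan(r.loc["A", "B"]) and np.isnan(p.loc["A", "B"])


def test_me_blup_correlations_identical_fits(small_fit):
    r, p = me_blup_correlations({"ME1": small_fit, "ME4": small_fit})
    assert r.loc["ME1", "ME4"] == pytest.approx(1.0)


def test_me_blup_correlations_null_when_independent():
    """Independent megaenvironments with no shared genetic signal: mean
    correlation across seeds is consistent with zero."""
    rs = []
    for seed in range(8):
        fits = {}
        for i, me in enumerate(("ME1", "ME4")):
            cfg = SimConfig(n_trials=1, n_genotypes=20, n_subblocks=4,
                            n_sites_per_me={me: 2}, sigma_g=0.0,
                            loading_scale=0.0, psi_range=(0.0, 0.0), fa_order=0,
                            trend_pct_per_year=0.0, seed=1000 * (i + 1) + seed)
            records, _, _ = simulate_series(cfg)
            # same entry labels in both MEs: relabel by position
            fits[me] = fit_met(records, MetSpec(model_variant="no_gxe", seed=seed))
        rs.append(me_blup_correlations(fits)[0].loc["ME1", "ME4"])
    se = np.std(rs, ddof=1) / np.sqrt(len(rs))
    assert abs(np.mean(rs)) < 2.5 * se + 0.05


def test_me_blup_correlations_high_when_genetic_signal_shared(small_series):
    """Splitting one trial's sites into two halves: shared genotype main
    effects give a clearly positive BLUP correlation."""
    records, _, truth = small_series
    sites = sorted(records["site"].unique())
    half1 = records[records["site"].isin(sites[:3])]
    half2 = records[records["site"].isin(sites[3:])]
    fits = {
        "A": fit_met(half1, MetSpec(model_variant="diagonal", seed=1)),
        "B": fit_met(half2, MetSpec(model_variant="diagonal", seed=1)),
    }
    r, _ = me_blup_correlations(fits)
    assert r.loc["A", "B"] > 0.2


def test_table_shape_invariants():
    with pytest.raises(ValidationError):
        GxETable(pd.DataFrame(np.ones((2, 3))))
    with pytest.raises(ValidationError):
        GxETable(pd.DataFrame(np.ones((5, 1))))
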