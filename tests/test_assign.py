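"""Geographic assignment: PCA, BIC cluster choice, DAPC, leave-one-out
likelihood self-assignment, continuous grid assignment, accuracy report."""

import numpy as np
import pandas as pd
import pytest

from panelforge import (
    GridSpec,
    PanelforgeError,
    PopulationModel,
    assignment_report,
    continuous_grid_assign,
    dapc_classify,
    find_clusters_bic,
    generate_structured_populations,
    loo_likelihood_assign,
    pca_genotypes,
)
from conftest import make_matrix


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_duplicated_sample_has_identical_scores():
    rng = np.random.default_rng(81)
    d = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
    d[3] = d[0]
    gm = make_matrix(d)
    scores, _, _ = pca_genotypes(gm, 2)
    assert np.allclose(scores[0], scores[3])


def test_pca_separates_two_populations():
    from sklearn.metrics import silhouette_score

    model = PopulationModel(n_pops=2, fst_target=0.3, n_loci=300, seed=82)
    gm, meta, _ = generate_structured_populations(model, 15)
    scores, _, _ = pca_genotypes(gm, 2)
    assert silhouette_score(scores[:, :1], meta["pop"]) > 0.5


def test_pca_handles_missing_by_mean_imputation():
    rng = np.random.default_rng(83)
    d = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
    d[rng.random(d.shape) < 0.1] = -1
    scores, loadings, ev = pca_genotypes(make_matrix(d), 3)
    assert np.isfinite(scores).all() and np.isfinite(loadings).all()


def test_pca_sign_convention_is_deterministic():
    rng = np.random.default_rng(84)
    gm = make_matrix(rng.integers(0, 3, size=(15, 30)))
    s1, l1, _ = pca_genotypes(gm, 2)
    s2, l2, _ = pca_genotypes(gm, 2)
    assert np.allclose(s1, s2) and np.allclose(l1, l2)
    for k in range(l1.shape[0]):
        assert l1[k, np.argmax(np.abs(l1[k]))] > 0


def test_pca_all_constant_errors():
    gm = make_matrix(np.ones((5, 4)))
    with pytest.raises(PanelforgeError):
        pca_genotypes(gm, 2)


# ---------------------------------------------------------------------------
# Cluster number by BIC
# ---------------------------------------------------------------------------

def test_bic_recovers_planted_k(five_pop_sim):
    gm, meta, _ = five_pop_sim
    scores, _, _ = pca_genotypes(gm, 20)
    k, curve = find_clusters_bic(scores, k_max=8, seed=0)
    assert k == 5
    assert curve.shape == (8,)


def test_bic_single_population_gives_k1():
    model = PopulationModel(n_pops=1, fst_target=0.05, n_loci=400, seed=85)
    gm, _, _ = generate_structured_populations(model, 40)
    scores, _, _ = pca_genotypes(gm, 20)
    k, _ = find_clusters_bic(scores, k_max=6, seed=0)
    assert k == 1


def test_bic_deterministic_under_seed(five_pop_sim):
    gm, _, _ = five_pop_sim
    scores, _, _ = pca_genotypes(gm, 10)
    _, c1 = find_clusters_bic(scores, 6, seed=2)
    _, c2 = find_clusters_bic(scores, 6, seed=2)
    assert np.allclose(c1, c2)


def test_bic_validates_k_max():
    with pytest.raises(PanelforgeError):
        find_clusters_bic(np.zeros((10, 2)), 0)
    with pytest.raises(PanelforgeError):
        find_clusters_bic(np.zeros((10, 2)), 10)


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

def test_dapc_perfect_reassignment_when_separated():
    model = PopulationModel(n_pops=3, fst_target=0.3, n_loci=400, seed=86)
    gm, meta, _ = generate_structured_populations(model, 12)
    post, reassign = dapc_classify(gm, meta["pop"], n_pcs=10)
    assert reassign.min() == 1.0
    assert np.allclose(post.sum(axis=1), 1.0)


def test_dapc_shuffled_labels_at_chance(five_pop_sim):
    gm, meta, _ = five_pop_sim
    rng = np.random.default_rng(87)
    shuffled = rng.permutation(meta["pop"].to_numpy())
    # few retained PCs keep in-sample LDA honest about random labels
    _, reassign = dapc_classify(gm, shuffled, n_pcs=2)
    assert abs(reassign.mean() - 0.2) < 0.15


def test_dapc_rejects_singleton_group():
    gm = make_matrix(np.random.default_rng(88).integers(0, 3, size=(5, 20)))
    with pytest.raises(PanelforgeError):
        dapc_classify(gm, ["a", "a", "a", "a", "b"], n_pcs=2)
    with pytest.raises(PanelforgeError):
        dapc_classify(gm, ["a", "a", "a", "b", "b"], n_pcs=0)


# ---------------------------------------------------------------------------
# Leave-one-out likelihood assignment
# ---------------------------------------------------------------------------

def test_loo_high_accuracy_at_panel_differentiation(five_pop_sim):
    gm, meta, _ = five_pop_sim
    res = loo_likelihood_assign(gm, meta["pop"].to_numpy())
    a = res.assignments
    correct_robust = ((a["map_label"] == a["true"]) & a["robust"]).mean()
    assert correct_robust >= 0.95
    assert np.allclose(res.posterior.sum(axis=1), 1.0, atol=1e-9)


def test_loo_identical_group_frequencies_give_mild_posteriors():
    """Two groups drawn from one panmictic population carry no assignment
    signal: posteriors stay close to 1/2 and assignments split evenly."""
    rng = np.random.default_rng(89)
    d = rng.binomial(2, np.full(20, 0.5), size=(50, 20)).astype(np.int8)
    gm = make_matrix(d)
    labels = ["a"] * 25 + ["b"] * 25
    res = loo_likelihood_assign(gm, labels)
    a = res.assignments
    assert a["posterior"].mean() < 0.85
    assert 0.2 <= (a["map_label"] == a["true"]).mean() <= 0.8


def test_loo_excludes_query_from_its_own_group_frequencies():
    """A sample opposite to its own group but identical to the other group
    must be assigned away - leakage of its own genotype would pull it back."""
    own = np.zeros((3, 100), dtype=np.int8)
    own[0] = 2  # the probe: all-alt genotype labelled group a
    other = np.full((3, 100), 2, dtype=np.int8)
    gm = make_matrix(np.vstack([own, other]))
    res = loo_likelihood_assign(gm, ["a"] * 3 + ["b"] * 3)
    probe = res.assignments.iloc[0]
    assert probe["map_label"] == "b"
    assert probe["robust"]


def test_loo_unrepresented_population_scores_weaker_posteriors():
    """Samples whose true population is absent from the reference groups
    receive systematically weaker posterior support than genuine members
    (with only four candidate groups their likelihood mass splits)."""
    model = PopulationModel(n_pops=5, fst_target=0.1, n_loci=200, seed=90)
    gm, meta, _ = generate_structured_populations(model, 10)
    labels = meta["pop"].to_numpy().copy()
    outsiders = labels == "pop4"
    labels[outsiders] = np.array(
        ["pop0", "pop1", "pop2", "pop3"] * 3
    )[: outsiders.sum()]
    res = loo_likelihood_assign(gm, labels)
    a = res.assignments
    assert a.loc[outsiders, "posterior"].mean() < a.loc[~outsiders, "posterior"].mean()


# ---------------------------------------------------------------------------
# Continuous grid assignment
# ---------------------------------------------------------------------------

def _grid():
    return GridSpec(-75.0, -45.0, -25.0, 5.0, 2.0)


def test_grid_posterior_sums_to_one(five_pop_sim):
    gm, meta, _ = five_pop_sim
    sub = gm.take_samples(range(10))
    res = continuous_grid_assign(
        sub, gm, meta[["lon", "lat"]].to_numpy(), _grid(), bandwidth_km=300
    )
    assert np.allclose(res.posterior.sum(axis=1), 1.0, atol=1e-9)


def test_grid_query_lands_near_its_cluster():
    model = PopulationModel(
        n_pops=2, fst_target=0.4, n_loci=300, seed=91,
        pop_coords=[(-70.0, -10.0), (-50.0, -10.0)],
    )
    gm, meta, _ = generate_structured_populations(model, 15)
    res = continuous_grid_assign(
        gm.take_samples([0]), gm, meta[["lon", "lat"]].to_numpy(),
        _grid(), bandwidth_km=300, loo=True,
    )
    a = res.assignments.iloc[0]
    # sample 0 belongs to the western population at lon -70
    assert abs(a["map_lon"] - (-70.0)) <= 4.0


def test_grid_flat_frequencies_give_flat_posterior():
    d = np.ones((6, 50), dtype=np.int8)  # every reference identical
    gm = make_matrix(d)
    coords = np.column_stack([np.linspace(-70, -50, 6), np.full(6, -10.0)])
    res = continuous_grid_assign(gm.take_samples([0]), gm, coords, _grid(), 500)
    post = res.posterior.iloc[0].to_numpy()
    assert post.max() / post.min() < 1.0001
    # MAP falls back to the posterior-mean coordinate
    cells = res.grid
    assert res.assignments.iloc[0]["map_lon"] == pytest.approx(
        float((post * cells[:, 0]).sum()), abs=1e-6
    )


def test_grid_cline_queries_recover_coarse_position():
    model = PopulationModel(
        n_pops=5, fst_target=0.05, n_loci=500, seed=92, cline_fraction=0.5,
        pop_coords=[(-72.0 + 6 * k, -10.0) for k in range(5)],
    )
    gm, meta, _ = generate_structured_populations(model, 10)
    west = np.where(meta["pop"] == "pop0")[0][:5]
    east = np.where(meta["pop"] == "pop4")[0][:5]
    res = continuous_grid_assign(
        gm.take_samples(np.concatenate([west, east])), gm,
        meta[["lon", "lat"]].to_numpy(), _grid(), bandwidth_km=300, loo=True,
    )
    a = res.assignments
    errs = np.abs(
        a["map_lon"].to_numpy()
        - meta.iloc[np.concatenate([west, east])]["lon"].to_numpy()
    )
    assert errs.mean() < (30.0 / 3.0)  # under a third of the domain width


def test_grid_small_bandwidth_approaches_nearest_sample():
    rng = np.random.default_rng(93)
    d = rng.integers(0, 3, size=(4, 80)).astype(np.int8)
    gm = make_matrix(d)
    coords = np.array([[-70, -10], [-60, -10], [-50, -10], [-46, -10]], float)
    grid = GridSpec(-71.0, -45.0, -11.0, -9.0, 1.0)
    res = continuous_grid_assign(
        gm.take_samples([2]), gm, coords, grid, bandwidth_km=60.0
    )
    a = res.assignments.iloc[0]
    assert abs(a["map_lon"] - (-50.0)) <= 1.0


def test_grid_validation_errors():
    gm = make_matrix(np.zeros((2, 5)))
    coords = np.zeros((2, 2))
    with pytest.raises(PanelforgeError):
        continuous_grid_assign(gm, gm, coords, _grid(), bandwidth_km=0)
    with pytest.raises(PanelforgeError):
        GridSpec(0, 1, 0, 1, 2.0).centers()  # fewer than 4 cells
    mask = np.zeros(15 * 15, dtype=bool)
    with pytest.raises(PanelforgeError):
        GridSpec(-75.0, -45.0, -25.0, 5.0, 2.0, mask=mask).centers()


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def test_report_arithmetic():
    from panelforge.assign import AssignmentResult

    assignments = pd.DataFrame(
        {
            "sample": ["q1", "q2"],
            "map_lon": [0.0, 0.0],
            "map_lat": [0.9, 5.4],
            "posterior": [0.9, 0.9],
        }
    )
    truth = pd.DataFrame(
        {"sample": ["q1", "q2"], "pop": ["a", "a"], "lon": [0.0, 0.0],
         "lat": [0.0, 0.0]}
    )
    res = AssignmentResult(posterior=pd.DataFrame(), assignments=assignments,
                           kind="grid")
    rep = assignment_report(res, truth, radius_km=500)
    overall = rep[rep["group"] == "overall"].iloc[0]
    # ~100 km and ~600 km errors: half within the 500 km radius
    assert overall["pct_within_radius"] == pytest.approx(50.0)
    assert overall["n"] == 2
    assert set(rep["group"]) == {"a", "overall"}


def test_report_requires_truth_rows():
    from panelforge.assign import AssignmentResult

    assignments = pd.DataFrame(
        {"sample": ["q1"], "map_label": ["a"], "posterior": [1.0]}
    )
    res = AssignmentResult(posterior=pd.DataFrame(), assignments=assignments)
    with pytest.raises(PanelforgeError):
        assignment_report(res, pd.DataFrame({"sample": ["zz"], "pop": ["a"]}))
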