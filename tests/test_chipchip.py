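"""Array normalization, moderated statistics, SVD classification, calling."""
import numpy as np
import pandas as pd
import pytest

from repeatbind import catalog, chipchip, simulate
from repeatbind.chipchip import (
    MTableError,
    PCAResult,
    build_mtable,
    call_occupancy,
    center_intensities,
    lowess_correct,
    lowess_fit,
    m_matrix,
    pca_classify,
    sam_differential,
)
from conftest import small_config


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_lowess(x, y, span=0.3, robust_iters=3):
    """Naive per-point weighted least squares with tricube/bisquare weights."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    robust = np.ones(n)
    fit = np.zeros(n)
    for pass_no in range(robust_iters + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            h = np.sort(d)[k - 1]
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3 if h > 0 else (d == 0).astype(float)
            w = w * robust
            design = np.column_stack([np.ones(n), x - x[i]])
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
            fit[i] = beta[0]
        if pass_no == robust_iters:
            break
        resid = y - fit
        s = np.median(np.abs(resid))
        if s <= 0:
            robust = (np.abs(resid) <= 1e-12).astype(float)
        else:
            robust = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return fit


def eig_pca_z(m_wide):
    """Z on the second component via eigendecomposition of the covariance."""
    x = m_wide.to_numpy(float)
    x = x - x.mean(axis=0, keepdims=True)
    cov = x.T @ x
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    v2 = vecs[:, order[1]]
    load = x @ v2
    z = load / load.std()
    a_cols = [j for j, c in enumerate(m_wide.columns) if c[0] == "A"]
    if v2[a_cols].mean() < 0:
        z = -z
    return z


# ---------------------------------------------------------------------------
# centering


def toy_raw():
    rows = []
    vals = {"T1": (8.0, 2.0), "T2": (3.0, 3.0), "C1": (2.0, 2.0), "C2": (4.0, 4.0)}
    for protein in ("A", "B"):
        for rep in (1, 2):
            for tid, (c1, c2) in vals.items():
                rows.append((tid, tid.startswith("C"), protein, rep, c1, c2))
    return pd.DataFrame(
        rows, columns=["tile_id", "is_control", "protein", "replicate", "ch1", "ch2"]
    )


class TestCentering:
    def test_control_mean_is_one_after_centering(self):
        out = center_intensities(toy_raw())
        ctrl = out[out["is_control"]]
        for _, sub in ctrl.groupby(["protein", "replicate"]):
            assert np.isclose(sub["ch1"].mean(), 1.0)
            assert np.isclose(sub["ch2"].mean(), 1.0)

    def test_global_array_multiplier_is_removed(self):
        raw = toy_raw()
        scaled = raw.copy()
        one_array = (scaled["protein"] == "A") & (scaled["replicate"] == 1)
        scaled.loc[one_array, ["ch1", "ch2"]] *= 7.0
        a = center_intensities(raw)
        b = center_intensities(scaled)
        assert np.allclose(a["ch1"], b["ch1"], atol=1e-12)
        assert np.allclose(a["ch2"], b["ch2"], atol=1e-12)

    def test_no_controls_is_an_error(self):
        raw = toy_raw()
        raw["is_control"] = False
        with pytest.raises(MTableError, match="control"):
            center_intensities(raw)


# ---------------------------------------------------------------------------
# lowess


class TestLowess:
    def test_constant_m_yields_zero(self, rng):
        a = rng.normal(size=500)
        m = np.full(500, 3.7)
        assert np.max(np.abs(lowess_correct(m, a))) < 1e-9

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=1000)
        y = np.sin(x) + 0.3 * rng.normal(size=1000)
        fit = lowess_fit(x, y, span=0.3, robust_iters=3)
        oracle = brute_force_lowess(x, y, span=0.3, robust_iters=3)
        assert np.max(np.abs(fit - oracle)) < 1e-9

    def test_noise_free_dye_bias_removal(self):
        # a linear dye bias is inside the local-linear smoother's function
        # class and is removed to machine precision; the default cubic is
        # removed to smoother-bias accuracy away from the sparse A extremes
        for dye, interior_tol in [((0.3, 0.0, 0.0), 1e-9), ((0.25, 0.08, -0.02), 0.1)]:
            cfg = small_config(seed=3)
            cfg.array = simulate.ArrayConfig(
                noise_log2_sd=0.0, dye_bias=dye, trend_log2_sd=0.0, channel_log2_sd=0.0
            )
            g = simulate.generate_repeat_genome(cfg)
            tiles = simulate.build_tiles(g)
            raw = simulate.simulate_array(g, tiles)
            mt = build_mtable(raw, pseudocount=0.0)
            err = np.abs(mt["M"].to_numpy() - np.log2(mt["fold_expect"].to_numpy()))
            a = mt["A"].to_numpy()
            lo, hi = np.percentile(a, [10, 90])
            assert err[(a >= lo) & (a <= hi)].max() < interior_tol

    def test_identical_a_values_rejected(self):
        with pytest.raises(MTableError, match="identical"):
            lowess_fit(np.ones(100), np.arange(100.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(MTableError):
            lowess_fit(np.arange(5.0), np.arange(5.0))


# ---------------------------------------------------------------------------
# moderated statistic


class TestSamDifferential:
    def test_identical_groups_give_zero_statistics(self, rng):
        a = rng.normal(size=(300, 3))
        res = sam_differential(a, a.copy(), n_permutations=20, rng=rng)
        assert np.all(res.d == 0)
        assert res.n_significant[res.delta_grid > 0].sum() == 0

    def test_group_swap_negates_every_d(self, rng):
        a = rng.normal(size=(200, 3))
        b = rng.normal(size=(200, 3)) + 0.5
        d_ab = sam_differential(a, b, n_permutations=10, rng=np.random.default_rng(0)).d
        d_ba = sam_differential(b, a, n_permutations=10, rng=np.random.default_rng(0)).d
        assert np.allclose(d_ab, -d_ba, atol=0)

    def test_planted_shift_detected_within_fdr_budget(self, rng):
        m_a, m_b, shifted = simulate.simulate_sam_matrix(
            rng, n_tiles=2000, frac_shifted=0.1, effect_sd=4.0
        )
        res = sam_differential(m_a, m_b, n_permutations=50, rng=rng)
        delta = res.threshold_for_fdr(0.25)
        sig = res.significant(delta)
        assert sig[shifted].mean() >= 0.9

    def test_too_few_permutations_rejected(self, rng):
        a = rng.normal(size=(50, 2))
        with pytest.raises(MTableError):
            sam_differential(a, a, n_permutations=5)


# ---------------------------------------------------------------------------
# SVD classification


class TestPcaClassify:
    def wide(self, arr, proteins=("A", "A", "B", "B"), reps=(1, 2, 1, 2)):
        cols = pd.MultiIndex.from_arrays([proteins, reps])
        return pd.DataFrame(arr, index=[f"t{i}" for i in range(arr.shape[0])], columns=cols)

    def test_duplicated_identical_arrays_give_zero_z(self, rng):
        x = rng.normal(size=100)
        m = self.wide(np.column_stack([x, x, x, x]))
        res = pca_classify(m)
        assert res.variance_fractions[1] < 1e-12
        assert np.all(res.z == 0)

    def test_z_scores_are_standardised(self, rng):
        m = self.wide(rng.normal(size=(400, 4)))
        res = pca_classify(m)
        assert abs(res.z.mean()) < 1e-9
        assert abs(res.z.std(ddof=0) - 1) < 1e-9

    def test_matches_covariance_eigendecomposition(self, rng):
        m = self.wide(rng.normal(size=(300, 4)) + [0.0, 0.1, 0.9, 1.0])
        res = pca_classify(m)
        assert np.max(np.abs(res.z.to_numpy() - eig_pca_z(m))) < 1e-9

    def test_sign_convention_puts_protein_a_positive(self, small_genome, small_tiles):
        raw = simulate.simulate_array(small_genome, small_tiles)
        mt = build_mtable(raw)
        res = pca_classify(m_matrix(mt))
        truth = small_genome.truth.repeat_classes
        tmap = catalog.tile_map_frame(small_tiles)
        by_tile = dict(zip(tmap["tile_id"], tmap["repeat_id"]))
        z_a = [res.z[t] for t in res.z.index if truth.get(by_tile.get(t)) == "A_ONLY"]
        z_b = [res.z[t] for t in res.z.index if truth.get(by_tile.get(t)) == "B_ONLY"]
        assert min(z_a) > 0 and max(z_b) < 0


# ---------------------------------------------------------------------------
# occupancy calling


def mtable_from_folds(folds_by_repeat):
    """folds_by_repeat: repeat -> (folds_a, folds_b); one tile per repeat."""
    rows = []
    for rid, (fa, fb) in folds_by_repeat.items():
        for protein, folds in (("A", fa), ("B", fb)):
            for rep, f in enumerate(folds, start=1):
                rows.append((f"{rid}|t0", False, protein, rep, np.log2(f), f))
    mt = pd.DataFrame(
        rows, columns=["tile_id", "is_control", "protein", "replicate", "M", "fold"]
    )
    tmap = pd.DataFrame(
        {
            "tile_id": [f"{r}|t0" for r in folds_by_repeat],
            "repeat_id": list(folds_by_repeat),
            "offset": 0,
            "is_control": False,
        }
    )
    return mt, tmap


def fake_pca(z_by_tile):
    z = pd.Series(z_by_tile, name="Z")
    return PCAResult(
        variance_fractions=np.array([0.8, 0.2]),
        array_scores=pd.DataFrame(),
        loadings=pd.DataFrame(),
        z=z,
    )


class TestCallOccupancy:
    @pytest.mark.parametrize(
        "fa, fb, z, expected",
        [
            # fourfold enrichment for both proteins in every replicate
            ((5, 6, 4.2), (4.8, 5, 4.1), 0.0, "CO_BOUND"),
            # fourfold for one protein, no enrichment for the other, high Z
            ((5, 5, 5), (1.0, 0.9, 0.8), 6.0, "A_ONLY"),
            ((1.0, 0.9, 0.8), (5, 5, 5), -6.0, "B_ONLY"),
            # one failing replicate breaks the all-replicates conjunction
            ((5, 5, 3.9), (0.5, 0.5, 0.5), 6.0, "UNCLASSIFIED"),
            # Z criterion is required for the single-protein classes
            ((5, 5, 5), (1.0, 0.9, 0.8), 3.0, "UNCLASSIFIED"),
            # slight enrichment of the other protein disqualifies
            ((5, 5, 5), (1.2, 0.9, 0.8), 6.0, "UNCLASSIFIED"),
        ],
    )
    def test_threshold_rules(self, fa, fb, z, expected):
        mt, tmap = mtable_from_folds({"R": (fa, fb)})
        calls = call_occupancy(mt, fake_pca({"R|t0": z}), tmap)
        assert calls[0].occupancy_class == expected

    def test_repeat_takes_best_supported_tile_class(self):
        mt, tmap = mtable_from_folds(
            {"R1": ((5, 5, 5), (5, 5, 5)), "R2": ((5, 5, 5), (0.5, 0.5, 0.5))}
        )
        # merge both tiles under one repeat
        tmap["repeat_id"] = "R"
        calls = call_occupancy(mt, fake_pca({"R1|t0": 0.0, "R2|t0": 6.0}), tmap)
        assert len(calls) == 1
        assert calls[0].occupancy_class == "CO_BOUND"  # co-binding outranks single

    def test_protein_swap_maps_single_classes(self, small_genome, small_tiles):
        raw = simulate.simulate_array(small_genome, small_tiles)
        tmap = catalog.tile_map_frame(small_tiles)

        def run(table):
            mt = build_mtable(table)
            pca = pca_classify(m_matrix(mt))
            return {c.repeat_id: c.occupancy_class for c in call_occupancy(mt, pca, tmap)}

        swapped = raw.copy()
        swapped["protein"] = swapped["protein"].map({"A": "B", "B": "A"})
        direct = run(raw)
        mirror = run(swapped)
        swap = {"A_ONLY": "B_ONLY", "B_ONLY": "A_ONLY"}
        for rid, cls in direct.items():
            assert mirror[rid] == swap.get(cls, cls)

    def test_unbalanced_replicates_rejected(self):
        mt, tmap = mtable_from_folds({"R": ((5, 5, 5), (5, 5, 5))})
        mt = mt[~((mt["protein"] == "B") & (mt["replicate"] == 3))]
        with pytest.raises(MTableError, match="replicate"):
            call_occupancy(mt, fake_pca({"R|t0": 0.0}), tmap)
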