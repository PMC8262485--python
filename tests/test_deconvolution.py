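"""NNLS spot deconvolution against simplex grid-search oracles."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from stcoloc.deconvolution import (
    deconvolve,
    dominant_labels,
    signature_fraction_by_region,
    spot_composition_report,
)
from stcoloc.io import Circle, RegionMask
from stcoloc.study import proportion_mae, run_replicate
from stcoloc.simulate import SimulationConfig


def _signature(profiles: dict[str, np.ndarray], genes=None) -> pd.DataFrame:
    mat = np.vstack(list(profiles.values()))
    genes = genes or [f"g{i}" for i in range(mat.shape[1])]
    return pd.DataFrame(np.log1p(mat), index=list(profiles.keys()), columns=genes)


def _spots(linear_rows: np.ndarray, genes=None) -> ad.AnnData:
    linear_rows = np.atleast_2d(linear_rows)
    genes = genes or [f"g{i}" for i in range(linear_rows.shape[1])]
    adata = ad.AnnData(X=np.log1p(linear_rows.astype(float)))
    adata.obs_names = [f"s{i}" for i in range(linear_rows.shape[0])]
    adata.var_names = genes
    return adata


def simplex_grid_oracle(S: np.ndarray, y: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Exhaustive search over the weight simplex at a fixed resolution."""
    k = S.shape[0]
    best, best_err = None, np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for combo in itertools.product(ticks, repeat=k - 1):
        last = 1.0 - sum(combo)
        if last < -1e-9:
            continue
        w = np.array(list(combo) + [max(last, 0.0)])
        err = np.linalg.norm(w @ S - y)
        if err < best_err:
            best, best_err = w, err
    return best


class TestDeconvolve:
    def test_pure_spot_is_one_hot(self, rng):
        profiles = {
            "A": np.array([100.0, 0, 0, 50]),
            "B": np.array([0, 80.0, 20, 0]),
        }
        sig = _signature(profiles)
        result = deconvolve(_spots(profiles["B"]), sig)
        np.testing.assert_allclose(result.scores.loc["s0"], [0.0, 1.0], atol=1e-9)

    def test_known_mixture_disjoint_supports(self):
        profiles = {
            "A": np.array([100.0, 50, 0, 0]),
            "B": np.array([0, 0, 80.0, 40]),
        }
        sig = _signature(profiles)
        y = 0.3 * profiles["A"] + 0.7 * profiles["B"]
        result = deconvolve(_spots(y), sig)
        np.testing.assert_allclose(result.scores.loc["s0"], [0.3, 0.7], atol=1e-6)
        S = np.vstack(list(profiles.values()))
        oracle = simplex_grid_oracle(S, y)
        np.testing.assert_allclose(result.scores.loc["s0"], oracle, atol=0.01)

    @pytest.mark.parametrize("seed", range(4))
    def test_three_cluster_noise_free_recovery(self, seed):
        rng = np.random.default_rng(seed)
        profiles = {}
        for i, name in enumerate("ABC"):
            p = np.zeros(12)
            p[i * 4 : (i + 1) * 4] = rng.uniform(20, 120, size=4)
            profiles[name] = p
        S = np.vstack(list(profiles.values()))
        w_true = rng.dirichlet([1, 1, 1])
        y = w_true @ S
        result = deconvolve(_spots(y), _signature(profiles))
        np.testing.assert_allclose(result.scores.loc["s0"], w_true, atol=1e-6)
        oracle = simplex_grid_oracle(S, y)
        np.testing.assert_allclose(oracle, w_true, atol=0.01)

    def test_all_zero_spot_unassigned(self):
        profiles = {"A": np.array([10.0, 5]), "B": np.array([0.0, 8])}
        result = deconvolve(_spots(np.zeros(2)), _signature(profiles))
        assert not result.assigned.loc["s0"]
        np.testing.assert_array_equal(result.scores.loc["s0"], [0.0, 0.0])

    def test_gene_reordering_invariance(self, rng):
        profiles = {"A": rng.uniform(0, 50, 8), "B": rng.uniform(0, 50, 8)}
        sig = _signature(profiles)
        y = 0.4 * profiles["A"] + 0.6 * profiles["B"]
        base = deconvolve(_spots(y), sig)
        perm = rng.permutation(8)
        genes = [f"g{i}" for i in range(8)]
        sig_perm = sig[[genes[i] for i in perm]]
        shuffled = deconvolve(_spots(y[perm], genes=[genes[i] for i in perm]), sig_perm)
        pd.testing.assert_frame_equal(base.scores, shuffled.scores)

    def test_empty_shared_gene_set_raises(self):
        sig = _signature({"A": np.array([1.0, 2]), "B": np.array([3.0, 1])})
        spots = _spots(np.array([1.0, 2]), genes=["x1", "x2"])
        with pytest.raises(ValueError):
            deconvolve(spots, sig)

    def test_identical_signature_rows_warn(self):
        p = np.array([10.0, 20, 5])
        with pytest.warns(UserWarning):
            deconvolve(_spots(p), _signature({"A": p, "B": p}))

    def test_noisy_synthetic_mean_error_below_5pct(self):
        # 500-spot sample at the default study conditions
        cfg = SimulationConfig(seed=42, grid_rows=23, grid_cols=22)
        rep = run_replicate(cfg)
        assert rep.truth.spot_proportions.shape[0] == 506
        assert proportion_mae(rep) < 0.05


class TestDominantLabels:
    def test_one_hot_and_tie_break(self, scores_factory):
        scores = scores_factory(
            {
                "s1": {"A": 0.0, "B": 1.0},
                "s2": {"A": 0.5, "B": 0.5},
            }
        )
        out = dominant_labels(scores).set_index("barcode")
        assert out.loc["s1", "dominant"] == "B"
        assert out.loc["s2", "dominant"] == "A"  # alphabetical tie-break

    def test_unassigned_label(self, scores_factory):
        scores = scores_factory({"s1": {"A": 0.0, "B": 0.0}})
        out = dominant_labels(scores).set_index("barcode")
        assert out.loc["s1", "dominant"] == "unassigned"
        assert out.loc["s1", "dominant_score"] == 0.0

    def test_recovers_truth_in_easy_regime(self):
        # concentrated compositions: the dominant label matches the true
        # argmax proportion for the vast majority of spots
        import dataclasses

        base = SimulationConfig()
        # small symmetric concentrations give near-pure spots
        alpha = {k: 0.25 for k in base.rest_alpha}
        cfg = SimulationConfig(
            seed=6,
            grid_rows=16,
            grid_cols=16,
            regions=(),
            rest_alpha=alpha,
            coloc=dataclasses.replace(base.coloc, fraction=0.0),
            low_region=dataclasses.replace(base.low_region, scale=1.0, injury_fold=1.0),
        )
        rep = run_replicate(cfg)
        truth = rep.truth.spot_proportions.idxmax(axis=1)
        est = rep.dominant.set_index("barcode")["dominant"].loc[truth.index]
        assert (est == truth).mean() >= 0.90


class TestRegionFractions:
    @staticmethod
    def _mask(region_id, spots):
        return RegionMask(region_id, Circle(0, 0, 1), list(spots))

    def test_hand_computed_example(self, scores_factory):
        scores = scores_factory(
            {
                "a1": {"K": 0.2, "L": 0.8},
                "a2": {"K": 0.4, "L": 0.6},
                "b1": {"K": 0.1, "L": 0.9},
                "b2": {"K": 0.0, "L": 1.0},
            }
        )
        out = signature_fraction_by_region(
            scores, self._mask("A", ["a1", "a2"]), self._mask("B", ["b1", "b2"])
        ).set_index("cluster")
        assert out.loc["K", "norm_sum_a"] == pytest.approx(0.3)
        assert out.loc["K", "norm_sum_b"] == pytest.approx(0.05)
        assert out.loc["K", "fraction_a"] == pytest.approx(6 / 7)
        assert out.loc["K", "fraction_b"] == pytest.approx(1 / 7)

    def test_cluster_confined_to_one_region(self, scores_factory):
        scores = scores_factory(
            {"a1": {"K": 1.0, "L": 0.0}, "b1": {"K": 0.0, "L": 1.0}}
        )
        out = signature_fraction_by_region(
            scores, self._mask("A", ["a1"]), self._mask("B", ["b1"])
        ).set_index("cluster")
        assert out.loc["K", "fraction_a"] == pytest.approx(1.0)
        assert out.loc["K", "fraction_b"] == pytest.approx(0.0)

    def test_equal_means_split_evenly_despite_size_imbalance(self, scores_factory):
        scores = scores_factory(
            {
                "a1": {"K": 0.3, "L": 0.7},
                "a2": {"K": 0.3, "L": 0.7},
                "a3": {"K": 0.3, "L": 0.7},
                "b1": {"K": 0.3, "L": 0.7},
            }
        )
        out = signature_fraction_by_region(
            scores, self._mask("A", ["a1", "a2", "a3"]), self._mask("B", ["b1"])
        ).set_index("cluster")
        assert out.loc["K", "fraction_a"] == pytest.approx(0.5)

    def test_overlapping_regions_rejected(self, scores_factory):
        scores = scores_factory({"s1": {"K": 1.0}})
        with pytest.raises(ValueError):
            signature_fraction_by_region(
                scores, self._mask("A", ["s1"]), self._mask("B", ["s1"])
            )


class TestCompositionReport:
    def test_threshold_filters_minor_contributors(self, scores_factory):
        scores = scores_factory({"s1": {"A": 0.85, "B": 0.09, "C": 0.06}})
        out = spot_composition_report(scores)
        assert out["cluster"].tolist() == ["A"]

    def test_even_split_keeps_both(self, scores_factory):
        scores = scores_factory({"s1": {"A": 0.5, "B": 0.5}})
        assert len(spot_composition_report(scores)) == 2

    def test_zero_threshold_keeps_all_nonzero(self, scores_factory):
        scores = scores_factory({"s1": {"A": 0.85, "B": 0.15, "C": 0.0}})
        out = spot_composition_report(scores, min_display=0.0)
        assert set(out["cluster"]) == {"A", "B"}
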