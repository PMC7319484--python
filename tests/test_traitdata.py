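"""Selection criteria, cleaning, community means, gridding, VIF pruning."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

import traitscape as ts
from traitscape.traitdata import (
    UnresolvableCollinearityError,
    _vif_one,
)


def obs_row(**kw):
    base = {
        "study_id": "s1", "site_id": "p1", "lon": 10.0, "lat": 45.0,
        "species": "sp1", "trait": "height", "value": 2.0, "unit": "m",
        "year": 2000, "is_direct_measurement": True,
        "sampling_strategy": "all_or_dominant", "life_stage": "adult_or_all",
        "natural_vegetation": True, "abundance": np.nan,
    }
    base.update(kw)
    return base


class TestSelectionCriteria:
    def test_each_removal_attributed_to_first_failing_criterion(self):
        rows = [
            obs_row(lon=np.nan),                       # c1
            obs_row(lat=np.nan),                       # c1
            obs_row(is_direct_measurement=False),      # c2 (species average)
            obs_row(natural_vegetation=False),         # c3 (plantation)
            obs_row(sampling_strategy="partial"),      # c4
            obs_row(sampling_strategy="partial"),      # c4
            obs_row(life_stage="juvenile_only"),       # c5
            obs_row(year=1975),                        # c6
            obs_row(), obs_row(), obs_row(), obs_row(),  # clean
        ]
        kept, report = ts.apply_selection_criteria(pd.DataFrame(rows))
        assert len(kept) == 4
        assert report.removed == {
            "c1_georeferenced": 2, "c2_direct_measurement": 1,
            "c3_natural_vegetation": 1, "c4_sampling_strategy": 2,
            "c5_life_stage": 1, "c6_year": 1,
        }
        assert report.uncheckable == 0
        assert report.check_conservation()

    def test_all_valid_is_identity(self):
        df = pd.DataFrame([obs_row() for _ in range(5)])
        kept, report = ts.apply_selection_criteria(df)
        assert len(kept) == 5
        assert sum(report.removed.values()) == 0
        assert report.uncheckable == 0

    @pytest.mark.parametrize("column,value", [
        ("sampling_strategy", "unknown"),
        ("life_stage", "unknown"),
        ("natural_vegetation", np.nan),
        ("year", np.nan),
    ])
    def test_unknown_flags_are_uncheckable(self, column, value):
        df = pd.DataFrame([obs_row(**{column: value}), obs_row()])
        kept, report = ts.apply_selection_criteria(df)
        assert len(kept) == 1
        assert report.uncheckable == 1
        assert sum(report.removed.values()) == 0

    def test_failure_beats_uncheckable_in_attribution(self):
        # row both lacks coordinates (c1) and has an unknown flag
        df = pd.DataFrame([obs_row(lon=np.nan, sampling_strategy="unknown")])
        with pytest.warns(UserWarning, match="no observations"):
            _, report = ts.apply_selection_criteria(df)
        assert report.removed["c1_georeferenced"] == 1
        assert report.uncheckable == 0


class TestCleaning:
    def test_exact_duplicates_collapse_to_one(self):
        df = pd.DataFrame([obs_row(), obs_row(), obs_row(value=3.0)])
        clean, log = ts.clean_observations(df)
        assert len(clean) == 2
        assert (log["reason"] == "duplicate").sum() == 1

    def test_globally_implausible_value_removed(self):
        df = pd.DataFrame([obs_row(value=5000.0), obs_row()])
        clean, log = ts.clean_observations(df)
        assert len(clean) == 1
        assert log.iloc[0]["reason"] == "global_bounds"

    def test_species_log_sd_outlier_removed(self):
        # 19 identical values and one offset: with n = 20 the outlier sits
        # ~4.25 sample SDs from the species mean whatever the offset, so it
        # is the single removal at k = 4
        rows = [obs_row(site_id=f"p{i}", value=np.e) for i in range(19)]
        rows.append(obs_row(site_id="p19", value=float(np.exp(4))))
        clean, log = ts.clean_observations(pd.DataFrame(rows))
        assert len(clean) == 19
        assert (log["reason"] == "species_log_sd").sum() == 1
        assert clean["value"].max() < 3


class TestCommunityMean:
    def test_species_first_averaging(self):
        rows = [
            obs_row(species="A", value=2.0, site_id="q"),
            obs_row(species="A", value=4.0, site_id="q"),
            obs_row(species="B", value=9.0, site_id="q"),
        ]
        cm = ts.community_mean(pd.DataFrame(rows))
        assert cm["value"].iloc[0] == pytest.approx(6.0)  # not (2+4+9)/3 = 5
        assert cm["n_species"].iloc[0] == 2
        assert cm["n_observations"].iloc[0] == 3

    def test_abundances_ignored(self):
        rows = [
            obs_row(species="A", value=2.0, abundance=100.0),
            obs_row(species="A", value=4.0, abundance=100.0),
            obs_row(species="B", value=9.0, abundance=1.0),
        ]
        cm = ts.community_mean(pd.DataFrame(rows))
        assert cm["value"].iloc[0] == pytest.approx(6.0)

    def test_single_observation(self):
        cm = ts.community_mean(pd.DataFrame([obs_row(value=7.5)]))
        assert cm["value"].iloc[0] == 7.5

    def test_invariant_to_duplicating_equal_valued_observation(self):
        rows = [obs_row(species="A", value=3.0), obs_row(species="B", value=5.0)]
        base = ts.community_mean(pd.DataFrame(rows))["value"].iloc[0]
        dup = rows + [dict(rows[0], site_id="p1")] * 4
        again = ts.community_mean(pd.DataFrame(dup))["value"].iloc[0]
        assert again == pytest.approx(base)


class TestGridAggregate:
    def test_half_degree_cell_indexing(self):
        cm = pd.DataFrame([dict(obs_row(lon=10.2, lat=45.3), value=1.0)])
        rec = ts.grid_aggregate(cm, ts.GridSpec())
        assert (rec["col"].iloc[0], rec["row"].iloc[0]) == (380, 270)

    def test_cell_mean_and_count(self):
        rows = [dict(obs_row(lon=10.1, lat=45.1, study_id="a"), value=4.0),
                dict(obs_row(lon=10.4, lat=45.4, study_id="b"), value=8.0)]
        rec = ts.grid_aggregate(pd.DataFrame(rows), ts.GridSpec())
        assert len(rec) == 1
        assert rec["value"].iloc[0] == pytest.approx(6.0)
        assert rec["n_communities"].iloc[0] == 2

    def test_shared_edge_belongs_to_upper_cell_only(self):
        cm = pd.DataFrame([dict(obs_row(lon=10.0, lat=45.0), value=1.0)])
        rec = ts.grid_aggregate(cm, ts.GridSpec())
        # (10.0+180)/0.5 = 380: the cell whose lower edge is exactly 10.0
        assert (rec["col"].iloc[0], rec["row"].iloc[0]) == (380, 270)
        assert len(rec) == 1

    def test_idempotent_on_single_record_cells(self):
        rows = [dict(obs_row(lon=lon, lat=45.1), value=v)
                for lon, v in [(10.1, 4.0), (11.1, 8.0), (12.1, 5.0)]]
        rec1 = ts.grid_aggregate(pd.DataFrame(rows), ts.GridSpec())
        again = rec1.rename(columns={})[["lon", "lat", "value"]].copy()
        again["study_id"] = "x"
        again["site_id"] = [f"s{i}" for i in range(len(again))]
        again["trait"] = rec1["trait"] if "trait" in rec1 else "height"
        rec2 = ts.grid_aggregate(again, ts.GridSpec())
        np.testing.assert_allclose(rec2["value"], rec1["value"])


class TestLinkEnv:
    def test_complete_cells_linked_and_conserved(self, small_world):
        stack, _, obs, _ = small_world
        cm = ts.community_mean(obs)
        rec = ts.grid_aggregate(cm, stack.grid)
        features, n_excl = ts.link_env(rec, stack)
        assert n_excl == 0
        assert len(features) == len(rec)
        assert not features[list(ts.PREDICTORS)].isna().any().any()

    def test_missing_predictor_excludes_and_counts(self, small_world):
        stack, _, obs, _ = small_world
        cm = ts.community_mean(obs)
        rec = ts.grid_aggregate(cm, stack.grid)
        holed = ts.PredictorStack(
            grid=stack.grid,
            layers={k: v.copy() for k, v in stack.layers.items()},
            mask=stack.mask.copy(),
        )
        r0, c0 = int(rec["row"].iloc[0]), int(rec["col"].iloc[0])
        holed.layers["ph"][r0, c0] = np.nan
        features, n_excl = ts.link_env(rec, holed)
        affected = int(((rec["row"] == r0) & (rec["col"] == c0)).sum())
        assert n_excl == affected > 0
        assert len(features) == len(rec) - affected


class TestVIF:
    @staticmethod
    def orthogonal_columns(n, k, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((n, k))
        a -= a.mean(axis=0)
        q, r = np.linalg.qr(a)
        return q * np.sign(np.diag(r))

    def test_orthogonal_predictors_all_retained_with_unit_vif(self):
        q = self.orthogonal_columns(200, 6, seed=0)
        df = pd.DataFrame(q, columns=list(ts.PREDICTORS))
        selected, trace = ts.vif_select(df)
        assert selected == list(ts.PREDICTORS)
        assert all(abs(v - 1.0) < 1e-10 for v in trace[-1]["vifs"].values())

    def test_r09_pair_yields_vif_526_and_one_drop(self):
        q = self.orthogonal_columns(200, 7, seed=1)
        cols = {p: q[:, j] for j, p in enumerate(ts.PREDICTORS)}
        # tmin-humind with sample correlation exactly 0.9, rest orthogonal
        cols["humind"] = 0.9 * cols["tmin"] + np.sqrt(1 - 0.81) * q[:, 6]
        df = pd.DataFrame(cols)
        selected, trace = ts.vif_select(df, threshold=4.0)
        first = trace[0]["vifs"]
        assert first["tmin"] == pytest.approx(1.0 / (1.0 - 0.81), rel=1e-6)
        assert trace[0]["dropped"] in ("tmin", "humind")
        assert len(selected) == 5

    def test_duplicated_column_dropped_first(self):
        q = self.orthogonal_columns(100, 6, seed=3)
        df = pd.DataFrame(q, columns=list(ts.PREDICTORS))
        df["humind"] = df["tmin"]  # exact duplicate
        selected, trace = ts.vif_select(df)
        assert trace[0]["dropped"] in ("tmin", "humind")
        assert len(selected) == 5

    def test_last_protected_group_member_never_dropped(self):
        q = self.orthogonal_columns(150, 4, seed=4)
        noise = 0.05 * q[:, 3]
        df = pd.DataFrame({
            "tmin": q[:, 0], "humind": q[:, 1],
            "cec": q[:, 0] * np.sqrt(1 - 0.0025) + noise,  # collinear w/ tmin
        })
        selected, trace = ts.vif_select(
            df, threshold=4.0,
            protected_groups={"climate": {"tmin", "humind"}, "soil": {"cec"}},
        )
        assert "cec" in selected       # last soil member is protected
        assert "tmin" not in selected  # the climate twin is dropped instead

    def test_vif_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((120, 5))
        X[:, 1] += 0.7 * X[:, 0]
        X[:, 4] += 0.4 * X[:, 2] - 0.3 * X[:, 3]
        design = np.column_stack([np.ones(len(X)), X])
        for j in range(5):
            mine = _vif_one(X, j)
            oracle = variance_inflation_factor(design, j + 1)
            assert mine == pytest.approx(oracle, rel=1e-8)

    def test_too_few_predictors_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((20, 2)),
                          columns=["tmin", "ph"])
        with pytest.raises(ValueError):
            ts.vif_select(df)
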