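"""Unit and property tests for plate normalization, Z-scoring and hit calling."""

import io
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slscreen.screen import (
    PlateGeometry,
    call_hits,
    compute_zscores,
    flag_position_effects,
    normalize_plate,
    read_screen_table,
    replicate_correlation,
)
from conftest import make_dataset


# ---------------------------------------------------------------------- I/O

SCREEN_CSV = """plate,well,reagent,role,genotype,replicate,readout
P1,A01,g1,library,WT,1,100
P1,A02,g2,library,WT,1,110
P1,A03,g3,library,WT,1,90
P1,A04,neg,negative_control,WT,1,105
"""


class TestReadScreenTable:
    def test_parses_toy_file(self):
        ds = read_screen_table(io.StringIO(SCREEN_CSV))
        assert len(ds.wells) == 4
        assert ds.wells["plate"].nunique() == 1
        assert list(ds.wells["col"]) == [1, 2, 3, 4]
        assert list(ds.wells["row"]) == [1, 1, 1, 1]

    def test_duplicate_well_rejected(self):
        bad = SCREEN_CSV + "P1,A01,g9,library,WT,1,50\n"
        with pytest.raises(ValueError, match="duplicate well"):
            read_screen_table(io.StringIO(bad))

    def test_row_out_of_range(self):
        bad = SCREEN_CSV + "P1,Q01,g9,library,WT,1,50\n"
        with pytest.raises(ValueError, match="row out of range"):
            read_screen_table(io.StringIO(bad))

    def test_unknown_role_rejected(self):
        bad = SCREEN_CSV.replace("negative_control", "mystery")
        with pytest.raises(ValueError, match="unknown well role"):
            read_screen_table(io.StringIO(bad))

    def test_negative_readout_rejected(self):
        bad = SCREEN_CSV.replace("A04,neg,negative_control,WT,1,105", "A04,neg,negative_control,WT,1,-3")
        with pytest.raises(ValueError, match="negative readout"):
            read_screen_table(io.StringIO(bad))


# -------------------------------------------------------------- normalization

def normalize_oracle(values, mask, n_iter=100):
    """Naive loop re-implementation of alternating median division."""
    values = np.array(values, dtype=float)
    for _ in range(n_iter):
        for i in range(values.shape[0]):
            lib = [values[i, j] for j in range(values.shape[1]) if mask[i, j]]
            if len(lib) >= 2:
                values[i, :] = values[i, :] / np.median(lib)
        for j in range(values.shape[1]):
            lib = [values[i, j] for i in range(values.shape[0]) if mask[i, j]]
            if len(lib) >= 2:
                values[:, j] = values[:, j] / np.median(lib)
    return values


class TestNormalizePlate:
    def test_constant_plate_converges_immediately(self):
        norm, info = normalize_plate(np.full((4, 6), 7.3))
        assert np.allclose(norm, 1.0)
        assert info.converged and info.iterations == 1

    def test_rank_one_bias_removed_exactly(self):
        r = np.arange(1, 5, dtype=float)
        c = np.arange(1, 12, 3, dtype=float)
        norm, info = normalize_plate(np.outer(r, c))
        assert np.allclose(norm, 1.0, atol=1e-12)
        assert info.converged

    def test_matches_bruteforce_oracle_on_noisy_plate(self, rng):
        r = rng.uniform(0.5, 2.0, 4)
        c = rng.uniform(0.5, 2.0, 4)
        plate = np.outer(r, c) * rng.lognormal(0, 0.2, (4, 4))
        mask = np.ones((4, 4), dtype=bool)
        # tol=0 disables early convergence so both run the same 100 passes
        norm, _ = normalize_plate(plate, mask, tol=0, max_iter=100)
        oracle = normalize_oracle(plate, mask)
        assert np.max(np.abs(norm - oracle)) < 1e-9

    def test_idempotent(self, rng):
        # median polish can need more than the default passes on random
        # plates; once converged, a re-run must be a no-op within tol
        plate = rng.lognormal(0, 0.3, (8, 12))
        once, info = normalize_plate(plate, max_iter=200)
        assert info.converged
        twice, _ = normalize_plate(once, max_iter=200)
        assert np.max(np.abs(twice - once)) <= 1e-6

    def test_controls_divided_but_excluded_from_medians(self):
        # one control column at 1000x: must not disturb library medians
        plate = np.ones((4, 4))
        plate[:, 3] = 1000.0
        mask = np.ones((4, 4), dtype=bool)
        mask[:, 3] = False
        norm, _ = normalize_plate(plate, mask)
        assert np.allclose(norm[:, :3], 1.0)
        assert np.allclose(norm[:, 3], 1000.0)

    def test_zero_median_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate plate"):
            normalize_plate(np.zeros((4, 4)))

    def test_sparse_row_skipped_with_warning(self):
        plate = np.ones((4, 4))
        mask = np.ones((4, 4), dtype=bool)
        mask[0, :] = [True, False, False, False]  # one library well in row 0
        with pytest.warns(UserWarning, match="skipped"):
            norm, _ = normalize_plate(plate, mask)
        assert np.allclose(norm[mask], 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        g=st.floats(0.1, 10),
        seed=st.integers(0, 2**16),
    )
    def test_any_multiplicative_plate_maps_to_ones(self, g, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(0.2, 5.0, 6)
        c = rng.uniform(0.2, 5.0, 8)
        norm, _ = normalize_plate(g * np.outer(r, c))
        assert np.allclose(norm, 1.0, atol=1e-9)


# ------------------------------------------------------------------ Z-scores

class TestComputeZScores:
    def test_library_z_standardized(self, rng):
        ds = make_dataset({("WT", 1): rng.lognormal(0, 0.2, (6, 6))})
        z = compute_zscores(ds)
        vals = z[("WT", 1)].to_numpy()
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std(ddof=1) - 1.0) < 1e-9

    def test_hand_computed_example(self):
        # replicate values 1..5: sample SD 1.5811, so value 5 has Z = 1.2649
        mat = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        ds = make_dataset({("WT", 1): mat}, geometry=PlateGeometry(1, 5))
        z = compute_zscores(ds)
        assert z.loc["g_1_5", ("WT", 1)] == pytest.approx(1.2649, abs=1e-4)
        assert z.loc["g_1_3", ("WT", 1)] == pytest.approx(0.0, abs=1e-12)

    def test_controls_scored_but_excluded_from_fit(self):
        mat = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 100.0]])
        roles = [["library"] * 5 + ["positive_control"]]
        ds = make_dataset({("WT", 1): mat}, geometry=PlateGeometry(1, 6), roles=roles)
        z = compute_zscores(ds)
        lib = z[z["role"] == "library"][("WT", 1)]
        assert abs(lib.mean()) < 1e-9  # fit unaffected by the control
        ctrl = z[z["role"] == "positive_control"][("WT", 1)]
        assert ctrl.iloc[0] == pytest.approx((100 - 3) / np.std([1, 2, 3, 4, 5], ddof=1), rel=1e-12)

    def test_degenerate_replicate(self):
        ds = make_dataset({("WT", 1): np.full((3, 3), 5.0)})
        with pytest.raises(ValueError, match="degenerate replicate"):
            compute_zscores(ds)


# ---------------------------------------------------------------- hit calling

def _ztable(zko, zwt):
    """Build a one-reagent Z table from per-replicate KO and WT scores."""
    cols = pd.MultiIndex.from_tuples(
        [("KO", i + 1) for i in range(len(zko))] + [("WT", i + 1) for i in range(len(zwt))]
    )
    df = pd.DataFrame([list(zko) + list(zwt)], index=["gX"], columns=cols)
    df.insert(0, "role", "library")
    return df


def hits_oracle(zko, zwt, threshold=-1.5, min_fraction=2 / 3, rule="replicate_fraction"):
    """Exhaustive per-reagent enumeration of the differential-lethality rule."""
    zko, zwt = np.asarray(zko, float), np.asarray(zwt, float)
    ko_ok, wt_ok = ~np.isnan(zko), ~np.isnan(zwt)
    if ko_ok.sum() < 2 or wt_ok.sum() < 2:
        return False
    if rule == "median_z":
        return np.nanmedian(zko) < threshold and np.nanmedian(zwt) >= threshold
    ko_frac = (zko[ko_ok] < threshold).sum() / ko_ok.sum()
    wt_frac = (zwt[wt_ok] >= threshold).sum() / wt_ok.sum()
    return ko_frac >= min_fraction and wt_frac >= min_fraction


class TestCallHits:
    def test_two_of_three_rule_example(self):
        hits = call_hits(_ztable([-2.0, -1.8, -0.3], [-0.2, 0.1, -1.6]))
        assert bool(hits.loc["gX", "is_hit"])

    def test_all_zero_not_a_hit(self):
        hits = call_hits(_ztable([0.0, 0.0, 0.0], [0.0, 0.0, 0.0]))
        assert not bool(hits.loc["gX", "is_hit"])

    def test_boundary_ties_count_as_wt_pass_ko_fail(self):
        # Z exactly at the threshold: "below" is strict, "above" is >=
        hits = call_hits(_ztable([-1.5, -1.5, -1.5], [-1.5, -1.5, -1.5]))
        assert not bool(hits.loc["gX", "is_hit"])
        assert hits.loc["gX", "wt_pass_fraction"] == 1.0
        assert hits.loc["gX", "ko_pass_fraction"] == 0.0

    def test_median_z_rule(self):
        z = _ztable([-2.0, -1.6, -0.3], [0.0, -0.1, 0.2])
        assert bool(call_hits(z, rule="median_z").loc["gX", "is_hit"])
        assert not bool(
            call_hits(_ztable([-2.0, -0.3, -0.2], [0.0, 0.0, 0.0]), rule="median_z").loc["gX", "is_hit"]
        )

    def test_uncallable_with_missing_replicates(self):
        hits = call_hits(_ztable([-2.0, np.nan, np.nan], [0.0, 0.0, 0.0]))
        assert not bool(hits.loc["gX", "is_hit"])
        assert not bool(hits.loc["gX", "callable"])

    def test_invalid_min_fraction(self):
        with pytest.raises(ValueError, match="min_fraction"):
            call_hits(_ztable([0.0, 0.0], [0.0, 0.0]), min_fraction=0.0)

    def test_missing_genotype(self):
        z = _ztable([0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="missing"):
            call_hits(z, ko="MUT")

    @pytest.mark.parametrize("rule", ["replicate_fraction", "median_z"])
    def test_matches_enumeration_oracle_on_random_tables(self, rule, rng):
        n = 1000
        cols = pd.MultiIndex.from_tuples([(g, r) for g in ("KO", "WT") for r in (1, 2, 3)])
        z = pd.DataFrame(rng.normal(-0.5, 1.2, (n, 6)), columns=cols,
                         index=[f"g{i}" for i in range(n)])
        z.insert(0, "role", "library")
        hits = call_hits(z, rule=rule)
        for gene in z.index:
            expected = hits_oracle(
                z.loc[gene, "KO"].to_numpy(dtype=float),
                z.loc[gene, "WT"].to_numpy(dtype=float),
                rule=rule,
            )
            assert bool(hits.loc[gene, "is_hit"]) == expected

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        zko=st.lists(st.floats(-4, 2), min_size=3, max_size=3),
        zwt=st.lists(st.floats(-4, 2), min_size=3, max_size=3),
        thr_shift=st.floats(0, 2),
    )
    def test_monotone_in_threshold_and_fraction(self, zko, zwt, thr_shift):
        # Raising min_fraction tightens both clauses: never adds a hit.
        # A more negative threshold tightens the KO (lethality) clause:
        # never adds a KO-passing replicate.
        z = _ztable(zko, zwt)
        base = call_hits(z, threshold=-1.5)
        harder_frac = call_hits(z, min_fraction=1.0)
        if bool(harder_frac.loc["gX", "is_hit"]):
            assert bool(base.loc["gX", "is_hit"])
        harder_thr = call_hits(z, threshold=-1.5 - thr_shift)
        assert (
            harder_thr.loc["gX", "ko_pass_fraction"] <= base.loc["gX", "ko_pass_fraction"]
        )


# ------------------------------------------------------------- position QC

class TestPositionEffects:
    def test_constant_plate_not_flagged(self):
        rep = flag_position_effects(np.ones((8, 12)))
        assert not rep.flagged

    def test_edge_depression_flagged(self, rng):
        flagged = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            plate = r.lognormal(0, 0.1, (8, 12))
            plate[0, :] *= 0.5
            plate[-1, :] *= 0.5
            plate[:, 0] *= 0.5
            plate[:, -1] *= 0.5
            if flag_position_effects(plate).flagged:
                flagged += 1
        assert flagged >= 95

    def test_null_flag_rate_calibrated(self):
        flags = sum(
            flag_position_effects(np.random.default_rng(seed).lognormal(0, 0.1, (8, 12))).flagged
            for seed in range(1000)
        )
        assert flags / 1000 <= 0.01 + 0.01

    def test_too_few_wells_warns(self):
        with pytest.warns(UserWarning, match="too few"):
            rep = flag_position_effects(np.ones((3, 3)))
        assert not rep.flagged and np.isnan(rep.test_p)


# --------------------------------------------------------------- correlation

class TestReplicateCorrelation:
    def test_identical_replicates(self, rng):
        mat = rng.lognormal(0, 0.2, (4, 6))
        ds = make_dataset({("WT", 1): mat, ("WT", 2): mat})
        assert replicate_correlation(ds).mean == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        mat = rng.lognormal(0, 0.2, (4, 6))
        ds = make_dataset({("WT", 1): mat, ("WT", 2): 2 * mat + 1e-9 * rng.normal(size=(4, 6))})
        assert replicate_correlation(ds).mean == pytest.approx(1.0, abs=1e-6)

    def test_requires_two_replicates(self, rng):
        ds = make_dataset({("WT", 1): rng.lognormal(0, 0.2, (4, 6))})
        with pytest.raises(ValueError, match="replicates"):
            replicate_correlation(ds)
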