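import numpy as np
import pandas as pd

from clinekit.core import MISSING
from clinekit.scan import (
    fit_snp_gradients,
    local_moran_scan,
    locate_individuals,
    manhattan_table,
    standardized_coords,
)
from clinekit.synth import SynthConfig, generate_clinal_dataset

from conftest import make_gm, make_sites
from oracles import local_moran_bruteforce


def _grid_dataset(seed=0, n_snps=120, slope=(2.0, 0.0)):
    """Individuals on a 6x6 site grid; SNP 0 carries a planted logistic
    gradient with the given slope on standardized coordinates."""
    rng = np.random.default_rng(seed)
    codes = [f"S{i}" for i in range(36)]
    lat = np.repeat(np.linspace(51, 53, 6), 6)
    lon = np.tile(np.linspace(4, 7, 6), 6)
    per = 28
    assignment = {f"i{k}": codes[k // per] for k in range(36 * per)}
    sites = make_sites(codes, lat=lat, lon=lon, assignment=assignment)
    ids = list(assignment)
    calls = rng.binomial(2, rng.uniform(0.3, 0.7, n_snps),
                         size=(len(ids), n_snps)).astype(np.int8)
    gm = make_gm(calls, ids=ids)
    xy = standardized_coords(gm, sites)
    eta = xy @ np.array(slope) + 0.1
    p = 1 / (1 + np.exp(-eta))
    calls[:, 0] = rng.binomial(2, p)
    gm = make_gm(calls, ids=ids)
    return gm, sites


class TestGradientFit:
    def test_flat_snp_has_near_zero_slope(self):
        gm, sites = _grid_dataset(seed=1, slope=(0.0, 0.0))
        fit = fit_snp_gradients(gm, sites)
        # background SNPs have no geographic signal; median ||a|| stays small
        assert np.median(fit.magnitude) < 0.15

    def test_planted_slope_recovered(self):
        gm, sites = _grid_dataset(seed=2, slope=(2.0, 0.0))
        fit = fit_snp_gradients(gm, sites)
        assert fit.converged[0]
        assert abs(fit.slopes[0, 0] - 2.0) < 0.3
        assert abs(fit.slopes[0, 1]) < 0.3

    def test_score_invariant_to_allele_flip(self):
        gm, sites = _grid_dataset(seed=3, slope=(1.5, 1.0))
        flipped = gm.calls.copy()
        typed = flipped != MISSING
        flipped[typed] = 2 - flipped[typed]
        gm2 = make_gm(flipped, ids=gm.individual_ids)
        f1 = fit_snp_gradients(gm, sites)
        f2 = fit_snp_gradients(gm2, sites)
        assert np.allclose(f1.magnitude, f2.magnitude, atol=1e-6)

    def test_steep_snps_rank_top_decile(self, dutch_sites):
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = SynthConfig(n_snps=800, n_individuals=8, cline_strength=0.15,
                              n_steep_snps=8, steep_factor=5.0, seed=seed)
            gm, st, truth = generate_clinal_dataset(cfg, dutch_sites)
            fit = fit_snp_gradients(gm, st)
            scores = fit.scores()
            cutoff = scores.quantile(0.9)
            in_top = (scores.loc[truth.steep_snps] >= cutoff).mean()
            hits += in_top == 1.0
        assert hits >= 0.9 * n_seeds - 1e-9


class TestLocate:
    def test_expected_dosage_individual_placed_at_site(self):
        gm, sites = _grid_dataset(seed=4, slope=(2.0, 0.0), n_snps=150)
        rng = np.random.default_rng(0)
        # plant strong gradients on every SNP so placement is identifiable
        xy = standardized_coords(gm, sites)
        slopes = rng.normal(scale=1.5, size=(150, 2))
        intercepts = rng.normal(scale=0.3, size=150)
        p = 1 / (1 + np.exp(-(xy @ slopes.T + intercepts)))
        calls = rng.binomial(2, p).astype(np.int8)
        gm = make_gm(calls, ids=gm.individual_ids)
        fit = fit_snp_gradients(gm, sites)
        placed = locate_individuals(fit, gm)
        # site-mean placements should track the true standardized coordinates
        df = placed.assign(site=[gm.individual_ids[i].split("_")[0] for i in range(len(placed))])
        err = np.linalg.norm(placed[["east", "north"]].to_numpy() - xy, axis=1)
        assert np.median(err) < 0.45

    def test_no_signal_gives_no_geography_out_of_sample(self):
        """With zero gradient signal, placements of individuals NOT used in
        fitting are uncorrelated with their true sites. (In-sample
        placements inherit fitting noise and do show a spurious
        correlation; the null behaviour is an out-of-sample property.)"""
        from clinekit.ordination import procrustes_protest

        rs, ps = [], []
        for tr_seed, te_seed in [(5, 105), (6, 206), (7, 307)]:
            gm, sites = _grid_dataset(seed=tr_seed, slope=(0.0, 0.0), n_snps=60)
            fit = fit_snp_gradients(gm, sites)
            gm_new, _ = _grid_dataset(seed=te_seed, slope=(0.0, 0.0), n_snps=60)
            placed = locate_individuals(fit, gm_new)
            xy = standardized_coords(gm_new, sites)
            ok = placed["success"].to_numpy()
            res = procrustes_protest(placed[["east", "north"]].to_numpy()[ok],
                                     xy[ok], n_perm=99, seed=0)
            rs.append(res.r)
            ps.append(res.p_value)
        assert max(rs) < 0.15  # no geographic structure in the placements
        assert sum(p > 0.05 for p in ps) >= 2  # a single p is a uniform draw


class TestLocalMoran:
    def test_equal_scores_give_zero(self):
        mm = pd.DataFrame({"id": ["a", "b", "c"], "chrom": "1",
                           "pos": [1000, 2000, 3000]})
        scores = pd.Series([2.0, 2.0, 2.0], index=["a", "b", "c"])
        res = local_moran_scan(scores, mm, window_bp=5000, n_perm=0)
        assert (res.table["I"] == 0).all()

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        for trial in range(8):
            n = int(rng.integers(10, 200))
            chrom = rng.choice(["1", "2"], n)
            pos = np.sort(rng.choice(np.arange(1, 5000) * 97, n, replace=False))
            mm = pd.DataFrame({"id": [f"m{i}" for i in range(n)],
                               "chrom": chrom, "pos": pos})
            mm = mm.sort_values(["chrom", "pos"]).reset_index(drop=True)
            z = rng.normal(size=n)
            scores = pd.Series(z, index=mm["id"])
            res = local_moran_scan(scores, mm, window_bp=20_000, n_perm=0)
            ref = local_moran_bruteforce(
                res.table["chrom"].to_numpy(), res.table["pos"].to_numpy(),
                res.table["score"].to_numpy(), 20_000,
            )
            ours = res.table["I"].to_numpy()
            both = np.isfinite(ref)
            assert np.array_equal(np.isfinite(ours), both)
            assert np.abs(ours[both] - ref[both]).max() < 1e-12

    def test_ten_marker_toy_values(self):
        mm = pd.DataFrame({"id": [f"m{i}" for i in range(10)], "chrom": "1",
                           "pos": (np.arange(10) + 1) * 1000})
        z = np.array([0, 0, 0, 5, 5, 5, 0, 0, 0, 0], dtype=float)
        scores = pd.Series(z, index=mm["id"])
        res = local_moran_scan(scores, mm, window_bp=1000, n_perm=0)
        ref = local_moran_bruteforce(["1"] * 10, mm["pos"].to_numpy(), z, 1000)
        assert np.allclose(res.table["I"].to_numpy(), ref, atol=1e-12)
        assert res.table["I"][4] > 0  # centre of the cluster: positive I

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        mm = pd.DataFrame({"id": [f"m{i}" for i in range(50)], "chrom": "1",
                           "pos": (np.arange(50) + 1) * 10_000})
        z = rng.normal(size=50)
        a = local_moran_scan(pd.Series(z, index=mm["id"]), mm,
                             window_bp=25_000, n_perm=0)
        b = local_moran_scan(pd.Series(3 * z + 7, index=mm["id"]), mm,
                             window_bp=25_000, n_perm=0)
        assert np.allclose(a.table["I"], b.table["I"], atol=1e-10)

    def test_planted_cluster_detected(self):
        detections = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 3000
            pos = (np.arange(n) + 1) * 20_000
            z = rng.normal(size=n)
            start = 1200
            cluster = slice(start, start + 8)
            pos[cluster] = pos[start] + np.arange(8) * 5000  # 8 SNPs in 35 kb
            pos[start + 8:] = pos[start + 7] + (np.arange(n - start - 8) + 1) * 20_000
            z[cluster] = rng.normal(4.0, 0.5, 8)
            mm = pd.DataFrame({"id": [f"m{i}" for i in range(n)], "chrom": "1",
                               "pos": pos})
            res = local_moran_scan(pd.Series(z, index=mm["id"]), mm,
                                   window_bp=50_000, n_perm=4000, seed=seed)
            hits = manhattan_table(res, p_threshold=5e-4)
            cluster_ids = {f"m{i}" for i in range(start, start + 8)}
            if cluster_ids <= set(hits["id"]):
                detections += 1
        assert detections >= n_seeds - 1

    def test_manhattan_table_contract(self):
        rng = np.random.default_rng(8)
        mm = pd.DataFrame({"id": [f"m{i}" for i in range(400)],
                           "chrom": rng.choice(["1", "2"], 400),
                           "pos": np.tile((np.arange(200) + 1) * 30_000, 2)[:400]})
        mm = mm.sort_values(["chrom", "pos"]).reset_index(drop=True)
        mm["pos"] = np.concatenate([
            (np.arange((mm["chrom"] == "1").sum()) + 1) * 30_000,
            (np.arange((mm["chrom"] == "2").sum()) + 1) * 30_000,
        ])
        z = rng.normal(size=400)
        res = local_moran_scan(pd.Series(z, index=mm["id"]), mm,
                               window_bp=50_000, n_perm=500, seed=0)
        hits = manhattan_table(res, p_threshold=5e-4)
        assert list(hits.columns) == list(res.table.columns)
        sorted_hits = hits.sort_values(["chrom", "pos"]).reset_index(drop=True)
        assert sorted_hits.equals(hits)
        none = manhattan_table(res, p_threshold=0.0)
        assert len(none) == 0
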