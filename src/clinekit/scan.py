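"""Per-SNP geographic allele-frequency gradients, individual placement, and
the local Moran's I genome scan for clustered steep-gradient regions.

Each SNP's alternate-allele dosage is modelled as Binomial(2, logistic(a.x +
b)) over standardized individual coordinates x; the gradient score is the
slope magnitude ||a||. Individuals are placed by maximizing the joint
binomial likelihood of their genotypes under the fitted per-SNP surfaces.
The scan flags markers whose extreme scores cluster with similarly extreme
neighbours inside a bp window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .core import MISSING, GenotypeMatrix, SiteTable
from .synth import planar_coords

_MAX_ABS_COEF = 20.0  # separation guard on the linear predictor scale


def standardized_coords(gm: GenotypeMatrix, sites: SiteTable) -> np.ndarray:
    """Per-individual (east, north) coordinates, zero mean / unit variance."""
    xy_site = planar_coords(sites)
    pos = {c: k for k, c in enumerate(sites.site_codes)}
    rows = np.array([pos[c] for c in sites.site_of(gm.individual_ids)])
    xy = xy_site[rows]
    sd = xy.std(axis=0)
    sd[sd == 0] = 1.0
    return (xy - xy.mean(axis=0)) / sd


@dataclass
class SnpGradientFit:
    """Per-SNP logistic gradient fits: slope vectors, intercepts, scores."""

    snp_ids: list[str]
    slopes: np.ndarray  # (n_snps, 2): (a_east, a_north)
    intercepts: np.ndarray
    converged: np.ndarray  # bool per SNP

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.slopes, axis=1)

    def scores(self) -> pd.Series:
        """||a|| per SNP; non-converged fits are NaN (excluded from scans)."""
        m = self.magnitude.copy()
        m[~self.converged] = np.nan
        return pd.Series(m, index=self.snp_ids, name="gradient")


def fit_snp_gradients(
    gm: GenotypeMatrix,
    sites: SiteTable,
    max_iter: int = 40,
    tol: float = 1e-8,
) -> SnpGradientFit:
    """Fit dosage ~ Binomial(2, logistic(a.x + b)) per SNP by IRLS,
    vectorised across SNPs.

    Fits hitting the separation guard (|coefficient| above the cap) are
    flagged non-converged.
    """
    xy = standardized_coords(gm, sites)
    n, S = gm.n_individuals, gm.n_snps
    X = np.column_stack([np.ones(n), xy])  # n x 3
    Y = gm.calls.astype(float)
    W_obs = (gm.calls != MISSING).astype(float)
    Y[gm.calls == MISSING] = 0.0

    beta = np.zeros((S, 3))
    # intercept start at the empirical logit of the overall frequency
    with np.errstate(divide="ignore", invalid="ignore"):
        pbar = Y.sum(axis=0) / (2.0 * W_obs.sum(axis=0))
    pbar = np.clip(np.nan_to_num(pbar, nan=0.5), 1e-3, 1 - 1e-3)
    beta[:, 0] = np.log(pbar / (1 - pbar))

    active = np.ones(S, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(X @ beta[active].T, -30.0, 30.0)  # n x S_active
        mu = expit(eta)
        w = 2.0 * mu * (1.0 - mu) * W_obs[:, active]
        resid = (Y[:, active] - 2.0 * mu) * W_obs[:, active]
        XtWX = np.einsum("ni,ns,nj->sij", X, w, X)
        XtWX += 1e-9 * np.eye(3)[None, :, :]
        rhs = np.einsum("ni,ns->si", X, resid)
        step = np.linalg.solve(XtWX, rhs[..., None])[..., 0]
        beta[active] += step
        moved = np.abs(step).max(axis=1)
        idx = np.flatnonzero(active)
        done = moved < tol
        capped = np.abs(beta[idx]).max(axis=1) > _MAX_ABS_COEF
        active[idx[done | capped]] = False

    capped = np.abs(beta).max(axis=1) > _MAX_ABS_COEF
    beta[capped] = np.clip(beta[capped], -_MAX_ABS_COEF, _MAX_ABS_COEF)
    converged = ~capped & ~active
    return SnpGradientFit(
        snp_ids=list(gm.marker_map["id"]),
        slopes=beta[:, 1:].copy(),
        intercepts=beta[:, 0].copy(),
        converged=converged,
    )


def locate_individuals(fit: SnpGradientFit, gm: GenotypeMatrix) -> pd.DataFrame:
    """Place each individual at the coordinates maximizing the joint
    binomial likelihood of its genotypes under the fitted surfaces.

    Returns a DataFrame (east, north, success) indexed by individual; failed
    optimizations yield NaN coordinates.
    """
    ok = fit.converged
    A = fit.slopes[ok]
    b = fit.intercepts[ok]
    out = np.full((gm.n_individuals, 2), np.nan)
    success = np.zeros(gm.n_individuals, dtype=bool)
    for i in range(gm.n_individuals):
        g = gm.calls[i, ok].astype(float)
        typed = g != MISSING
        gt, At, bt = g[typed], A[typed], b[typed]

        def nll(x):
            eta = np.clip(At @ x + bt, -30, 30)
            mu = expit(eta)
            return -(gt * np.log(mu) + (2 - gt) * np.log(1 - mu)).sum()

        def grad(x):
            eta = np.clip(At @ x + bt, -30, 30)
            mu = expit(eta)
            return -At.T @ (gt - 2 * mu)

        res = minimize(nll, np.zeros(2), jac=grad, method="BFGS")
        if res.success or res.status == 2:  # precision loss still usable
            out[i] = res.x
            success[i] = True
    return pd.DataFrame(
        {"east": out[:, 0], "north": out[:, 1], "success": success},
        index=gm.individual_ids,
    )


@dataclass
class MoranScanResult:
    table: pd.DataFrame  # id, chrom, pos, score, n_window, I, p
    window_bp: int
    n_permutations: int

    @property
    def I(self) -> np.ndarray:
        return self.table["I"].to_numpy()

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()


def _window_bounds(chrom: np.ndarray, pos: np.ndarray, window_bp: int):
    """Per-marker [lo, hi) index bounds of same-chromosome neighbours within
    window_bp (marker map assumed sorted)."""
    n = len(pos)
    lo = np.empty(n, dtype=int)
    hi = np.empty(n, dtype=int)
    start = 0
    for c in pd.unique(chrom):
        stop = start + int((chrom == c).sum())
        p = pos[start:stop]
        lo[start:stop] = start + np.searchsorted(p, p - window_bp, side="left")
        hi[start:stop] = start + np.searchsorted(p, p + window_bp, side="right")
        start = stop
    return lo, hi


def local_moran_scan(
    scores: pd.Series,
    marker_map: pd.DataFrame,
    window_bp: int = 50_000,
    n_perm: int = 10_000,
    seed: int | None = 0,
    variance: str = "genome",
) -> MoranScanResult:
    """Local Moran's I over per-SNP scores with a bp-window neighbourhood.

    ``I_i = [n_i / ((n_i - 1) S^2)] (Z_i - Zbar) sum_j w_ij (Z_j - Zbar)``
    with binary window weights, ``n_i`` the marker count inside the window
    (including i), and ``Zbar``/``S^2`` the genome-wide mean and variance of
    the scores (``variance="window"`` uses window-local moments instead).
    The one-sided p (positive local autocorrelation) reshuffles the scores
    over all markers. Markers with fewer than 2 in-window markers, or with
    NaN scores, are excluded.
    """
    mm = marker_map.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    z = scores.reindex(mm["id"]).to_numpy(dtype=float)
    keep = np.isfinite(z)
    mm = mm[keep].reset_index(drop=True)
    z = z[keep]
    chrom = mm["chrom"].to_numpy()
    pos = mm["pos"].to_numpy()
    n = len(z)
    lo, hi = _window_bounds(chrom, pos, window_bp)
    n_win = hi - lo  # markers within the window, including i

    zbar_g = z.mean()
    s2_g = z.var()
    if s2_g == 0:
        table = pd.DataFrame(
            {"id": mm["id"], "chrom": chrom, "pos": pos, "score": z,
             "n_window": n_win, "I": 0.0, "p": np.nan}
        )
        return MoranScanResult(table, window_bp, 0)

    def moran(zv: np.ndarray) -> np.ndarray:
        if variance == "genome":
            # permutations leave the genome-wide moments unchanged
            zbar, s2 = zbar_g, s2_g
        elif variance == "window":
            zbar = np.array([zv[l:h].mean() for l, h in zip(lo, hi)])
            s2 = np.array([zv[l:h].var() for l, h in zip(lo, hi)])
        else:
            raise ValueError(f"unknown variance {variance!r}")
        zc = zv - zbar
        csum = np.concatenate([[0.0], np.cumsum(zc)])
        neigh = csum[hi] - csum[lo] - zc  # sum over j != i in window
        with np.errstate(invalid="ignore", divide="ignore"):
            return n_win / ((n_win - 1.0) * s2) * zc * neigh

    I_obs = moran(z)
    excluded = n_win < 2
    I_obs[excluded] = np.nan

    p = np.full(n, np.nan)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(n)
        for _ in range(n_perm):
            I_b = moran(rng.permutation(z))
            exceed += I_b >= I_obs - 1e-12
        p = (1 + exceed) / (n_perm + 1)
        p[excluded] = np.nan

    table = pd.DataFrame(
        {"id": mm["id"], "chrom": chrom, "pos": pos, "score": z,
         "n_window": n_win, "I": I_obs, "p": p}
    )
    return MoranScanResult(table, window_bp, n_perm)


def manhattan_table(scan: MoranScanResult, p_threshold: float = 5e-4) -> pd.DataFrame:
    """Markers below the significance threshold, sorted by (chrom, pos)."""
    t = scan.table
    out = t[t["p"] < p_threshold].sort_values(["chrom", "pos"], kind="stable")
    return out.reset_index(drop=True)
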