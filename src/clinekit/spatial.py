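"""Spatial hypothesis tests: great-circle distances, the distance-class
spatial autocorrelogram of genetic covariance with permutation significance
and a combined P, the Mantel test, and the bearing correlogram that orients
a genetic cline.

All permutation p-values are of the form ``(1 + #{stat_perm >= stat_obs}) /
(B + 1)`` and are therefore never smaller than ``1 / (B + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import haversine_distances

from .core import PairMatrix, SiteTable

#: Mean earth radius in km (IUGG R1).
EARTH_RADIUS_KM = 6371.0088


def geodesic_distance(sites: SiteTable) -> PairMatrix:
    """Great-circle distances (km) between sites on a spherical earth."""
    rad = np.radians(sites.coords())
    d = haversine_distances(rad) * EARTH_RADIUS_KM
    return PairMatrix(sites.site_codes, d, "geographic").validate()


def expand_to_individuals(
    geo: PairMatrix, individual_ids, assignment: dict[str, str]
) -> PairMatrix:
    """Individual-level geographic matrix: pairs inherit their sites'
    distance; within-site pairs are at distance 0."""
    pos = {c: k for k, c in enumerate(geo.labels)}
    rows = np.array([pos[assignment[i]] for i in individual_ids])
    vals = geo.values[np.ix_(rows, rows)]
    np.fill_diagonal(vals, 0.0)
    return PairMatrix(list(individual_ids), vals, "geographic")


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel(
    D1: PairMatrix, D2: PairMatrix, n_perm: int = 1000, seed: int | None = 0
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of the upper triangles, one-sided p
    by jointly permuting rows and columns of ``D2``."""
    if D1.labels != D2.labels:
        D2 = D2.reindex(D1.labels)
    x = _offdiag(D1.values)
    v2 = D2.values
    y = _offdiag(v2)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("mantel: constant matrix, correlation undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    if n_perm <= 0:
        return r_obs, float("nan")
    rng = np.random.default_rng(seed)
    n = D1.n
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _offdiag(v2[np.ix_(perm, perm)])
        if np.corrcoef(x, yp)[0, 1] >= r_obs - 1e-12:
            exceed += 1
    return r_obs, (1 + exceed) / (n_perm + 1)


@dataclass
class Correlogram:
    """Distance-class autocorrelogram of genetic covariance."""

    bounds: np.ndarray  # class upper bounds (km); lower bound of class 0 is 0
    r: np.ndarray
    p: np.ndarray  # per-class two-sided permutation p
    combined_p: float
    n_pairs: np.ndarray
    n_permutations: int
    seed: int | None


def _class_r(C: np.ndarray, class_of_pair: np.ndarray, incident: list[np.ndarray], n_classes: int) -> np.ndarray:
    """r_h = (sum of c_ij over pairs in class h) / (sum of c_ii over
    individuals incident to class h)."""
    iu = np.triu_indices(C.shape[0], k=1)
    num = np.bincount(class_of_pair, weights=C[iu], minlength=n_classes)
    diag = np.diag(C)
    denom = np.array([diag[inc].sum() for inc in incident])
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / denom


def spatial_autocorrelogram(
    C: PairMatrix,
    geo: PairMatrix,
    assignment: dict[str, str] | None = None,
    n_classes: int = 24,
    n_perm: int = 1000,
    seed: int | None = 0,
    binning: str = "equal_count",
) -> Correlogram:
    """Spatial autocorrelogram of an individual-level covariance matrix.

    ``geo`` may be site-level (then ``assignment`` expands it to the
    individuals of ``C``) or already individual-level. Distance classes are
    equal-count by default (equal-width available); the first class is
    closed at zero so within-site pairs are counted. The null permutes the
    individuals' site labels (equivalently, jointly permutes the rows and
    columns of ``C``), preserving per-site sample sizes. Per-class p-values
    are two-sided; the combined p ranks the Fisher combination statistic of
    the observed correlogram within the permutation ensemble.
    """
    if assignment is not None:
        geo = expand_to_individuals(geo, C.labels, assignment)
    elif geo.labels != C.labels:
        geo = geo.reindex(C.labels)
    n = C.n
    iu = np.triu_indices(n, k=1)
    d = geo.values[iu]
    if binning == "equal_count":
        qs = np.quantile(d, np.linspace(0, 1, n_classes + 1))
        edges = np.unique(qs[1:])
    elif binning == "equal_width":
        edges = np.linspace(d.min(), d.max(), n_classes + 1)[1:]
        edges = np.unique(edges)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    n_classes = len(edges)
    class_of_pair = np.searchsorted(edges, d, side="left")
    class_of_pair = np.minimum(class_of_pair, n_classes - 1)
    n_pairs = np.bincount(class_of_pair, minlength=n_classes)

    pair_i, pair_j = iu
    incident = []
    for h in range(n_classes):
        sel = class_of_pair == h
        incident.append(np.unique(np.concatenate([pair_i[sel], pair_j[sel]])))

    r_obs = _class_r(C.values, class_of_pair, incident, n_classes)
    if n_perm <= 0:
        return Correlogram(edges, r_obs, np.full(n_classes, np.nan), float("nan"),
                           n_pairs, 0, seed)

    rng = np.random.default_rng(seed)
    r_all = np.empty((n_perm + 1, n_classes))
    r_all[0] = r_obs
    for b in range(1, n_perm + 1):
        perm = rng.permutation(n)
        Cp = C.values[np.ix_(perm, perm)]
        r_all[b] = _class_r(Cp, class_of_pair, incident, n_classes)

    valid = np.isfinite(r_all).all(axis=0) & (n_pairs > 0)
    absr = np.abs(r_all[:, valid])
    # p of each ensemble member per class: fraction of members with |r| >= own
    B1 = n_perm + 1
    p_members = np.empty_like(absr)
    for k in range(absr.shape[1]):
        order = np.sort(absr[:, k])
        # count of members strictly greater, plus ties (including self)
        p_members[:, k] = (B1 - np.searchsorted(order, absr[:, k] - 1e-15, side="left")) / B1
    p_class = np.full(n_classes, np.nan)
    p_class[valid] = p_members[0]
    fisher = -2.0 * np.log(np.clip(p_members, 1e-300, 1.0)).sum(axis=1)
    combined_p = float((fisher >= fisher[0] - 1e-12).sum() / B1)
    return Correlogram(edges, r_obs, p_class, combined_p, n_pairs, n_perm, seed)


def initial_bearings(sites: SiteTable) -> np.ndarray:
    """Initial great-circle bearing (degrees clockwise from north) from each
    site to each other site."""
    latlon = np.radians(sites.coords())
    lat = latlon[:, 0][:, None]
    lon = latlon[:, 1][:, None]
    dlon = lon.T - lon
    y = np.sin(dlon) * np.cos(latlon[:, 0])[None, :]
    x = np.cos(lat) * np.sin(latlon[:, 0])[None, :] - np.sin(lat) * np.cos(
        latlon[:, 0]
    )[None, :] * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


@dataclass
class BearingProfile:
    angles: np.ndarray  # degrees in [0, 180)
    r: np.ndarray
    p: np.ndarray
    argmax: float

    def r_at(self, angle: float) -> float:
        return float(self.r[np.argmin(np.abs(self.angles - (angle % 180.0)))])


def bearing_correlogram(
    Dgen: PairMatrix,
    sites: SiteTable,
    step_deg: float = 1.0,
    n_perm: int = 999,
    seed: int | None = 0,
) -> BearingProfile:
    """Bearing correlogram: Mantel correlation between a genetic distance
    matrix and bearing-weighted geographic distances.

    For each angle theta the geographic matrix is ``d_ij * cos^2(alpha_ij -
    theta)`` with ``alpha_ij`` the initial bearing between sites; the
    profile is 180-degree periodic, and its argmax orients the cline. The
    permutation p at each angle jointly permutes the genetic matrix.
    """
    if Dgen.n < 4:
        raise ValueError("bearing correlogram needs at least 4 sites")
    order = [sites.site_codes.index(l) for l in Dgen.labels]
    sub = SiteTable(sites.sites.iloc[order].reset_index(drop=True), {})
    geo = geodesic_distance(sub)
    alpha = initial_bearings(sub)
    n = Dgen.n
    iu = np.triu_indices(n, k=1)
    angles = np.arange(0.0, 180.0, step_deg)
    gvec = geo.values[iu][None, :] * np.cos(
        np.radians(alpha[iu][None, :] - angles[:, None])
    ) ** 2  # (n_angles, n_pairs)

    x = Dgen.values[iu]
    xc = x - x.mean()
    xn = np.sqrt((xc**2).sum())
    gc = gvec - gvec.mean(axis=1, keepdims=True)
    gn = np.sqrt((gc**2).sum(axis=1))
    r = (gc @ xc) / (gn * xn)

    p = np.full(len(angles), np.nan)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perm_vecs = np.empty((n_perm, len(x)))
        for b in range(n_perm):
            perm = rng.permutation(n)
            perm_vecs[b] = Dgen.values[np.ix_(perm, perm)][iu]
        pc = perm_vecs - perm_vecs.mean(axis=1, keepdims=True)
        pn = np.sqrt((pc**2).sum(axis=1))
        r_perm = (gc @ pc.T) / (gn[:, None] * pn[None, :])  # angles x perms
        p = (1 + (r_perm >= r[:, None] - 1e-12).sum(axis=1)) / (n_perm + 1)

    return BearingProfile(angles, r, p, float(angles[int(np.argmax(r))]))
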