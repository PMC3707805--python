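"""Weir-Cockerham Fst (per SNP and combined pairwise) and distance-based
AMOVA under an external grouping of subpopulations.

The Fst estimator is the variance-components theta-hat of Weir & Cockerham
(1984): per SNP the among-population component ``a`` over ``a + b + c``;
combined across SNPs as a ratio of sums. Negative values are clamped to zero
in the pairwise matrix only (per-SNP estimates keep their sign).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PairMatrix, SiteTable


def pop_counts(gm: GenotypeMatrix, sites: SiteTable):
    """Per-subpopulation per-SNP (n typed, alt frequency, het frequency)."""
    idx = {x: i for i, x in enumerate(gm.individual_ids)}
    groups = sites.groups(gm.individual_ids)
    codes = list(groups)
    n = np.zeros((len(codes), gm.n_snps))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, code in enumerate(codes):
        rows = np.array([idx[m] for m in groups[code]])
        sub = gm.calls[rows]
        typed = sub != MISSING
        n[k] = typed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(sub == MISSING, 0, sub).sum(axis=0) / (2.0 * n[k])
            h[k] = (sub == 1).sum(axis=0) / n[k]
    return codes, n, p, h


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """WC84 variance components (a, b, c) per SNP for r populations.

    Inputs are (r, n_snps) arrays of sample sizes, allele frequencies and
    heterozygote frequencies. SNPs where fewer than two populations have
    data get NaN components.
    """
    valid = n > 0
    r = valid.sum(axis=0).astype(float)
    n_ = np.where(valid, n, 0.0)
    p_ = np.where(valid, p, 0.0)
    h_ = np.where(valid, h, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_.sum(axis=0) / r
        nc = (r * nbar - (n_**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n_ * p_).sum(axis=0) / (r * nbar)
        s2 = (n_ * (p_ - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_ * h_).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (r < 2) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


@dataclass
class FstResult:
    per_snp_theta: pd.Series  # theta-hat across all analysed populations
    combined: float  # ratio-of-sums across SNPs, all analysed populations
    pairwise: PairMatrix | None  # over populations meeting the size floor
    clamped_count: int
    populations: list[str] = field(default_factory=list)


def wc_fst(
    gm: GenotypeMatrix,
    sites: SiteTable,
    pops: list[str] | None = None,
    min_n: int = 10,
) -> FstResult:
    """Weir-Cockerham Fst among subpopulations.

    ``per_snp_theta`` and ``combined`` use every analysed subpopulation;
    the ``pairwise`` combined-Fst matrix is restricted to subpopulations
    with at least ``min_n`` individuals, with negative entries clamped to 0.
    """
    codes, n, p, h = pop_counts(gm, sites)
    if pops is not None:
        keep = [codes.index(c) for c in pops]
        codes = list(pops)
        n, p, h = n[keep], p[keep], h[keep]
    if len(codes) < 2:
        raise ValueError("need at least two subpopulations")
    a, b, c = wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    per_snp = pd.Series(theta, index=list(gm.marker_map["id"]), name="theta")
    denom = a + b + c
    use = np.isfinite(denom) & (denom != 0)
    combined = float(a[use].sum() / denom[use].sum())

    membership = sites.groups(gm.individual_ids)
    big = [k for k, code in enumerate(codes) if len(membership.get(code, ())) >= min_n]
    pair = None
    clamped = 0
    if len(big) >= 2:
        labels = [codes[k] for k in big]
        vals = np.zeros((len(big), len(big)))
        for ii in range(len(big)):
            for jj in range(ii + 1, len(big)):
                sel = [big[ii], big[jj]]
                a2, b2, c2 = wc_components(n[sel], p[sel], h[sel])
                d2 = a2 + b2 + c2
                ok = np.isfinite(d2) & (d2 != 0)
                fst = a2[ok].sum() / d2[ok].sum() if ok.any() else 0.0
                if fst < 0:
                    fst = 0.0
                    clamped += 1
                vals[ii, jj] = vals[jj, ii] = fst
        pair = PairMatrix(labels, vals, "fst").validate()
    return FstResult(
        per_snp_theta=per_snp,
        combined=combined,
        pairwise=pair,
        clamped_count=clamped,
        populations=codes,
    )


@dataclass
class AmovaResult:
    """Three-level AMOVA: among groups / among subpopulations within groups /
    within subpopulations."""

    sigma: dict  # variance components
    percent: dict  # percentage of total per level (negatives not clamped)
    phi: dict  # Phi-statistics
    p_among_groups: float
    n_permutations: int
    negative_components: bool
    degenerate: bool  # a group with a single subpopulation


def _group_ss(T: np.ndarray, sizes: np.ndarray, membership: list[np.ndarray]) -> float:
    """Sum over groups of (within-group unordered pair sum) / group size.

    ``T`` holds ordered-pair sums, hence the factor 2."""
    ss = 0.0
    for idx in membership:
        ss += T[np.ix_(idx, idx)].sum() / (2.0 * sizes[idx].sum())
    return ss


def amova(
    gm: GenotypeMatrix,
    sites: SiteTable,
    groups: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Distance-based AMOVA with sites shuffled among groups for the
    among-group permutation test.

    Distances are squared Euclidean on 0/1/2 dosage codes (missing calls
    mean-imputed per SNP). The reported p is
    ``(1 + #{sigma_a_perm >= sigma_a_obs}) / (n_perm + 1)``.
    """
    site_list = [c for c in sites.site_codes if c in set(sites.site_of(gm.individual_ids))]
    for code in site_list:
        if code not in groups:
            raise ValueError(f"site {code} has no group assignment")
    idx = {x: i for i, x in enumerate(gm.individual_ids)}
    memb = sites.groups(gm.individual_ids)
    site_list = list(memb)

    g = gm.calls.astype(float)
    g[gm.calls == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    inds = np.where(np.isnan(g), col_mean[None, :], g)
    sq = (inds**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * inds @ inds.T
    np.fill_diagonal(d2, 0.0)

    P = len(site_list)
    sizes = np.array([len(memb[c]) for c in site_list], dtype=float)
    N = sizes.sum()
    # site-level ORDERED pair sums: T[p, q] = sum over i in p, j in q of d2_ij
    T = np.zeros((P, P))
    rows = [np.array([idx[m] for m in memb[c]]) for c in site_list]
    for pi in range(P):
        for qi in range(pi, P):
            block = d2[np.ix_(rows[pi], rows[qi])]
            T[pi, qi] = T[qi, pi] = block.sum()

    group_names = sorted({groups[c] for c in site_list})
    gidx = {gn: np.array([k for k, c in enumerate(site_list) if groups[c] == gn]) for gn in group_names}
    G = len(group_names)
    if G < 2:
        raise ValueError("need at least two groups")
    degenerate = any(len(v) == 1 for v in gidx.values())

    ss_total = T.sum() / (2.0 * N)
    ss_wp = sum(T[k, k] / (2.0 * sizes[k]) for k in range(P))

    def sigma_a_of(membership: list[np.ndarray]):
        ss_wg = _group_ss(T, sizes, membership)
        ss_ag = ss_total - ss_wg
        ss_ap = ss_wg - ss_wp
        df_a, df_b, df_c = G - 1, P - G, N - P
        ms_a, ms_b, ms_c = ss_ag / df_a, ss_ap / df_b, ss_wp / df_c
        sumsq_within_groups = sum(
            (sizes[m] ** 2).sum() / sizes[m].sum() for m in membership
        )
        n1 = (N - sumsq_within_groups) / df_b
        n2 = (sumsq_within_groups - (sizes**2).sum() / N) / df_a
        n3 = (N - sum(sizes[m].sum() ** 2 for m in membership) / N) / df_a
        sc = ms_c
        sb = (ms_b - sc) / n1
        sa = (ms_a - sc - n2 * sb) / n3
        return sa, sb, sc

    membership = [gidx[gn] for gn in group_names]
    sa, sb, sc = sigma_a_of(membership)
    total = sa + sb + sc
    if total == 0:
        percent = dict.fromkeys(
            ("among_groups", "among_subpops_within_groups", "within_subpops"), 0.0
        )
        phi = dict.fromkeys(("phi_ct", "phi_sc", "phi_st"), float("nan"))
    else:
        percent = {
            "among_groups": 100.0 * sa / total,
            "among_subpops_within_groups": 100.0 * sb / total,
            "within_subpops": 100.0 * sc / total,
        }
        phi = {
            "phi_ct": sa / total,
            "phi_sc": sb / (sb + sc) if (sb + sc) != 0 else float("nan"),
            "phi_st": (sa + sb) / total,
        }

    rng = np.random.default_rng(seed)
    group_sizes = [len(m) for m in membership]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(P)
        start = 0
        shuffled = []
        for gs in group_sizes:
            shuffled.append(perm[start : start + gs])
            start += gs
        sa_p, _, _ = sigma_a_of(shuffled)
        if sa_p >= sa - 1e-15:
            exceed += 1

    return AmovaResult(
        sigma={"among_groups": sa, "among_subpops_within_groups": sb, "within_subpops": sc},
        percent=percent,
        phi=phi,
        p_among_groups=(1 + exceed) / (n_perm + 1),
        n_permutations=n_perm,
        negative_components=bool(sa < 0 or sb < 0 or sc < 0),
        degenerate=degenerate,
    )
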