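"""Marker and individual cleaning chain.

Stages run in a fixed order: Tukey IBS outlier/relatedness screen within
subpopulations, per-subpopulation missingness filter, per-subpopulation
exact Hardy-Weinberg test with Bonferroni correction, and greedy LD pruning
on Kendall's tau-B between genotype vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
from scipy.stats import kendalltau

from .core import MISSING, GenotypeMatrix, SiteTable
from .distances import ibs_distance

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Per-stage exclusions and counts of the cleaning chain."""

    excluded_individuals: list[tuple[str, str]] = field(default_factory=list)
    excluded_snps: list[tuple[str, str]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def excluded_individual_ids(self) -> set[str]:
        return {i for i, _ in self.excluded_individuals}

    def excluded_snp_ids(self) -> set[str]:
        return {s for s, _ in self.excluded_snps}


def tukey_ibs_outliers(
    gm: GenotypeMatrix, sites: SiteTable, k: float = 1.5
) -> QCReport:
    """Tukey screen on within-subpopulation IBS distances.

    Within each subpopulation of at least three individuals, the pool of all
    pairwise IBS distances defines the quartile fences. An individual whose
    median distance to the others exceeds ``Q3 + k*IQR`` is a genetic
    outlier; a pair below ``Q1 - k*IQR`` is flagged related and the member
    with the higher missingness (ties: lexicographically larger id) is
    excluded. Smaller subpopulations are skipped with a log note.
    """
    D = ibs_distance(gm)
    idx = {x: i for i, x in enumerate(gm.individual_ids)}
    miss = gm.missing_rate()
    report = QCReport()
    for code, members in sites.groups(gm.individual_ids).items():
        if len(members) < 3:
            log.info("tukey_ibs_outliers: skipping %s (n=%d < 3)", code, len(members))
            continue
        rows = np.array([idx[m] for m in members])
        sub = D.values[np.ix_(rows, rows)]
        iu = np.triu_indices(len(members), k=1)
        pool = sub[iu]
        q1, q3 = np.percentile(pool, [25, 75])
        iqr = q3 - q1
        hi, lo = q3 + k * iqr, q1 - k * iqr
        med = np.array(
            [np.median(np.delete(sub[i], i)) for i in range(len(members))]
        )
        for i in np.flatnonzero(med > hi):
            report.excluded_individuals.append((members[i], "outlier"))
        for a, b in zip(*iu):
            if sub[a, b] < lo:
                ia, ib = members[a], members[b]
                if (miss[idx[ia]], ia) >= (miss[idx[ib]], ib):
                    drop = ia
                else:
                    drop = ib
                if drop not in report.excluded_individual_ids():
                    report.excluded_individuals.append((drop, "related"))
    report.counts["tukey_excluded"] = len(report.excluded_individuals)
    return report


def missingness_filter(
    gm: GenotypeMatrix, sites: SiteTable, max_rate: float = 0.10
) -> list[str]:
    """SNP ids kept: removed iff missing rate strictly exceeds ``max_rate``
    in at least one subpopulation."""
    missing = gm.calls == MISSING
    idx = {x: i for i, x in enumerate(gm.individual_ids)}
    remove = np.zeros(gm.n_snps, dtype=bool)
    for _, members in sites.groups(gm.individual_ids).items():
        rows = np.array([idx[m] for m in members])
        rate = missing[rows].mean(axis=0)
        remove |= rate > max_rate
    ids = gm.marker_map["id"].to_numpy()
    return [str(s) for s in ids[~remove]]


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Conditional exact Hardy-Weinberg test p-value.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one. A monomorphic sample returns 1.
    """
    n = n_het + n_hom1 + n_hom2
    n_a = 2 * n_hom1 + n_het  # copies of allele 1
    n_b = 2 * n_hom2 + n_het
    if n == 0 or min(n_a, n_b) == 0:
        return 1.0

    def logprob(h: int) -> float:
        ha = (n_a - h) // 2
        hb = (n_b - h) // 2
        return (
            lgamma(n + 1)
            - lgamma(ha + 1)
            - lgamma(h + 1)
            - lgamma(hb + 1)
            + h * np.log(2.0)
            + lgamma(n_a + 1)
            + lgamma(n_b + 1)
            - lgamma(2 * n + 1)
        )

    rare = min(n_a, n_b)
    hs = np.arange(rare % 2, rare + 1, 2)
    lps = np.array([logprob(int(h)) for h in hs])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hs == n_het)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_filter(
    gm: GenotypeMatrix,
    sites: SiteTable,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[str]:
    """SNP ids kept after the per-subpopulation exact HWE test.

    A SNP is removed iff its exact p in any subpopulation falls below
    ``alpha / (n_snps * n_subpops)`` (Bonferroni). Monomorphic SNPs have
    p = 1 and are kept.
    """
    if correction != "bonferroni":
        raise ValueError(f"unknown correction {correction!r}")
    if gm.n_snps == 0:
        return []
    idx = {x: i for i, x in enumerate(gm.individual_ids)}
    groups = sites.groups(gm.individual_ids)
    threshold = alpha / (gm.n_snps * max(1, len(groups)))
    remove = np.zeros(gm.n_snps, dtype=bool)
    for _, members in groups.items():
        rows = np.array([idx[m] for m in members])
        sub = gm.calls[rows]
        for s in range(gm.n_snps):
            if remove[s]:
                continue
            col = sub[:, s]
            n_hom1 = int((col == 0).sum())
            n_het = int((col == 1).sum())
            n_hom2 = int((col == 2).sum())
            if hwe_exact_p(n_het, n_hom1, n_hom2) < threshold:
                remove[s] = True
    ids = gm.marker_map["id"].to_numpy()
    return [str(s) for s in ids[~remove]]


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-B between two genotype vectors.

    Pairs with any missing call are dropped; if nothing remains (or a vector
    is constant after dropping) the statistic is undefined and NaN is
    returned.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if len(x) < 2 or len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return float("nan")
    tau, _ = kendalltau(x, y, variant="b")
    return float(tau)


def ld_prune(
    gm: GenotypeMatrix, window_bp: int = 500_000, tau_max: float = 0.5
) -> list[str]:
    """Greedy map-order LD pruning.

    Scanning left to right within each chromosome, a SNP is kept iff
    ``|tau-B| < tau_max`` against every already-kept SNP within
    ``window_bp``. Undefined tau (monomorphic columns) passes.
    """
    gm = gm.sort_markers()
    ids = gm.marker_map["id"].to_numpy()
    chrom = gm.marker_map["chrom"].to_numpy()
    pos = gm.marker_map["pos"].to_numpy()
    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for s in range(gm.n_snps):
        ok = True
        for t in reversed(kept_by_chrom.get(chrom[s], [])):
            if pos[s] - pos[t] > window_bp:
                break
            tau = kendall_tau_b(gm.calls[:, s], gm.calls[:, t])
            if not np.isnan(tau) and abs(tau) >= tau_max:
                ok = False
                break
        if ok:
            kept.append(s)
            kept_by_chrom.setdefault(chrom[s], []).append(s)
    return [str(x) for x in ids[kept]]


def run_qc(
    gm: GenotypeMatrix,
    sites: SiteTable,
    tukey_k: float = 1.5,
    max_missing: float = 0.10,
    hwe_alpha: float = 0.05,
    ld_window_bp: int = 500_000,
    tau_max: float = 0.5,
    tukey: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full cleaning chain in fixed order:
    individual outliers -> missingness -> HWE -> LD pruning.

    ``tukey=False`` skips the individual screen (the marker filters are then
    idempotent on their own output; the Tukey fences move whenever
    individuals are removed, so its flags are not)."""
    report = tukey_ibs_outliers(gm, sites, k=tukey_k) if tukey else QCReport()
    keep_ind = [i for i in gm.individual_ids if i not in report.excluded_individual_ids()]
    gm1 = gm.subset(individuals=keep_ind)
    report.counts["individuals_in"] = gm.n_individuals
    report.counts["individuals_out"] = gm1.n_individuals

    kept = missingness_filter(gm1, sites, max_rate=max_missing)
    dropped = set(gm1.marker_map["id"]) - set(kept)
    report.excluded_snps += [(s, "missingness") for s in sorted(dropped)]
    gm2 = gm1.subset(snps=kept)

    kept = hwe_filter(gm2, sites, alpha=hwe_alpha)
    dropped = set(gm2.marker_map["id"]) - set(kept)
    report.excluded_snps += [(s, "hwe") for s in sorted(dropped)]
    gm3 = gm2.subset(snps=kept)

    kept = ld_prune(gm3, window_bp=ld_window_bp, tau_max=tau_max)
    dropped = set(gm3.marker_map["id"]) - set(kept)
    report.excluded_snps += [(s, "ld") for s in sorted(dropped)]
    gm4 = gm3.subset(snps=kept)

    report.counts["snps_in"] = gm.n_snps
    report.counts["snps_after_missingness"] = gm2.n_snps
    report.counts["snps_after_hwe"] = gm3.n_snps
    report.counts["snps_out"] = gm4.n_snps
    return gm4, report
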