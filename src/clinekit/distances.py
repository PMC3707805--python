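"""Pairwise relationship matrices: IBS distance, squared genotype distance
with its derived covariance, and normalized IBD-segment sharing.

Conventions documented here because the field is loose about them:

* IBS allele sharing between dosages ``g`` and ``h`` is the allele-count
  overlap ``2 - |g - h|``, except the het-het pair (1, 1) which shares both
  alleles (2). The IBS distance is one minus the mean shared fraction over
  jointly typed SNPs.
* The squared distance d2 is the mean squared dosage difference over jointly
  typed SNPs; the covariance is its double-centring, which on complete data
  equals the centred genotype Gram matrix divided by the SNP count.
* IBD sharing follows the interval-union normalization: chromosomes are cut
  into elementary intervals at all segment endpoints, each interval's length
  is down-weighted by the number of pairs covering it, and a pair's sharing
  W_ij is its covered weight as a fraction of the total weight W_tot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, IBDSegmentTable, PairMatrix

log = logging.getLogger(__name__)


def ibs_distance(gm: GenotypeMatrix) -> PairMatrix:
    """Identity-by-state distance between all pairs of individuals.

    ``d(i, j) = 1 - mean_s shared(g_is, g_js) / 2`` over SNPs typed in both;
    a pair with zero jointly typed SNPs gets a NaN cell (logged).
    """
    g = gm.calls.astype(np.float64)
    typed = (gm.calls != MISSING).astype(np.float64)
    g_t = np.where(gm.calls == MISSING, 0.0, g)
    n_joint = typed @ typed.T
    # sum over joint SNPs of |g_i - g_j|: expand |a-b| for a,b in {0,1,2}
    # via indicator algebra: |a-b| = a + b - 2*min(a,b); min over dosages is
    # awkward vectorised, so use the three indicator planes instead.
    planes = [(gm.calls == c).astype(np.float64) for c in (0, 1, 2)]
    absdiff = np.zeros_like(n_joint)
    hethet = planes[1] @ planes[1].T
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            absdiff += abs(a - b) * (planes[a] @ planes[b].T)
    shared = 2.0 * n_joint - absdiff  # het-het contributes |1-1|=0, i.e. 2 shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - shared / (2.0 * n_joint)
    if (n_joint == 0).any():
        log.warning("ibs_distance: %d pairs share no typed SNPs", int((n_joint == 0).sum() - 0))
    np.fill_diagonal(d, 0.0)
    return PairMatrix(list(gm.individual_ids), d, "distance").validate()


def d2_distance(gm: GenotypeMatrix) -> PairMatrix:
    """Mean squared dosage difference over jointly typed SNPs."""
    typed = (gm.calls != MISSING).astype(np.float64)
    g = np.where(gm.calls == MISSING, 0.0, gm.calls.astype(np.float64))
    g2 = g * g
    n_joint = typed @ typed.T
    cross = g @ g.T
    sq_i = g2 @ typed.T
    ssd = sq_i + sq_i.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = ssd / n_joint
    if (n_joint == 0).any():
        log.warning("d2_distance: %d pairs share no typed SNPs", int((n_joint == 0).sum()))
    np.fill_diagonal(d2, 0.0)
    m = PairMatrix(list(gm.individual_ids), d2, "distance")
    # squared distances: validate symmetry/diagonal but values are d^2
    return m.validate()


def covariance_from_d2(D2: PairMatrix) -> PairMatrix:
    """Double-centre a squared-distance matrix into a covariance matrix.

    ``c_ij = -(d2_ij - rowmean_i - rowmean_j + grandmean) / 2``. Every row of
    the result sums to zero; on complete data it equals the centred genotype
    Gram matrix over the SNP count.
    """
    v = D2.values
    if np.isnan(v).any():
        raise ValueError("covariance_from_d2: matrix has missing cells")
    row = v.mean(axis=1)
    c = -(v - row[:, None] - row[None, :] + v.mean()) / 2.0
    c = (c + c.T) / 2.0
    return PairMatrix(list(D2.labels), c, "covariance").validate()


@dataclass
class IBDSharingResult:
    """Normalized pairwise IBD sharing.

    ``W`` holds W_ij in [0, 1]; ``W_tot`` the maximum attainable sharing
    weight; ``intervals`` the elementary intervals with their per-interval
    weight F(s) = length / n_covering_pairs.
    """

    W: PairMatrix
    W_tot: float
    intervals: pd.DataFrame  # chrom, start_bp, end_bp, n_pairs, F

    def distance(self) -> PairMatrix:
        d = 1.0 - self.W.values
        np.fill_diagonal(d, 0.0)
        return PairMatrix(list(self.W.labels), d, "distance").validate()


def ibd_sharing(segments: IBDSegmentTable, gm: GenotypeMatrix) -> IBDSharingResult:
    """Gusev-style normalized IBD sharing from a segment table.

    Each chromosome is partitioned at the union of segment endpoints into
    elementary intervals; interval weight F(s) = l_s / pi_s where pi_s counts
    the pairs covering it. ``W_ij`` is the pair's covered weight divided by
    ``W_tot`` (the sum of all weights). An empty table yields all-zero W.
    """
    segments.validate(gm)
    ids = list(gm.individual_ids)
    index = {x: i for i, x in enumerate(ids)}
    n = len(ids)
    W_num = np.zeros((n, n))
    rows = []
    W_tot = 0.0
    for chrom, grp in segments.records.groupby("chrom"):
        cuts = np.unique(np.concatenate([grp["start_bp"], grp["end_bp"]]))
        starts, ends = cuts[:-1], cuts[1:]
        seg_start = grp["start_bp"].to_numpy()
        seg_end = grp["end_bp"].to_numpy()
        pair_idx = [(index[a], index[b]) for a, b in zip(grp["id_a"], grp["id_b"])]
        for s, e in zip(starts, ends):
            covering = np.flatnonzero((seg_start <= s) & (seg_end >= e))
            pairs = {tuple(sorted(pair_idx[k])) for k in covering}
            if not pairs:
                continue
            F = float(e - s) / len(pairs)
            W_tot += F
            for i, j in pairs:
                W_num[i, j] += F
                W_num[j, i] += F
            rows.append((chrom, int(s), int(e), len(pairs), F))
    W = W_num / W_tot if W_tot > 0 else W_num
    np.fill_diagonal(W, 0.0)
    intervals = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_pairs", "F"])
    return IBDSharingResult(
        W=PairMatrix(ids, W, "covariance"), W_tot=W_tot, intervals=intervals
    )
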