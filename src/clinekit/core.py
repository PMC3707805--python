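"""Shared data model for the toolkit.

Genotypes are diploid biallelic SNP calls coded as the number of copies of the
alternate allele (0, 1, 2) with a distinct missing sentinel. All pairwise
relationship matrices (IBS distance, squared genotype distance, covariance,
Fst, geographic distance) travel as :class:`PairMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Never 0.
MISSING: int = -1

VALID_CALLS = frozenset({0, 1, 2, MISSING})


class ValidationError(ValueError):
    """Raised when a data object violates its structural invariants."""


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs alternate-allele dosage matrix with a marker map.

    Parameters
    ----------
    individual_ids
        Unique opaque identifiers, one per row of ``calls``.
    marker_map
        DataFrame with columns ``id``, ``chrom``, ``pos`` (1-based bp),
        one row per column of ``calls``. Positions are strictly increasing
        within each chromosome.
    calls
        ``int8`` array of shape ``(n_individuals, n_snps)`` with values in
        {0, 1, 2, MISSING}.
    """

    individual_ids: list[str]
    marker_map: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.marker_map = self.marker_map.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.marker_map)

    def validate(self) -> "GenotypeMatrix":
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dupes = pd.Series(self.individual_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate individual ids: {dupes}")
        if self.calls.shape != (self.n_individuals, self.n_snps):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.n_individuals} individuals x {self.n_snps} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError(f"{bad.sum()} calls outside {{0,1,2,MISSING}}")
        ids = self.marker_map["id"]
        if ids.duplicated().any():
            raise ValidationError(
                f"duplicate marker ids: {sorted(ids[ids.duplicated()].unique())}"
            )
        for chrom, grp in self.marker_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        return self

    def sort_markers(self) -> "GenotypeMatrix":
        """Return a copy sorted by (chromosome, position)."""
        order = self.marker_map.sort_values(
            ["chrom", "pos"], kind="stable"
        ).index.to_numpy()
        return GenotypeMatrix(
            list(self.individual_ids),
            self.marker_map.iloc[order].reset_index(drop=True),
            self.calls[:, order],
        )

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Subset by individual ids and/or marker ids (order preserved)."""
        calls = self.calls
        ids = list(self.individual_ids)
        mm = self.marker_map
        if individuals is not None:
            keep = set(individuals)
            idx = [i for i, x in enumerate(ids) if x in keep]
            ids = [ids[i] for i in idx]
            calls = calls[idx, :]
        if snps is not None:
            keep = set(snps)
            mask = mm["id"].isin(keep).to_numpy()
            mm = mm[mask]
            calls = calls[:, mask]
        return GenotypeMatrix(ids, mm.reset_index(drop=True), calls)

    def missing_rate(self) -> np.ndarray:
        """Per-individual fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)


@dataclass
class SiteTable:
    """Sampling sites with coordinates plus an individual→site assignment.

    ``sites`` holds columns ``site``, ``lat``, ``lon`` (decimal degrees,
    WGS84); ``assignment`` maps individual id to site code.
    """

    sites: pd.DataFrame
    assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)

    @property
    def site_codes(self) -> list[str]:
        return list(self.sites["site"])

    def validate(self) -> "SiteTable":
        s = self.sites
        if s["site"].duplicated().any():
            raise ValidationError("duplicate site codes")
        if ((s["lat"] < -90) | (s["lat"] > 90)).any():
            bad = s.loc[(s["lat"] < -90) | (s["lat"] > 90), "site"].tolist()
            raise ValidationError(f"latitude out of [-90, 90] at sites {bad}")
        if ((s["lon"] < -180) | (s["lon"] > 180)).any():
            bad = s.loc[(s["lon"] < -180) | (s["lon"] > 180), "site"].tolist()
            raise ValidationError(f"longitude out of [-180, 180] at sites {bad}")
        known = set(s["site"])
        orphans = sorted({v for v in self.assignment.values() if v not in known})
        if orphans:
            raise ValidationError(f"individuals assigned to unknown sites: {orphans}")
        return self

    def coords(self) -> np.ndarray:
        """(n_sites, 2) array of (lat, lon) in degrees."""
        return self.sites[["lat", "lon"]].to_numpy(dtype=float)

    def site_of(self, individual_ids) -> list[str]:
        missing = [i for i in individual_ids if i not in self.assignment]
        if missing:
            raise ValidationError(f"individuals without site assignment: {missing}")
        return [self.assignment[i] for i in individual_ids]

    def groups(self, individual_ids) -> dict[str, list[str]]:
        """Individuals grouped by site, in site-table order."""
        out: dict[str, list[str]] = {c: [] for c in self.site_codes}
        for i in individual_ids:
            out[self.assignment[i]].append(i)
        return {c: v for c, v in out.items() if v}


PAIR_KINDS = ("distance", "covariance", "fst", "geographic")


@dataclass
class PairMatrix:
    """Labelled symmetric matrix of pairwise quantities.

    ``kind`` is one of ``distance``, ``covariance``, ``fst``, ``geographic``.
    Missing cells are ``NaN`` and propagate; consumers that cannot handle
    them (e.g. MDS) must refuse.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.labels)

    def validate(self, tol: float = 1e-9) -> "PairMatrix":
        if self.kind not in PAIR_KINDS:
            raise ValidationError(f"unknown kind {self.kind!r}")
        v = self.values
        if v.shape != (self.n, self.n):
            raise ValidationError(f"matrix shape {v.shape} vs {self.n} labels")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.T)) if v.size else 0.0
        if asym > tol:
            raise ValidationError(f"matrix asymmetric (max |v - v.T| = {asym:.3g})")
        if self.kind in ("distance", "geographic"):
            diag = np.diag(v)
            if np.nanmax(np.abs(diag)) > tol:
                raise ValidationError("distance matrix has nonzero diagonal")
            if np.nanmin(v) < -tol:
                raise ValidationError("distance matrix has negative entries")
        if self.kind == "fst" and np.nanmin(v) < -tol:
            raise ValidationError("fst matrix has negative entries (clamp upstream)")
        return self

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def reindex(self, labels) -> "PairMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)


@dataclass
class IBDSegmentTable:
    """Detected IBD segments: (id_a, id_b, chrom, start_bp, end_bp) records."""

    records: pd.DataFrame  # columns id_a, id_b, chrom, start_bp, end_bp

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)

    def validate(self, gm: GenotypeMatrix | None = None) -> "IBDSegmentTable":
        r = self.records
        if (r["id_a"] == r["id_b"]).any():
            raise ValidationError("segment with id_a == id_b")
        if (r["start_bp"] >= r["end_bp"]).any():
            raise ValidationError("segment with start_bp >= end_bp")
        if gm is not None:
            spans = gm.marker_map.groupby("chrom")["pos"].agg(["min", "max"])
            for chrom, grp in r.groupby("chrom"):
                if chrom not in spans.index:
                    raise ValidationError(f"segment on unknown chromosome {chrom}")
                lo, hi = spans.loc[chrom]
                if (grp["start_bp"] < lo).any() or (grp["end_bp"] > hi).any():
                    raise ValidationError(
                        f"segment outside marker span on chromosome {chrom}"
                    )
        return self

    def __len__(self) -> int:
        return len(self.records)
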