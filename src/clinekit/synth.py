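"""Synthetic Dutch-like genotype datasets with known planted structure.

The generator emulates a grid-like national sampling design: ~54 sites over a
~300 km extent, a weak allele-frequency cline at a configurable compass
bearing, planted genetic outliers, related pairs, and steep-gradient SNPs.
Site-level allele frequencies are deterministic given the drawn per-SNP
logistic coefficients; individual genotype sampling is the only noise, which
keeps parameter-recovery targets sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import MISSING, GenotypeMatrix, IBDSegmentTable, SiteTable, ValidationError

#: km per degree of latitude on the spherical earth used throughout.
KM_PER_DEG = 111.19492664455873


@dataclass
class SynthConfig:
    """Configuration of the clinal-dataset generator.

    ``cline_bearing`` is degrees clockwise from geographic north in [0, 180);
    ``cline_strength`` is the maximum allele-frequency range a background SNP
    can span across the sampled extent (0 disables the cline).
    """

    n_snps: int = 2000
    n_individuals: int | dict = 18
    cline_bearing: float = 110.0
    cline_strength: float = 0.1
    baseline_maf: tuple[float, float] = (0.1, 0.9)
    n_outliers: int = 0
    n_related_pairs: int = 0
    n_steep_snps: int = 0
    steep_factor: float = 5.0
    outlier_shift: float = 0.15
    related_copy_fraction: float = 0.6
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if not (0 <= self.cline_strength <= 0.5):
            raise ValidationError("cline_strength must be in [0, 0.5]")
        for name in ("n_snps", "n_outliers", "n_related_pairs", "n_steep_snps"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        return self


@dataclass
class TruthLabels:
    """Ground truth of a generated dataset."""

    outliers: list[str]
    related_pairs: list[tuple[str, str]]
    steep_snps: list[str]
    bearing: float
    gradients: np.ndarray  # per-SNP (a_east, a_north) logit slope vector
    site_freqs: pd.DataFrame  # sites x SNPs expected allele frequencies
    seed: int = 0


def planar_coords(sites: SiteTable) -> np.ndarray:
    """Local planar (east, north) km coordinates of the sites, centred."""
    latlon = sites.coords()
    lat0 = latlon[:, 0].mean()
    east = (latlon[:, 1] - latlon[:, 1].mean()) * KM_PER_DEG * np.cos(np.radians(lat0))
    north = (latlon[:, 0] - lat0) * KM_PER_DEG
    return np.column_stack([east, north])


def bearing_projection(sites: SiteTable, bearing_deg: float) -> np.ndarray:
    """Project sites onto the axis at ``bearing_deg`` (clockwise from north),
    rescaled so the sampled extent spans [-0.5, 0.5]."""
    xy = planar_coords(sites)
    theta = np.radians(bearing_deg)
    u = xy[:, 0] * np.sin(theta) + xy[:, 1] * np.cos(theta)
    span = u.max() - u.min()
    if span == 0:
        return np.zeros_like(u)
    return (u - (u.max() + u.min()) / 2) / span


def generate_clinal_dataset(
    cfg: SynthConfig, sites: SiteTable
) -> tuple[GenotypeMatrix, SiteTable, TruthLabels]:
    """Draw a genotype dataset with a planted cline and known structure.

    Per SNP ``s`` and site with projected coordinate ``u``, the site allele
    frequency is ``expit(alpha_s + beta_s * u)``. Background slopes are drawn
    so the frequency range across the extent is at most ``cline_strength``;
    steep SNPs have the slope amplified by ``steep_factor``. Returns the
    genotype matrix, a SiteTable with the individual assignment filled in,
    and the truth labels.
    """
    cfg.validate()
    if len(sites.sites) == 0:
        raise ValidationError("sites table is empty")
    rng = np.random.default_rng(cfg.seed)
    codes = sites.site_codes
    n_sites = len(codes)
    if isinstance(cfg.n_individuals, dict):
        per_site = [int(cfg.n_individuals[c]) for c in codes]
    else:
        per_site = [int(cfg.n_individuals)] * n_sites

    S = cfg.n_snps
    p0 = rng.uniform(cfg.baseline_maf[0], cfg.baseline_maf[1], S)
    alpha = logit(p0)
    # slope scaled so |delta p| across unit extent <= cline_strength at p0
    deriv = p0 * (1 - p0)
    tilt = rng.uniform(-1.0, 1.0, S)
    steep_idx = rng.choice(S, size=min(cfg.n_steep_snps, S), replace=False)
    # steep SNPs get an unambiguous tilt away from zero before amplification
    tilt[steep_idx] = rng.choice([-1.0, 1.0], len(steep_idx)) * rng.uniform(
        0.5, 1.0, len(steep_idx)
    )
    beta = tilt * cfg.cline_strength / deriv
    beta[steep_idx] *= cfg.steep_factor

    u = bearing_projection(sites, cfg.cline_bearing)
    site_p = expit(alpha[None, :] + beta[None, :] * u[:, None])  # sites x SNPs

    ids: list[str] = []
    assignment: dict[str, str] = {}
    blocks = []
    for k, (code, n_ind) in enumerate(zip(codes, per_site)):
        g = rng.binomial(2, site_p[k], size=(n_ind, S)).astype(np.int8)
        blocks.append(g)
        for j in range(n_ind):
            iid = f"{code}_{j:03d}"
            ids.append(iid)
            assignment[iid] = code
    calls = np.vstack(blocks) if blocks else np.empty((0, S), dtype=np.int8)

    # planted frequency-shift outliers: fixed offset on half the SNPs
    shifted_snps = rng.choice(S, size=S // 2, replace=False)
    outlier_rows = rng.choice(len(ids), size=min(cfg.n_outliers, len(ids)), replace=False)
    for row in outlier_rows:
        k = codes.index(assignment[ids[row]])
        p = site_p[k].copy()
        p[shifted_snps] = np.clip(p[shifted_snps] + cfg.outlier_shift, 0.01, 0.99)
        calls[row] = rng.binomial(2, p).astype(np.int8)

    # related pairs: copy a fraction of one member's calls into the other
    pool = [i for i in range(len(ids)) if i not in set(outlier_rows)]
    rng.shuffle(pool)
    related: list[tuple[str, str]] = []
    for _ in range(cfg.n_related_pairs):
        if len(pool) < 2:
            break
        a, b = pool.pop(), pool.pop()
        copy_mask = rng.random(S) < cfg.related_copy_fraction
        calls[b, copy_mask] = calls[a, copy_mask]
        related.append((ids[a], ids[b]))

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    # marker map: SNPs spread over 22 autosomes, 50 kb spacing
    chrom = (np.arange(S) % 22 + 1).astype(str)
    pos = (np.arange(S) // 22 + 1) * 50_000
    mm = pd.DataFrame(
        {"id": [f"snp{idx}" for idx in range(S)], "chrom": chrom, "pos": pos}
    )
    gm = GenotypeMatrix(ids, mm, calls).sort_markers().validate()

    st = SiteTable(sites.sites.copy(), assignment).validate()
    truth = TruthLabels(
        outliers=[ids[r] for r in outlier_rows],
        related_pairs=related,
        steep_snps=[f"snp{idx}" for idx in steep_idx],
        bearing=cfg.cline_bearing % 180.0,
        gradients=np.column_stack(
            [
                beta * np.sin(np.radians(cfg.cline_bearing)),
                beta * np.cos(np.radians(cfg.cline_bearing)),
            ]
        ),
        site_freqs=pd.DataFrame(site_p, index=codes, columns=list(mm["id"])),
        seed=cfg.seed,
    )
    return gm, st, truth


def generate_ibd_segments(
    gm: GenotypeMatrix, sharing_spec, seed: int = 0
) -> IBDSegmentTable:
    """Place IBD segments uniformly within chromosome spans.

    ``sharing_spec`` is a list of ``((id_a, id_b), n_segments, mean_len_bp)``;
    requested counts are honoured exactly. Segment lengths are uniform in
    [0.5, 1.5] x mean; a segment that cannot fit on any chromosome raises.
    """
    rng = np.random.default_rng(seed)
    spans = gm.marker_map.groupby("chrom")["pos"].agg(["min", "max"])
    known = set(gm.individual_ids)
    rows = []
    for (a, b), n_seg, mean_len in sharing_spec:
        if a not in known or b not in known:
            raise ValidationError(f"unknown individuals in pair ({a}, {b})")
        for _ in range(int(n_seg)):
            length = int(rng.uniform(0.5, 1.5) * mean_len)
            fits = spans[(spans["max"] - spans["min"]) >= length]
            if fits.empty:
                raise ValidationError(
                    f"segment of length {length} bp exceeds every chromosome span"
                )
            chrom = rng.choice(fits.index.to_numpy())
            lo, hi = fits.loc[chrom]
            start = int(rng.integers(lo, hi - length + 1))
            rows.append((a, b, chrom, start, start + length))
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "chrom", "start_bp", "end_bp"])
    return IBDSegmentTable(df).validate(gm)


def dutch_site_fixture() -> SiteTable:
    """The 54 Dutch sampling sites with their printed coordinates.

    Extra columns ``n_initial`` and ``n_clean`` carry the published per-site
    sample sizes before and after data cleaning.
    """
    with resources.files("clinekit.data").joinpath("dutch_sites.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"site": str})
    return SiteTable(df).validate()


def dutch_sample_sizes() -> pd.DataFrame:
    """Per-site published sample sizes (site, n_initial, n_clean)."""
    return dutch_site_fixture().sites[["site", "n_initial", "n_clean"]].copy()
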