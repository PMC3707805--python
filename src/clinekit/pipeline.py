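"""End-to-end orchestration: QC -> relationship matrices -> MDS / Fst ->
spatial tests -> gradient scan, from one configuration mapping, with a run
manifest that pins inputs, config, seeds and per-stage counts.

All randomness flows from one master seed through named per-stage
substreams, so disabling a stage does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import GenotypeMatrix, SiteTable
from .differentiation import wc_fst
from .distances import covariance_from_d2, d2_distance, ibs_distance
from .io import read_genotypes, read_sites, write_matrix
from .ordination import classical_mds, procrustes_protest
from .qc import run_qc
from .scan import fit_snp_gradients, local_moran_scan
from .spatial import (
    bearing_correlogram,
    expand_to_individuals,
    geodesic_distance,
    mantel,
    spatial_autocorrelogram,
)

STAGES = ("qc", "distances", "mds", "fst", "autocorr", "mantel", "bearing", "scan")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed (below 2**31)."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config: dict
    input_hashes: dict
    seeds: dict
    counts: dict = field(default_factory=dict)
    stages_run: list = field(default_factory=list)
    stages_skipped: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)


def run_pipeline(
    config: dict,
    out_dir,
    gm: GenotypeMatrix | None = None,
    sites: SiteTable | None = None,
) -> RunManifest:
    """Execute the enabled stages in fixed order and write TSV outputs plus
    ``manifest.json`` under ``out_dir``.

    ``config`` keys: ``inputs`` (``genotypes``/``format``/``sites``/
    ``assignment`` paths; ignored when ``gm``/``sites`` are passed
    directly), ``stages`` (list, default all), ``seed`` (master seed) and
    optional per-stage parameter mappings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = list(config.get("stages", STAGES))
    master = int(config.get("seed", 0))
    hashes = {}
    if gm is None:
        inp = config["inputs"]
        for key in ("genotypes", "sites", "assignment"):
            if key in inp and inp[key]:
                hashes[key] = _hash_file(inp[key])
        gm = read_genotypes(inp["genotypes"], format=inp.get("format", "vcf"))
        sites = read_sites(inp["sites"], inp.get("assignment"))
    manifest = RunManifest(
        version=__version__,
        config=config,
        input_hashes=hashes,
        seeds={s: stage_seed(master, s) for s in STAGES},
    )
    manifest.counts["individuals_in"] = gm.n_individuals
    manifest.counts["snps_in"] = gm.n_snps

    def on(stage: str) -> bool:
        if stage in enabled:
            manifest.stages_run.append(stage)
            return True
        manifest.stages_skipped.append(stage)
        return False

    if on("qc"):
        gm, report = run_qc(gm, sites, **config.get("qc", {}))
        pd.DataFrame(report.excluded_individuals, columns=["id", "reason"]).to_csv(
            out / "qc_excluded_individuals.tsv", sep="\t", index=False
        )
        pd.DataFrame(report.excluded_snps, columns=["id", "reason"]).to_csv(
            out / "qc_excluded_snps.tsv", sep="\t", index=False
        )
        manifest.counts.update({f"qc_{k}": v for k, v in report.counts.items()})

    D_ibs = cov = None
    if on("distances"):
        D_ibs = ibs_distance(gm)
        D2 = d2_distance(gm)
        cov = covariance_from_d2(D2)
        write_matrix(D_ibs, out / "ibs_distance.tsv")
        write_matrix(D2, out / "d2_distance.tsv")
        write_matrix(cov, out / "covariance.tsv")

    if on("mds"):
        D_ibs = D_ibs if D_ibs is not None else ibs_distance(gm)
        mds = classical_mds(D_ibs, k=2, correct=True)
        coords = pd.DataFrame(
            mds.coordinates, index=mds.labels, columns=["dim1", "dim2"]
        )
        coords.to_csv(out / "mds_coordinates.tsv", sep="\t", index_label="id")
        site_of = sites.site_of(gm.individual_ids)
        means = coords.groupby(site_of).mean()
        geo = sites.sites.set_index("site").loc[means.index, ["lon", "lat"]]
        pr = procrustes_protest(
            means.to_numpy(), geo.to_numpy(), seed=stage_seed(master, "mds")
        )
        manifest.counts["mds_protest_r"] = round(pr.r, 6)
        manifest.counts["mds_protest_p"] = pr.p_value

    fst = None
    if on("fst"):
        fst = wc_fst(gm, sites, **config.get("fst", {}))
        fst.per_snp_theta.to_csv(out / "fst_per_snp.tsv", sep="\t")
        if fst.pairwise is not None:
            write_matrix(fst.pairwise, out / "fst_pairwise.tsv")
        manifest.counts["fst_combined"] = float(fst.combined)

    geo_sites = geodesic_distance(sites)
    if on("autocorr"):
        cov = cov if cov is not None else covariance_from_d2(d2_distance(gm))
        cg = spatial_autocorrelogram(
            cov, geo_sites, dict(zip(gm.individual_ids, sites.site_of(gm.individual_ids))),
            seed=stage_seed(master, "autocorr"), **config.get("autocorr", {}),
        )
        pd.DataFrame(
            {"upper_km": cg.bounds, "r": cg.r, "p": cg.p, "n_pairs": cg.n_pairs}
        ).to_csv(out / "autocorrelogram.tsv", sep="\t", index=False)
        manifest.counts["autocorr_combined_p"] = cg.combined_p

    if on("mantel") and fst is not None and fst.pairwise is not None:
        r, p = mantel(
            fst.pairwise, geo_sites.reindex(fst.pairwise.labels),
            seed=stage_seed(master, "mantel"),
        )
        manifest.counts["mantel_r"] = round(r, 6)
        manifest.counts["mantel_p"] = p

    if on("bearing") and fst is not None and fst.pairwise is not None:
        prof = bearing_correlogram(
            fst.pairwise, sites, seed=stage_seed(master, "bearing"),
            **config.get("bearing", {}),
        )
        pd.DataFrame({"angle": prof.angles, "r": prof.r, "p": prof.p}).to_csv(
            out / "bearing_profile.tsv", sep="\t", index=False
        )
        manifest.counts["bearing_argmax"] = prof.argmax

    if on("scan"):
        fit = fit_snp_gradients(gm, sites)
        scan = local_moran_scan(
            fit.scores(), gm.marker_map, seed=stage_seed(master, "scan"),
            **config.get("scan", {}),
        )
        scan.table.to_csv(out / "moran_scan.tsv", sep="\t", index=False)
        manifest.counts["scan_n_markers"] = len(scan.table)

    manifest.write(out / "manifest.json")
    return manifest
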