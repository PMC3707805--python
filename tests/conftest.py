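import numpy as np
import pandas as pd
import pytest

from clinekit.core import GenotypeMatrix, SiteTable
from clinekit.synth import SynthConfig, dutch_site_fixture, generate_clinal_dataset


@pytest.fixture(scope="session")
def dutch_sites() -> SiteTable:
    return dutch_site_fixture()


@pytest.fixture(scope="session")
def clinal_small(dutch_sites):
    """Small clinal dataset shared across read-only tests: 54 sites x 6
    individuals x 300 SNPs, bearing 110, with planted structure."""
    cfg = SynthConfig(
        n_snps=300, n_individuals=6, cline_bearing=110.0, cline_strength=0.2,
        n_outliers=2, n_related_pairs=1, n_steep_snps=5, seed=11,
    )
    gm, st, truth = generate_clinal_dataset(cfg, dutch_sites)
    return gm, st, truth


def make_gm(calls, chrom=None, pos=None, ids=None) -> GenotypeMatrix:
    """Handcrafted genotype matrix from a nested list of dosages."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_snp = calls.shape
    mm = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n_snp)],
            "chrom": chrom if chrom is not None else ["1"] * n_snp,
            "pos": pos if pos is not None else [(i + 1) * 1000 for i in range(n_snp)],
        }
    )
    ids = ids if ids is not None else [f"i{k}" for k in range(n_ind)]
    return GenotypeMatrix(ids, mm, calls).validate()


def make_sites(codes, lat=None, lon=None, assignment=None) -> SiteTable:
    df = pd.DataFrame(
        {
            "site": codes,
            "lat": lat if lat is not None else np.linspace(51, 53, len(codes)),
            "lon": lon if lon is not None else np.linspace(4, 7, len(codes)),
        }
    )
    return SiteTable(df, assignment or {}).validate()
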