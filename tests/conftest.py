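import numpy as np
import pandas as pd
import pytest

from gbtspanel.core import SITE_COLUMNS, DepthMatrix, GenotypeMatrix


def make_sites(n, chrom="SL2.40ch01", prefix="s", source_db="db1", start_pos=100, step=100):
    """Canonical site table with n evenly spaced SNPs."""
    return pd.DataFrame({
        "site_id": [f"{prefix}{i}" for i in range(n)],
        "chrom": chrom,
        "pos": [start_pos + step * i for i in range(n)],
        "ref_allele": "A",
        "alt_allele": "G",
        "variant_class": "SNP",
        "source_db": source_db,
        "is_trait_marker": source_db == "trait",
    })[list(SITE_COLUMNS)]


def make_gm(columns, samples=None, sites=None):
    """GenotypeMatrix from a list of per-site coded columns."""
    calls = np.array(columns, dtype=np.int8).T
    n_samples, n_sites = calls.shape
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    if sites is None:
        sites = make_sites(n_sites)
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


def make_dm(depth, total=None, on_target=None, duplicate=None, samples=None, regions=None):
    """DepthMatrix from a 2-D array; totals default to consistent values."""
    depth = np.asarray(depth, dtype=np.int64)
    n_samples, n_regions = depth.shape
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    if regions is None:
        regions = [f"r{j}" for j in range(n_regions)]
    row_sums = depth.sum(axis=1)
    on_target = row_sums if on_target is None else np.asarray(on_target)
    total = on_target if total is None else np.asarray(total)
    duplicate = np.zeros(n_samples, dtype=np.int64) if duplicate is None else np.asarray(duplicate)
    totals = pd.DataFrame(
        {"total_reads": total, "on_target_reads": on_target, "duplicate_reads": duplicate},
        index=pd.Index(samples, name="sample_id"),
    )
    return DepthMatrix(samples=samples, regions=regions, depth=depth, totals=totals)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
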