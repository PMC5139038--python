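import numpy as np
import pytest

from svbalscan import HaplotypeMatrix, Region, SVGenotypePanel


def make_matrix(rows, positions=None, sample_ids=None, pops=None, chrom="chr1"):
    """Build a HaplotypeMatrix from a list of 0/1 row strings or arrays."""
    alleles = np.array([[int(c) for c in r] if isinstance(r, str) else r for r in rows],
                       dtype=np.int8)
    n_hap, n_site = alleles.shape
    if positions is None:
        positions = np.arange(10, 10 + 10 * n_site, 10)
    if sample_ids is None:
        sample_ids = [f"S{i // 2}" for i in range(n_hap)]
    return HaplotypeMatrix(
        alleles=alleles,
        positions=np.asarray(positions),
        site_ids=[f"site{j}" for j in range(n_site)],
        sample_ids=sample_ids,
        pop_labels=pops or [],
        chrom=chrom,
    )


@pytest.fixture
def small_matrix():
    return make_matrix(["00", "01", "10", "11"])


@pytest.fixture
def two_class_matrix():
    """Two deeply separated haplotype classes (10 fixed differences) with
    private variation inside each class."""
    rng = np.random.default_rng(7)
    n_per, n_fixed, n_noise = 6, 10, 6
    fixed_a = np.zeros((n_per, n_fixed), dtype=np.int8)
    fixed_b = np.ones((n_per, n_fixed), dtype=np.int8)
    noise = (rng.random((2 * n_per, n_noise)) < 0.2).astype(np.int8)
    alleles = np.concatenate(
        [np.concatenate([fixed_a, fixed_b], axis=0), noise], axis=1
    )
    order = np.argsort(np.concatenate(
        [np.arange(n_fixed) * 10, 1000 + np.arange(n_noise) * 10]
    ))
    h = make_matrix(
        alleles[:, order],
        positions=np.sort(np.concatenate(
            [np.arange(n_fixed) * 10, 1000 + np.arange(n_noise) * 10]
        )),
    )
    labels = np.array([0] * n_per + [1] * n_per, dtype=np.int8)
    return h, labels


def make_sv_panel(dosages, hap_carrier=None, sample_ids=None):
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(len(dosages))]
    return SVGenotypePanel(
        sample_ids=sample_ids,
        dosage=np.asarray(dosages),
        hap_carrier=None if hap_carrier is None else np.asarray(hap_carrier),
    )
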