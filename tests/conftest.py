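import numpy as np
import pytest

from ssapkit.marker_data import MarkerMatrix, TaxonScheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scheme():
    """Two diploid progenitors and three polyploids, two accessions each."""
    taxon_of = {}
    for t in ("SYL", "TRI", "NUD", "REP", "ISL"):
        for i in (1, 2):
            taxon_of[f"{t.lower()}{i}"] = t
    return TaxonScheme(taxon_of=taxon_of, maternal_diploid="SYL",
                       paternal_diploid="TRI", polyploids=("NUD", "REP", "ISL"))


def random_matrix(rng, n_loci=20, n_acc=10, te_family="TE", p=0.5):
    calls = (rng.random((n_loci, n_acc)) < p).astype(np.uint8)
    calls[calls.sum(axis=1) == 0, 0] = 1  # avoid fully empty loci by default
    return MarkerMatrix(
        te_family=te_family,
        locus_ids=tuple(f"L{i}" for i in range(n_loci)),
        accession_ids=tuple(f"a{j}" for j in range(n_acc)),
        calls=calls,
    )


@pytest.fixture
def random_matrix_factory(rng):
    def make(**kw):
        return random_matrix(rng, **kw)
    return make


def matrix_for_scheme(rng, scheme, n_loci=30, p=0.5, te_family="TE"):
    accs = tuple(scheme.taxon_of)
    calls = (rng.random((n_loci, len(accs))) < p).astype(np.uint8)
    return MarkerMatrix(te_family=te_family,
                        locus_ids=tuple(f"L{i}" for i in range(n_loci)),
                        accession_ids=accs, calls=calls)
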