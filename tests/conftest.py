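import numpy as np
import pytest

from aimpanel.ancestry import ReferenceDatabase
from aimpanel.qc import AIMProfile
from aimpanel.syndata import FrequencySet, SimulationConfig


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_populations=3,
        n_markers=20,
        ancestral_freqs=tuple(np.linspace(0.2, 0.8, 20)),
        fst=(0.05, 0.10, 0.15),
        n_individuals=(12, 12, 12),
        seed=42,
    )


@pytest.fixture
def db_factory():
    """Build a ReferenceDatabase directly from a (meta x marker) frequency
    matrix with a fixed per-marker total allele count."""

    def build(freqs, totals=400, metas=None, markers=None):
        freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
        k, m = freqs.shape
        metas = tuple(metas) if metas else tuple(f"META{i + 1}" for i in range(k))
        markers = tuple(markers) if markers else tuple(f"M{j + 1:04d}" for j in range(m))
        alleles = {marker: ("A", "G") for marker in markers}
        totals_matrix = np.full((k, m), float(totals))
        return ReferenceDatabase(
            meta_populations=metas,
            markers=markers,
            alleles=alleles,
            allele1=np.round(freqs * totals),
            totals=totals_matrix,
            min_individuals=1,
        )

    return build


@pytest.fixture
def profile_factory():
    """Profile from an allele-1 dosage vector over A/G markers."""

    def build(dosages, sample="S1", markers=None):
        markers = markers or [f"M{j + 1:04d}" for j in range(len(dosages))]
        genotype_of = {2: ("A", "A"), 1: ("A", "G"), 0: ("G", "G"), None: None}
        return AIMProfile(
            sample=sample,
            genotypes={m: genotype_of[d] for m, d in zip(markers, dosages)},
        )

    return build


@pytest.fixture
def frequency_set_factory():
    def build(freqs, populations=None, markers=None, alleles=None):
        freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
        k, m = freqs.shape
        populations = tuple(populations) if populations else tuple(f"POP{i + 1}" for i in range(k))
        markers = tuple(markers) if markers else tuple(f"M{j + 1:04d}" for j in range(m))
        alleles = tuple(alleles) if alleles else (("A", "G"),) * m
        return FrequencySet(markers=markers, populations=populations, alleles=alleles, freqs=freqs)

    return build
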