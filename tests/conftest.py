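import numpy as np
import pytest

from m6asupp import GeneratorConfig, TranscriptModel
from m6asupp.signatures import run_study


def make_random_model(rng: np.random.Generator, tid: str = "T",
                      coding: bool = True, n_exons: int | None = None,
                      ) -> TranscriptModel:
    """A random but valid transcript model for property tests."""
    n = int(rng.integers(1, 7)) if n_exons is None else n_exons
    lengths = rng.integers(5, 400, size=n)
    introns = rng.integers(50, 500, size=max(n - 1, 0))
    strand = "+" if rng.uniform() < 0.5 else "-"
    g = int(rng.integers(0, 10_000))
    g_exons = []
    for i, ln in enumerate(lengths):
        g_exons.append((g, g + int(ln)))
        g += int(ln)
        if i < n - 1:
            g += int(introns[i])
    exons = tuple(g_exons if strand == "+" else g_exons[::-1])
    tlen = int(lengths.sum())
    cs = ce = None
    if coding and tlen >= 10:
        cs = int(rng.integers(0, tlen // 3 + 1))
        ce = int(rng.integers(cs + 3, tlen + 1))
    return TranscriptModel(tid, f"G_{tid}", "chrT", strand, exons,
                           cds_start=cs, cds_end=ce)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture
def three_exon() -> TranscriptModel:
    """Plus-strand transcript with exon lengths 200, 100, 300 and a CDS."""
    return TranscriptModel("T3", "G3", "chr1", "+",
                           ((100, 300), (400, 500), (700, 1000)),
                           cds_start=50, cds_end=350)


@pytest.fixture(scope="session")
def study():
    """One seeded default-configuration synthetic study, shared by the
    end-to-end tests."""
    return run_study(GeneratorConfig(seed=11))
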