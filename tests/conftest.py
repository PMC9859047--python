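import numpy as np
import pandas as pd
import pytest

from mirqtl.containers import GenotypeMatrix


def make_genotypes(dosages, chrom="chr1", pos_start=1000, spacing=5000,
                   samples=None):
    """Wrap a plain dosage array in a GenotypeMatrix with synthetic metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    samples = samples or [f"S{i:03d}" for i in range(n)]
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    pos = {}
    rows = []
    for j in range(m):
        c = chroms[j]
        pos[c] = pos.get(c, pos_start) + spacing
        rows.append({"id": f"v{j:03d}", "chrom": c, "pos": pos[c],
                     "ref": "A", "alt": "G"})
    return GenotypeMatrix(dosages=dosages, samples=samples,
                          variants=pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic study, shared
    across tests (deterministic given the fixed seed)."""
    from mirqtl.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline(RunConfig(outdir=str(out), seed=11))
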