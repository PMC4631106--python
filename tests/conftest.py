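import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from linegwas import (
    SimulationConfig,
    apply_filters,
    build_covariates,
    genotype_pca,
    simulate_panel,
)
from linegwas.datatypes import GenotypePanel, PhenotypeTable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_panel(dosages, chrom=None, pos=None, line_ids=None):
    """Hand-built panel from a dosage array (rows = lines)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = ["2L"] * m if chrom is None else chrom
    pos = list(range(100, 100 + 200 * m, 200))[:m] if pos is None else pos
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": ["A"] * m,
            "alt": ["T"] * m,
        }
    )
    line_ids = [f"L{i}" for i in range(n)] if line_ids is None else line_ids
    return GenotypePanel(line_ids=line_ids, variants=variants, dosages=dosages)


def make_phenotypes(line_values, reps=3, wolbachia=None, noise_sd=0.0, seed=0):
    """Phenotype table with `reps` identical-or-noisy replicates per line."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, (lid, mu) in enumerate(line_values.items()):
        w = 0 if wolbachia is None else int(wolbachia[i])
        for r in range(reps):
            rows.append((lid, r // 5 + 1, r % 5 + 1, mu + noise_sd * rng.standard_normal(), w))
    return PhenotypeTable(
        flies=pd.DataFrame(rows, columns=["line_id", "vial", "fly", "lifespan_days", "wolbachia"])
    )


@pytest.fixture(scope="session")
def sim_small():
    """Default-structure simulated panel, modest size, with ground truth."""
    cfg = SimulationConfig(n_snps=4000, n_causal=150, seed=11)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def sim_small_qc(sim_small):
    panel, phenos, truth = sim_small
    filtered, report = apply_filters(panel)
    pcs = genotype_pca(filtered, n_components=4)
    covars = build_covariates(pcs, phenos)
    return filtered, phenos, truth, covars
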