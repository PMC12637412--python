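import numpy as np
import pandas as pd
import pytest

from cmapneuro import (
    ExpressionMatrix,
    Level,
    ProbePanel,
    SampleMeta,
    SimConfig,
    make_panel,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_panel() -> ProbePanel:
    return make_panel(n_genes=50, invariant_set_size=5, seed=11)


@pytest.fixture(scope="session")
def small_screen(small_panel):
    """A compact simulated screen: 6 compounds (3 active), 3 replicates."""
    cfg = SimConfig(
        seed=101, panel=small_panel, n_compounds=6, n_active=3,
        doses=(5.0,), n_replicates=3, n_vehicle_wells=8, beads_per_analyte=10,
    )
    beads, samples, truth = simulate_screen(cfg)
    return cfg, beads, samples, truth


def sig_matrix(values, genes, ids, perts, level=Level.L5_SIGNATURE):
    """Signature matrix with perturbagen ids attached, for query tests."""
    samples = [
        SampleMeta(sample_id=s, plate_id="p1", well=f"A{i % 24 + 1:02d}",
                   perturbagen_id=p, dose=5.0)
        for i, (s, p) in enumerate(zip(ids, perts))
    ]
    return ExpressionMatrix(
        values=pd.DataFrame(np.asarray(values, dtype=float), index=genes,
                            columns=ids),
        samples=samples, level=level)


def make_matrix(values, gene_ids, sample_ids, level=Level.L2_MFI, plate="plate1"):
    samples = [
        SampleMeta(sample_id=s, plate_id=plate, well=f"A{i + 1:02d}")
        for i, s in enumerate(sample_ids)
    ]
    return ExpressionMatrix(
        values=pd.DataFrame(np.asarray(values, dtype=float), index=gene_ids,
                            columns=sample_ids),
        samples=samples,
        level=level,
    )
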