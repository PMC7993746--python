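import numpy as np
import pandas as pd
import pytest

from mpscore import (
    GenePanel,
    PanelGene,
    SimulationConfig,
    generate_cohort,
    load_published_panel,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded cohort with 10 planted prognostic genes (single risk program)."""
    cfg = SimulationConfig(
        n_tumor=150,
        n_normal=30,
        n_genes=80,
        n_prognostic=10,
        n_de=25,
        censor_rate=0.4,
        noise_sd=1.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def published_panel() -> GenePanel:
    return load_published_panel()


@pytest.fixture()
def toy_panel() -> GenePanel:
    return GenePanel(
        [
            PanelGene("A", 1, 0, 2.0),
            PanelGene("B", 0, 1, 3.0),
            PanelGene("C", 1, 0, 5.0),
        ],
        provenance="toy",
    )


def score_frame(panel: GenePanel, rows: dict[str, list[int]], samples=None) -> pd.DataFrame:
    """Binary gene x sample score matrix helper."""
    n = len(next(iter(rows.values())))
    samples = samples or [f"s{i}" for i in range(n)]
    return pd.DataFrame(rows, index=samples).T.loc[list(rows)]


@pytest.fixture(scope="session")
def covariate_cohort():
    """Cohort whose hazard is driven by two clinical covariates, no genes."""
    cfg = SimulationConfig(
        n_tumor=500,
        n_normal=0,
        n_genes=2,
        n_prognostic=0,
        n_de=0,
        censor_rate=0.35,
        covariate_betas={"m_status": float(np.log(2.0)), "stage_group": float(np.log(1.5))},
        seed=11,
    )
    return generate_cohort(cfg)
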