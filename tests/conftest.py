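import numpy as np
import pandas as pd
import pytest

from kinsig.harmonize import zscore_normalize
from kinsig.synthetic import (
    CellLinePanel,
    CohortSpec,
    PanelSpec,
    generate_cellline_panel,
    generate_patient_cohort,
)


def normalize_panel(panel: CellLinePanel) -> CellLinePanel:
    return CellLinePanel(
        matrix=zscore_normalize(panel.matrix),
        labels=panel.labels,
        line_ids=panel.line_ids,
        informative_features=panel.informative_features,
        spec=panel.spec,
    )


@pytest.fixture(scope="session")
def strong_panel():
    """Default-shape panel with strong (3 SD) subgroup separation."""
    return generate_cellline_panel(PanelSpec(seed=1, effect_size=3.0))


@pytest.fixture(scope="session")
def strong_panel_norm(strong_panel):
    return normalize_panel(strong_panel)


@pytest.fixture(scope="session")
def std_cohort():
    """Benefit-in-metabolism cohort matching the strong panel's features."""
    return generate_patient_cohort(
        CohortSpec(
            n_patients=600,
            panel=PanelSpec(seed=1, effect_size=3.0),
            seed=11,
        )
    )


def exp_survival_frame(
    rng: np.random.Generator,
    n: int,
    log_hr: np.ndarray,
    baseline_median: float = 24.0,
    censor: float = 60.0,
) -> pd.DataFrame:
    """Exponential PH survival frame for simulation oracles in tests."""
    lam = np.log(2.0) / baseline_median
    t_raw = rng.exponential(1.0 / (lam * np.exp(log_hr)))
    event = (t_raw <= censor).astype(int)
    time = np.minimum(t_raw, censor)
    return pd.DataFrame({"os_months": time, "os_event": event})
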