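import warnings

import numpy as np
import pandas as pd
import pytest

from triomics import normalize, qa, synth

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_study():
    """Compact synthetic study reused by read-only tests."""
    return synth.simulate_study(
        cohort=synth.CohortConfig(n_per_generation=(24, 24, 21), n_families=24),
        taxa_config=synth.TaxaConfig(n_taxa=80, library_size=8000),
        ko_config=synth.KOConfig(n_kos=150, depth=15000),
        n_features=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def default_study():
    """Study-scale cohort (67/67/63, 150 features) under generator
    defaults; session-scoped because normalization is the slow step."""
    return synth.simulate_study(seed=202)


@pytest.fixture(scope="session")
def default_normalized(default_study):
    s = default_study
    mat, report = qa.run_qa(s.matrix, s.meta)
    norm, info = normalize.normalize_pipeline(mat, s.meta)
    return {"study": s, "qa_matrix": mat, "qa_report": report,
            "normalized": norm, "info": info}


def toy_meta(n_study=6, n_qc=3, n_blank=1, batch=1):
    """Minimal injection metadata for hand-built matrices."""
    rows = []
    order = 0
    for i in range(n_qc):
        order += 1
        rows.append({"sample_id": f"QC{i+1}", "batch": batch,
                     "injection_order": order, "role": "qc",
                     "qc_kind": "interspersed", "generation": "", "family": ""})
    for i in range(n_study):
        order += 1
        rows.append({"sample_id": f"S{i+1}", "batch": batch,
                     "injection_order": order, "role": "study",
                     "qc_kind": "", "generation": "Infant", "family": f"F{i+1}"})
    for i in range(n_blank):
        order += 1
        rows.append({"sample_id": f"BL{i+1}", "batch": batch,
                     "injection_order": order, "role": "blank",
                     "qc_kind": "", "generation": "", "family": ""})
    return pd.DataFrame(rows)
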