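import numpy as np
import pandas as pd
import pytest

from proxitome import (
    AnnotationTable,
    ContrastResult,
    IntensityTable,
    SimConfig,
    simulate_turboid,
)


def make_table(values: dict, metadata_rows: list[dict]) -> IntensityTable:
    """Build an IntensityTable from a {sample: column} dict of per-protein values."""
    first = next(iter(values.values()))
    ids = [f"P{i}" for i in range(1, len(first) + 1)]
    df = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"), dtype=float)
    meta = pd.DataFrame(metadata_rows).set_index("sample_id")
    return IntensityTable(df, meta)


def simple_metadata(samples, variant_of) -> list[dict]:
    rows = []
    reps: dict = {}
    for s in samples:
        v = variant_of(s)
        reps[v] = reps.get(v, 0) + 1
        rows.append(
            {"sample_id": s, "variant": v, "egf": "-", "inhibitor": "-",
             "replicate": reps[v]}
        )
    return rows


def contrast_from_stats(stats: dict, **kwargs) -> ContrastResult:
    """ContrastResult from {protein: (log2fc, p_value)} pairs."""
    df = pd.DataFrame(
        {
            "log2fc": {k: v[0] for k, v in stats.items()},
            "p_value": {k: v[1] for k, v in stats.items()},
            "n_obs_A": 3,
            "n_obs_B": 3,
            "n_imputed_A": 0,
            "n_imputed_B": 0,
        }
    )
    df.index.name = "protein_id"
    return ContrastResult(df, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_experiment():
    """One bait + control, modest size, default effect structure."""
    cfg = SimConfig(
        n_proteins=600, variants=("WT",), egf_states=("-",), seed=7
    )
    return simulate_turboid(cfg)


@pytest.fixture
def toy_annotations():
    return AnnotationTable(
        {
            "P1": {"has_pTyr_site"},
            "P2": {"mitochondrial"},
            "P3": {"matrix"},
            "P4": {"intermembrane_space"},
            "P5": {"complex_IV"},
            "P6": {"complex_IV"},
            "P7": {"complex_IV", "has_pTyr_site"},
        }
    )
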