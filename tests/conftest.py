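import numpy as np
import pandas as pd
import pytest

from plasmirna.panel_io import CountMatrix


def make_matrix(counts: dict[str, list[int]], probe_classes: dict[str, str]) -> CountMatrix:
    """Small CountMatrix from literal dicts: probe_id -> per-sample counts."""
    ids = list(counts)
    frame = pd.DataFrame(
        {f"S{j + 1}": [counts[p][j] for p in ids] for j in range(len(next(iter(counts.values()))))},
        index=pd.Index(ids, name="probe_id"),
    )
    ann = []
    for p in ids:
        cls = probe_classes.get(p, "endogenous")
        if cls == "endogenous":
            species = "viral" if not p.startswith("hsa-") else "human"
            prefix = p.split("-")[0] if species == "viral" else None
        else:
            species, prefix = "control", None
        ann.append((cls, species, prefix))
    probes = pd.DataFrame(
        ann, columns=["probe_class", "species", "viral_prefix"], index=frame.index
    )
    return CountMatrix(probes=probes, counts=frame)


@pytest.fixture()
def tiny_matrix() -> CountMatrix:
    """3 endogenous probes, 2 negative + 1 positive control, 4 samples."""
    return make_matrix(
        {
            "hsa-miR-1": [100, 200, 150, 120],
            "hsa-miR-2": [5, 6, 4, 5],
            "ebv-miR-BART1": [50, 55, 60, 45],
            "POS_A": [1000, 1100, 900, 1000],
            "NEG_A": [10, 12, 8, 11],
            "NEG_B": [12, 10, 14, 9],
        },
        {"POS_A": "positive_control", "NEG_A": "negative_control", "NEG_B": "negative_control"},
    )


@pytest.fixture()
def hi_design() -> pd.DataFrame:
    """Two HI subjects with two replicates each, matching samples S1..S4."""
    return pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "S4"],
            "subject_id": ["A", "A", "B", "B"],
            "group": ["HI"] * 4,
            "replicate_index": [1, 2, 1, 2],
            "age": [45, 45, 50, 50],
            "sex": ["M", "M", "F", "F"],
            "bmi": [23.0, 23.0, 26.0, 26.0],
            "survival_time": [np.nan] * 4,
            "event": [np.nan] * 4,
        }
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small-panel simulated dataset shared across tests (seed 42)."""
    from plasmirna import synthetic_data as sd

    cfg = sd.SimConfig(
        n_hi=6, n_replicates=3, n_gp=8,
        n_human_probes=40, n_viral_probes=10,
        n_expressed_human=30, n_expressed_viral=2,
    )
    return sd.simulate_dataset(cfg, seed=42)
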