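import numpy as np
import pytest

from haploscreen.core import DiseaseHaplotype, HMMParams, MarkerPanel


def make_uniform_panel(
    n_markers: int = 21,
    spacing_cm: float = 0.1,
    spacing_bp: int = 100_000,
    alt_freq: float = 0.5,
    dcv_at: int | None = None,
    start_bp: int = 1_000_000,
) -> MarkerPanel:
    """Evenly spaced single-chromosome panel; DCV at the centre by default."""
    pos = start_bp + spacing_bp * np.arange(n_markers, dtype=np.int64)
    cm = spacing_cm * np.arange(n_markers, dtype=float)
    freq = np.full(n_markers, alt_freq, dtype=float)
    i = n_markers // 2 if dcv_at is None else dcv_at
    return MarkerPanel(
        "1", pos, cm, ["A"] * n_markers, ["G"] * n_markers, freq,
        dcv_pos_bp=int(pos[i]),
    )


def random_instance(rng, n_markers=None, missing_rate=0.15):
    """A random small scoring instance: (panel, disease hap, hapA, hapB, params)."""
    m = int(rng.integers(3, 9)) if n_markers is None else n_markers
    pos = np.sort(rng.choice(np.arange(1, 400) * 5000, size=m, replace=False))
    cm = np.sort(rng.uniform(0.0, 2.0, m))
    freq = rng.uniform(0.05, 0.95, m)
    panel = MarkerPanel(
        "1", pos, cm, ["A"] * m, ["G"] * m, freq,
        dcv_pos_bp=int(pos[rng.integers(m)]),
    )
    d = rng.integers(0, 2, m).astype(np.int8)
    hapA = rng.integers(0, 2, m).astype(np.int8)
    hapB = rng.integers(0, 2, m).astype(np.int8)
    hapA[rng.random(m) < missing_rate] = -1
    hapB[rng.random(m) < missing_rate] = -1
    if d[panel.dcv_index] < 0:
        d[panel.dcv_index] = 1
    disease = DiseaseHaplotype("h0", "v", d, "1", panel.dcv_pos_bp)
    params = HMMParams(
        g=float(rng.uniform(0.005, 0.05)),
        decay_meioses=float(rng.uniform(5.0, 50.0)),
    )
    return panel, disease, hapA, hapB, params


@pytest.fixture
def uniform_panel():
    return make_uniform_panel()


@pytest.fixture
def params():
    return HMMParams()
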