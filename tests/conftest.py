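import warnings

import numpy as np
import pandas as pd
import pytest

from kinoscope import differential, krsa, preprocess as pp, simulate as sim

TWO_GROUPS = ("synaptosomal", "nuclear")
INJECTED = {"KIN01": 1.5, "KIN02": 1.5, "KIN03": 1.5, "KIN04": 1.5}


def make_config(**overrides) -> sim.SimulationConfig:
    """A small two-group recovery scenario used across modules."""
    kwargs = dict(
        n_kinases=16,
        peptides_per_kinase=(8, 16),
        groups=TWO_GROUPS,
        active_kinases={"synaptosomal": dict(INJECTED)},
        noise_cv=0.05,
        seed=0,
    )
    kwargs.update(overrides)
    return sim.SimulationConfig(**kwargs)


def run_to_log2fc(cfg, case="synaptosomal", control="nuclear", cutoff=0.15):
    """simulate -> fit -> QC -> matrix -> log2FC; returns intermediates."""
    kmap = sim.generate_kinase_map(cfg)
    series, truth = sim.simulate_exposure_series(cfg, kmap)
    slopes = pp.fit_slopes(series)
    qc = pp.apply_qc(slopes, groups=[case, control])
    matrix = pp.build_signal_matrix(slopes, qc.keep)
    lfc = differential.log2fc(matrix, case, control, cutoff=cutoff)
    return dict(kmap=kmap, series=series, truth=truth, slopes=slopes,
                qc=qc, matrix=matrix, lfc=lfc)


def quiet_krsa(*args, **kwargs):
    """krsa_score with the unmapped-peptide warning silenced (low-signal
    peptides are intentionally outside the QC-passed universe)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return krsa.krsa_score(*args, **kwargs)


def matrix_from_values(values: dict[tuple[str, str], list[float]], peptides=None) -> pp.SignalMatrix:
    """Build a SignalMatrix directly from per-sample log2 signal vectors.

    ``values`` maps (group, chip) -> list of per-peptide log2 values.
    """
    cols = pd.MultiIndex.from_tuples(values.keys(), names=["group", "chip"])
    data = np.column_stack([np.asarray(v, dtype=float) for v in values.values()])
    if peptides is None:
        peptides = [f"pep_{i + 1:03d}" for i in range(data.shape[0])]
    log2 = pd.DataFrame(data, index=pd.Index(peptides, name="peptide_id"), columns=cols)
    mu = log2.mean(axis=1)
    sd = log2.std(axis=1, ddof=1)
    z = log2.sub(mu, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)
    return pp.SignalMatrix(log2=log2, zscore=z, floor=1.0)


@pytest.fixture
def small_series() -> pd.DataFrame:
    """Deterministic 4-peptide, 2-group, 2-chip, noise-free series."""
    cfg = sim.SimulationConfig(
        n_peptides=4, n_kinases=1, peptides_per_kinase=(1, 1),
        groups=("A", "B"), n_chips=2, noise_cv=0.0,
        n_low_signal_peptides=0, seed=5,
    )
    kmap = sim.generate_kinase_map(cfg)
    series, _ = sim.simulate_exposure_series(cfg, kmap)
    return series


@pytest.fixture
def recovery_cfg() -> sim.SimulationConfig:
    return make_config()
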