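import numpy as np
import pandas as pd
import pytest

import stimulon as st
from stimulon.genome import GeneFeature, GenomeAnnotation, Replicon


def make_annotation(genes, length=10000, seed=0, replicon="r1"):
    """Small handcrafted annotation with a random sequence."""
    rng = np.random.default_rng(seed)
    ann = GenomeAnnotation()
    ann.replicons[replicon] = Replicon(replicon, length)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    ann.sequences[replicon] = alphabet[
        rng.integers(0, 4, size=length)].tobytes().decode()
    for g in genes:
        ann.genes[g.id] = g
    return ann


def plant(ann, replicon, start, insert):
    """Overwrite part of a replicon sequence (1-based start)."""
    seq = ann.sequences[replicon]
    ann.sequences[replicon] = (seq[:start - 1] + insert
                               + seq[start - 1 + len(insert):])


@pytest.fixture(scope="session")
def default_sim():
    """One full default simulation shared across tests."""
    return st.simulate(st.SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def default_de(default_sim):
    ann, truth, cm = default_sim
    return st.run_de(cm)


@pytest.fixture(scope="session")
def default_classification(default_sim, default_de):
    ann, truth, cm = default_sim
    return st.classify(ann, default_de)


def de_table(genes, fc, p, base_mean=500.0):
    """Hand-built contrast table for classifier unit tests."""
    fc = np.asarray(fc, dtype=float)
    return pd.DataFrame({
        "fc": fc, "log2fc": np.log2(fc), "p": np.asarray(p, dtype=float),
        "mean_norm_treatment": base_mean * fc,
        "mean_norm_baseline": np.full(len(genes), base_mean),
        "call": (np.maximum(fc, 1 / fc) >= 3.0)
                & (np.asarray(p, dtype=float) < 0.05),
        "direction": np.where(fc >= 1, "up", "down"),
    }, index=pd.Index(genes, name="gene"))
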