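"""Shared fixtures: toy ROGLs, tiny studies, helpers to build objects inline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import fishcmap as fc
from fishcmap.rogl import ConditionMeta, LogFCProfile, ROGL, ROGLSet


def make_rogl(
    logfc: dict[str, float],
    chemical: str = "X",
    experiment_id: str = "e1",
    sample_id: str = "s1",
    tissue: str = "liver",
    dose: str = "1x",
) -> ROGL:
    """Build a ROGL through the public construction path from a LogFC dict."""
    pids = np.array(list(logfc), dtype=object)
    vals = np.array([logfc[p] for p in pids], dtype=float)
    meta = ConditionMeta(
        chemical=chemical, dose=dose, sex="M", tissue=tissue,
        duration="48hr", experiment_id=experiment_id,
    )
    return fc.build_rogl(LogFCProfile(pids, vals, meta, sample_id=sample_id))


def make_signature(
    probes: dict[str, int],
    name: str = "sig",
    chemical: str = "X",
    experiment_id: str = "q1",
) -> fc.Signature:
    pids = np.array(list(probes), dtype=object)
    signs = np.array([probes[p] for p in pids], dtype=int)
    meta = ConditionMeta(
        chemical=chemical, dose="1x", sex="M", tissue="liver",
        duration="48hr", experiment_id=experiment_id,
    )
    return fc.Signature(
        name=name, platform_id="", probe_ids=pids, signs=signs,
        logfc=signs.astype(float), fdr=np.full(len(pids), 0.01), meta=meta,
    )


def random_rogl(rng: np.random.Generator, n: int, **kw) -> ROGL:
    logfc = {f"P{i:04d}": float(v) for i, v in enumerate(rng.normal(0, 1, n))}
    return make_rogl(logfc, **kw)


@pytest.fixture
def toy_rogl() -> ROGL:
    """The 5-probe worked example: ranks P1=+1, P4=-2, P3=+3, P5=+4, P2=-5."""
    return make_rogl({"P1": 0.1, "P2": -2.0, "P3": 0.5, "P4": -0.3, "P5": 1.0})


@pytest.fixture
def toy_set(toy_rogl) -> ROGLSet:
    return ROGLSet(set_id="toy", members=[toy_rogl], key_values={"chemical": "X"})


def two_group_inputs(
    x: np.ndarray, n_treated: int, probe_ids=None
) -> tuple[fc.ExpressionMatrix, fc.SampleTable, list[str]]:
    """Wrap a (probes x samples) array as matrix + one-color sample table."""
    n, total = x.shape
    if probe_ids is None:
        probe_ids = [f"P{i:04d}" for i in range(n)]
    cols = [f"T{i}" for i in range(n_treated)] + [f"C{i}" for i in range(total - n_treated)]
    matrix = fc.ExpressionMatrix(pd.DataFrame(x, index=probe_ids, columns=cols), "PLAT")
    rows = [
        dict(
            sample_id=c,
            experiment_id="e1",
            platform_id="PLAT",
            chemical="A",
            dose="1x",
            tissue="liver",
            sex="M",
            duration="24hr",
            role="treated" if c.startswith("T") else "control",
            control_group_id="g1",
            design="one_color",
        )
        for c in cols
    ]
    return matrix, fc.SampleTable(pd.DataFrame(rows)), cols[:n_treated]


@pytest.fixture(scope="session")
def small_study():
    """A compact strong-effect study every condition of which yields a signature."""
    cfg = fc.SimConfig(
        n_probes=1500,
        module_size=40,
        effect_size=2.0,
        chemicals=(
            ("E2", "ER agonist"),
            ("EE2", "ER agonist"),
            ("FIP", "GABA antagonist"),
            ("MUS", "GABA antagonist"),
        ),
        platform_id="SIM1K5",
    )
    matrix, samples, truth = fc.simulate_study(cfg, seed=101)
    return cfg, matrix, samples, truth
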