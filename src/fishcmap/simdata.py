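"""Synthetic multi-chemical expression studies with planted MOA structure.

The generator emulates the data regime of multi-laboratory fish microarray
studies: a platform of N probes with lognormal-like baseline intensities
(log2-scale Normal(8, 2) probe means), additive Gaussian noise per sample,
and per-chemical differential-expression modules.  Chemicals belong to MOA
classes; chemicals in the same class perturb a shared core of module probes
with identical signs (the overlap fraction) plus chemical-specific probes,
so that signature queries can recover both self-connections and same-class
connections against the noise.

Dose is modeled as a linear multiplier on the log2 effect size.  The
generator is deterministic given its seed; a Student-t noise flag provides
heavier tails for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .iodata import ExpressionMatrix, MOATable, SampleTable, ValidationError
from .crossmap import MappingTable

#: Default chemical -> MOA class panel: three classes of three chemicals,
#: echoing estrogen-receptor agonists, aryl-hydrocarbon-receptor-activating
#: PAHs, and GABA-receptor-targeting neurotoxicants.
DEFAULT_CHEMICALS: tuple[tuple[str, str], ...] = (
    ("E2", "ER agonist"),
    ("EE2", "ER agonist"),
    ("DES", "ER agonist"),
    ("TCDD", "AhR agonist"),
    ("BAA", "AhR agonist"),
    ("PHE", "AhR agonist"),
    ("FIP", "GABA antagonist"),
    ("MUS", "GABA agonist2"),
    ("DIA", "GABA antagonist"),
)


@dataclass
class SimConfig:
    """Study-design parameters for :func:`simulate_study`.

    Defaults describe one tissue, one dose, 4 treated vs 4 control replicate
    fish per condition on a 10,000-probe platform, a 100-probe DE module per
    chemical with 60 % of the module shared within an MOA class, a log2
    effect size of 1.0 and per-sample noise SD of 0.5 log2 units.
    """

    n_probes: int = 10_000
    chemicals: tuple[tuple[str, str], ...] = DEFAULT_CHEMICALS
    module_size: int = 100
    class_overlap: float = 0.6
    effect_size: float = 1.0
    dose_multipliers: tuple[float, ...] = (1.0,)
    n_treated: int = 4
    n_control: int = 4
    noise_sd: float = 0.5
    tissues: tuple[str, ...] = ("liver",)
    design: str = "one_color"
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_df: float | None = None  # Student-t noise when set
    sex: str = "M"
    duration: str = "48hr"
    platform_id: str = "SIM10K"

    def __post_init__(self) -> None:
        if not 0.0 <= self.class_overlap <= 1.0:
            raise ValidationError("class_overlap must lie in [0, 1]")
        if self.module_size > self.n_probes:
            raise ValidationError("module_size cannot exceed n_probes")
        if min(self.n_treated, self.n_control) < 1:
            raise ValidationError("replicate counts must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.design != "one_color":
            raise ValidationError("only the one_color design is simulated")
        if not self.chemicals:
            raise ValidationError("at least one chemical required")
        names = [c for c, _ in self.chemicals]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chemical names")
        # disjoint class modules must fit on the platform
        per_class: dict[str, int] = {}
        for _, cls in self.chemicals:
            per_class[cls] = per_class.get(cls, 0) + 1
        core = int(round(self.class_overlap * self.module_size))
        needed = sum(
            core + cnt * (self.module_size - core) for cnt in per_class.values()
        )
        if needed > self.n_probes:
            raise ValidationError(
                f"module layout needs {needed} probes but the platform has {self.n_probes}"
            )


@dataclass
class GroundTruth:
    """Planted differential-expression modules per condition."""

    modules: dict[str, dict] = field(default_factory=dict)
    chemical_class: dict[str, str] = field(default_factory=dict)

    def probes(self, condition: str) -> np.ndarray:
        return self.modules[condition]["probe_ids"]

    def signs(self, condition: str) -> np.ndarray:
        return self.modules[condition]["signs"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, mod in sorted(self.modules.items()):
            for pid, sign, eff in zip(mod["probe_ids"], mod["signs"], mod["effects"]):
                rows.append((cond, mod["chemical"], pid, int(sign), float(eff)))
        return pd.DataFrame(
            rows, columns=["condition", "chemical", "probe_id", "sign", "effect"]
        )


def moa_table(cfg: SimConfig) -> MOATable:
    """The planted chemical -> MOA class table for a configuration."""
    return MOATable(classes={chem: frozenset({cls}) for chem, cls in cfg.chemicals})


def simulate_study(
    cfg: SimConfig, seed: int
) -> tuple[ExpressionMatrix, SampleTable, GroundTruth]:
    """Generate (matrix, samples, truth) for one synthetic multi-chemical study.

    Every condition (chemical x dose x tissue) gets its own experiment ID and
    its own control group of ``n_control`` samples; treated samples
    additionally shift their chemical's module probes by
    ``sign * effect_size * dose multiplier`` on the log2 scale.  Identical
    configuration and seed reproduce byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_probes
    probe_ids = np.array([f"P{i:06d}" for i in range(1, n + 1)], dtype=object)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)

    # carve disjoint per-class pools: shared core + per-chemical unique probes
    by_class: dict[str, list[str]] = {}
    for chem, cls in cfg.chemicals:
        by_class.setdefault(cls, []).append(chem)
    core_size = int(round(cfg.class_overlap * cfg.module_size))
    uniq_size = cfg.module_size - core_size
    pool = rng.permutation(n)
    cursor = 0
    truth = GroundTruth(chemical_class={chem: cls for chem, cls in cfg.chemicals})
    chem_module: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cls in sorted(by_class):
        core_idx = pool[cursor : cursor + core_size]
        cursor += core_size
        core_signs = rng.choice((-1, 1), size=core_size)
        for chem in by_class[cls]:
            uniq_idx = pool[cursor : cursor + uniq_size]
            cursor += uniq_size
            uniq_signs = rng.choice((-1, 1), size=uniq_size)
            idx = np.concatenate([core_idx, uniq_idx]).astype(int)
            signs = np.concatenate([core_signs, uniq_signs]).astype(int)
            chem_module[chem] = (idx, signs)

    def noise(size: tuple[int, ...]) -> np.ndarray:
        if cfg.noise_df is not None:
            return rng.standard_t(cfg.noise_df, size=size) * cfg.noise_sd
        return rng.normal(0.0, cfg.noise_sd, size=size)

    columns: dict[str, np.ndarray] = {}
    rows = []
    for chem, cls in cfg.chemicals:
        for tissue in cfg.tissues:
            for mult in cfg.dose_multipliers:
                dose = f"{mult:g}x"
                cond = f"{chem}_{dose}_{tissue}"
                exp_id = f"exp_{cond}"
                group = f"ctrl_{cond}"
                for j in range(cfg.n_control):
                    sid = f"{cond}_C{j + 1}"
                    columns[sid] = baseline + noise((n,))
                    rows.append((sid, exp_id, "control", group, chem, dose, tissue))
                idx, signs = chem_module[chem]
                effect = np.zeros(n)
                effect[idx] = signs * cfg.effect_size * mult
                for j in range(cfg.n_treated):
                    sid = f"{cond}_T{j + 1}"
                    columns[sid] = baseline + effect + noise((n,))
                    rows.append((sid, exp_id, "treated", group, chem, dose, tissue))
                truth.modules[cond] = {
                    "chemical": chem,
                    "probe_ids": probe_ids[idx],
                    "signs": signs.copy(),
                    "effects": np.abs(effect[idx]),
                }
    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=probe_ids), platform_id=cfg.platform_id
    )
    meta_rows = []
    for sid, exp_id, role, group, chem_, dose_, tissue_ in rows:
        meta_rows.append(
            {
                "sample_id": sid,
                "experiment_id": exp_id,
                "platform_id": cfg.platform_id,
                "chemical": chem_,
                "dose": dose_,
                "tissue": tissue_,
                "sex": cfg.sex,
                "duration": cfg.duration,
                "role": role,
                "control_group_id": group,
                "design": cfg.design,
                "pair_id": "",
                "dye_swap": "0",
            }
        )
    samples = SampleTable(pd.DataFrame(meta_rows))
    return matrix, samples, truth


def make_ortholog_fixture(
    n_source: int,
    n_target: int,
    frac_1to1: float,
    frac_1tomany: float = 0.0,
    targets_per_source: int = 3,
    seed: int = 0,
) -> MappingTable:
    """A synthetic probe-orthology table with controlled coverage.

    ``frac_1to1`` of the source probes map one-to-one to distinct targets;
    ``frac_1tomany`` map to ``targets_per_source`` distinct targets each
    (sharing one gene ID); the rest stay unmapped — mirroring the partial
    cross-platform coverage (roughly 37-65 %) typical of real probe
    orthology.  Deterministic given the seed.
    """
    if frac_1to1 < 0 or frac_1tomany < 0 or frac_1to1 + frac_1tomany > 1.0 + 1e-12:
        raise ValidationError("mapping fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    n_one = int(round(frac_1to1 * n_source))
    n_many = int(round(frac_1tomany * n_source))
    targets_needed = n_one + n_many * targets_per_source
    if targets_needed > n_target:
        raise ValidationError(
            f"mapping needs {targets_needed} target probes but only {n_target} exist"
        )
    src_ids = [f"S{i:06d}" for i in range(1, n_source + 1)]
    tgt_ids = [f"T{i:06d}" for i in range(1, n_target + 1)]
    src_order = rng.permutation(n_source)
    tgt_order = rng.permutation(n_target)
    rows = []
    gene = 0
    t_cursor = 0
    for k in range(n_one):
        gene += 1
        rows.append((src_ids[src_order[k]], tgt_ids[tgt_order[t_cursor]], f"g{gene:06d}"))
        t_cursor += 1
    for k in range(n_one, n_one + n_many):
        gene += 1
        for _ in range(targets_per_source):
            rows.append(
                (src_ids[src_order[k]], tgt_ids[tgt_order[t_cursor]], f"g{gene:06d}")
            )
            t_cursor += 1
    return MappingTable(
        table=pd.DataFrame(rows, columns=["source_probe", "target_probe", "gene_id"])
    )
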