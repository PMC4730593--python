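"""LogFC profiles and signed rank-ordered gene lists (ROGLs).

A ROGL re-expresses one treated sample's log2 fold-changes against its
control reference as a complete signed permutation of the platform's probes:
probes are sorted by |LogFC| ascending and assigned ranks 1..N in that order,
each rank carrying the sign of the probe's LogFC.  Probes with the weakest
response therefore occupy the lowest ranks, where they contribute least to
any connectivity score.

Tie-breaking is a stable ascending sort with a lexicographic probe-ID
tiebreak; a LogFC of exactly zero is given a positive sign.  Both choices are
arbitrary but fixed, so ROGLs are bit-reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .iodata import ExpressionMatrix, SampleTable, ValidationError

META_FIELDS = ("chemical", "dose", "sex", "tissue", "duration", "experiment_id")


@dataclass(frozen=True)
class ConditionMeta:
    """Treatment-condition metadata attached to profiles, ROGLs, signatures."""

    chemical: str = ""
    dose: str = ""
    sex: str = ""
    tissue: str = ""
    duration: str = ""
    experiment_id: str = ""

    def label(self) -> str:
        """Condition name in the order chemical, dose, sex, tissue, duration."""
        parts = [self.chemical, self.dose, self.sex, self.tissue, self.duration]
        return "_".join(p for p in parts if p)

    @classmethod
    def from_sample(cls, samples: SampleTable, sample_id: str) -> "ConditionMeta":
        return cls(**samples.condition(sample_id))


@dataclass
class LogFCProfile:
    """Per-probe log2 fold-change of one treated sample vs its control reference."""

    probe_ids: np.ndarray
    logfc: np.ndarray
    meta: ConditionMeta
    sample_id: str = ""
    platform_id: str = ""

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.logfc = np.asarray(self.logfc, dtype=float)
        if self.probe_ids.shape != self.logfc.shape:
            raise ValidationError("probe_ids and logfc must have equal length")

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.logfc)))


@dataclass
class ROGL:
    """A complete signed rank permutation of the (non-missing) probes.

    ``signed_rank[i]`` is in {-N..-1, +1..+N}; the multiset of absolute ranks
    is exactly {1..N}.
    """

    probe_ids: np.ndarray
    signed_rank: np.ndarray
    meta: ConditionMeta
    sample_id: str = ""
    platform_id: str = ""

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.signed_rank = np.asarray(self.signed_rank, dtype=int)
        n = len(self.signed_rank)
        if sorted(np.abs(self.signed_rank)) != list(range(1, n + 1)):
            raise ValidationError("signed ranks must be a signed permutation of 1..N")

    @property
    def n(self) -> int:
        return len(self.signed_rank)

    def rank_series(self) -> pd.Series:
        return pd.Series(self.signed_rank, index=self.probe_ids)


@dataclass
class ROGLSet:
    """ROGLs grouped by shared experimental parameters (e.g. chemical+tissue)."""

    set_id: str
    members: list[ROGL]
    key_values: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"ROGL set {self.set_id!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)

    def experiment_ids(self) -> set[str]:
        return {r.meta.experiment_id for r in self.members}

    def consensus(self, fld: str) -> str:
        """The shared value of a metadata field across members, else ''."""
        if fld in self.key_values:
            return self.key_values[fld]
        vals = {getattr(r.meta, fld) for r in self.members}
        return vals.pop() if len(vals) == 1 else ""


def compute_logfc(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    treated_id: str,
    control_average: str = "log",
) -> LogFCProfile:
    """Log2 fold-change of a treated sample over its control reference.

    One-color and two-color-common-reference designs subtract the mean of the
    control/reference group from the treated sample; a two-color direct
    design subtracts the single paired control hybridized on the same array,
    with the sign flipped when the pair is a dye swap.

    ``control_average`` selects how the control group is averaged: ``"log"``
    (arithmetic mean of log2 values, i.e. geometric mean of intensities, the
    default) or ``"intensity"`` (mean of 2**x back-transformed to log2).
    Probes missing in the treated sample or in every control are returned as
    NaN and later excluded from ranking.
    """
    if control_average not in ("log", "intensity"):
        raise ValidationError(f"unknown control_average {control_average!r}")
    row = samples.row(treated_id)
    if row["role"] != "treated":
        raise ValidationError(f"sample {treated_id!r} has role {row['role']!r}, not treated")
    if treated_id not in matrix.sample_ids:
        raise ValidationError(f"treated sample {treated_id!r} absent from matrix")
    control_ids = samples.controls_for(treated_id)
    control_ids = [c for c in control_ids if c in matrix.sample_ids]
    if not control_ids:
        raise ValidationError(f"no control measurements in matrix for sample {treated_id!r}")
    treated = matrix.data[treated_id].to_numpy(dtype=float)
    controls = matrix.data[control_ids].to_numpy(dtype=float)
    if row["design"] == "two_color_direct":
        ref = controls[:, 0]
    elif control_average == "log":
        ref = np.nanmean(controls, axis=1)
    else:
        ref = np.log2(np.nanmean(np.exp2(controls), axis=1))
    logfc = treated - ref
    if row["design"] == "two_color_direct" and row["dye_swap"]:
        logfc = -logfc
    return LogFCProfile(
        probe_ids=matrix.probe_ids.to_numpy(dtype=object),
        logfc=logfc,
        meta=ConditionMeta.from_sample(samples, treated_id),
        sample_id=treated_id,
        platform_id=matrix.platform_id,
    )


def build_rogl(profile: LogFCProfile) -> ROGL:
    """Rank probes by ascending |LogFC| and sign each rank by its direction.

    Missing probes are excluded; the ROGL then covers the remaining N'
    probes.  Zero LogFC gets a positive sign; ties in |LogFC| break by
    lexicographic probe ID.
    """
    finite = np.isfinite(profile.logfc)
    if not finite.any():
        raise ValidationError(f"profile {profile.sample_id!r}: all probes missing")
    pids = profile.probe_ids[finite]
    lfc = profile.logfc[finite]
    order = np.lexsort((pids.astype(str), np.abs(lfc)))
    n = len(order)
    signed = np.empty(n, dtype=int)
    ranks = np.arange(1, n + 1)
    signs = np.where(lfc[order] < 0, -1, 1)
    signed[order] = ranks * signs
    return ROGL(
        probe_ids=pids,
        signed_rank=signed,
        meta=profile.meta,
        sample_id=profile.sample_id,
        platform_id=profile.platform_id,
    )


def build_rogls(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    treated_ids: Sequence[str] | None = None,
    control_average: str = "log",
) -> list[ROGL]:
    """Convenience: one ROGL per treated sample present in the matrix."""
    if treated_ids is None:
        treated_ids = [t for t in samples.treated_ids() if t in matrix.sample_ids]
    return [
        build_rogl(compute_logfc(matrix, samples, t, control_average=control_average))
        for t in treated_ids
    ]


def group_rogls(rogls: Sequence[ROGL], keys: Sequence[str] = ("chemical",)) -> list[ROGLSet]:
    """Partition ROGLs into sets by shared metadata field values.

    An empty key list yields a single set containing everything.  The number
    of resulting sets S is the denominator of the critical p-value 1/S.
    """
    for k in keys:
        if k not in META_FIELDS:
            raise ValidationError(f"unknown grouping key {k!r}; allowed: {list(META_FIELDS)}")
    groups: dict[tuple[str, ...], list[ROGL]] = {}
    for rogl in rogls:
        kv = tuple(getattr(rogl.meta, k) for k in keys)
        groups.setdefault(kv, []).append(rogl)
    sets = []
    for kv in sorted(groups):
        set_id = "|".join(kv) if kv else "all"
        sets.append(
            ROGLSet(set_id=set_id, members=groups[kv], key_values=dict(zip(keys, kv)))
        )
    return sets
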