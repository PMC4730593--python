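"""Cross-platform / cross-species signature translation.

A query signature built on one microarray platform interrogates another
platform's ROGLs by substituting its probe IDs with equivalent or
orthologous probe IDs on the target platform, while keeping the source
log-fold-changes and direction signs.  The probe-to-probe mapping (typically
derived upstream from shared gene IDs) is an input table and may be
many-to-many.

Many-to-many resolution is conservative: every source probe expands to all
its targets, duplicate targets collapse to the source record with the
largest |LogFC|, and a target receiving conflicting signs from different
source probes is dropped rather than assigned a fabricated direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .iodata import ValidationError
from .signature import NoSignatureError, Signature

POLICIES = ("conservative",)


@dataclass
class MappingTable:
    """Rows of (source_probe, target_probe, shared gene_id); set semantics."""

    table: pd.DataFrame
    source_platform: str = ""
    target_platform: str = ""

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("source_probe", "target_probe", "gene_id"):
            if col not in df.columns:
                raise ValidationError(f"mapping table missing column {col!r}")
            df[col] = df[col].astype(str)
        if ((df["source_probe"] == "") | (df["target_probe"] == "")).any():
            raise ValidationError("mapping table has empty probe ID(s)")
        self.table = df.drop_duplicates().reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


class MappingCoverage(NamedTuple):
    n_source_mapped: int
    n_target_mapped: int
    n_shared_genes: int


def mapping_coverage(mapping: MappingTable) -> MappingCoverage:
    """Distinct counts of mapped source probes, target probes, and gene IDs."""
    t = mapping.table
    return MappingCoverage(
        n_source_mapped=t["source_probe"].nunique(),
        n_target_mapped=t["target_probe"].nunique(),
        n_shared_genes=t["gene_id"].nunique(),
    )


def translate_signature(
    sig: Signature,
    mapping: MappingTable,
    policy: str = "conservative",
    min_size: int = 4,
    max_size: int = 500,
) -> Signature:
    """Swap a signature's probe IDs into the target platform.

    Each signature probe expands to all of its target probes, carrying the
    source sign, LogFC and FDR.  Duplicate targets collapse to the source
    with the largest |LogFC| (ties: lexicographic source probe); targets
    receiving conflicting signs are dropped.  The result is re-ranked by
    source FDR and truncated at ``max_size``; fewer than ``min_size``
    surviving probes raises :class:`NoSignatureError`.
    """
    if policy not in POLICIES:
        raise ValidationError(f"unknown translation policy {policy!r}; allowed: {list(POLICIES)}")
    if mapping.source_platform and sig.platform_id and mapping.source_platform != sig.platform_id:
        raise ValidationError(
            f"mapping source platform {mapping.source_platform!r} does not match "
            f"signature platform {sig.platform_id!r}"
        )
    src = pd.DataFrame(
        {
            "source_probe": sig.probe_ids.astype(str),
            "sign": sig.signs,
            "logfc": sig.logfc,
            "fdr": sig.fdr,
            "src_order": np.arange(sig.m),
        }
    )
    expanded = src.merge(mapping.table, on="source_probe", how="inner")
    if expanded.empty:
        raise NoSignatureError(
            f"signature {sig.name!r}: no probes map to platform "
            f"{mapping.target_platform or 'target'!r}"
        )
    kept = []
    for target, grp in expanded.groupby("target_probe", sort=True):
        if grp["sign"].nunique() > 1:
            continue  # conflicting direction: drop rather than fabricate
        grp = grp.sort_values(
            ["logfc", "source_probe"],
            key=lambda s: -s.abs() if s.name == "logfc" else s,
            kind="stable",
        )
        kept.append(grp.iloc[0])
    if len(kept) < min_size:
        raise NoSignatureError(
            f"signature {sig.name!r}: {len(kept)} probes after translation; "
            f"minimum signature size is {min_size}"
        )
    out = pd.DataFrame(kept).sort_values(["fdr", "src_order"], kind="stable").head(max_size)
    return Signature(
        name=f"{sig.name}.IDswap" if sig.name else "IDswap",
        platform_id=mapping.target_platform,
        probe_ids=out["target_probe"].to_numpy(dtype=object),
        signs=out["sign"].to_numpy(dtype=int),
        logfc=out["logfc"].to_numpy(dtype=float),
        fdr=out["fdr"].to_numpy(dtype=float),
        meta=sig.meta,
    )
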