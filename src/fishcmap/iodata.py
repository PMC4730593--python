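"""Readers and writers for every on-disk artifact.

All tabular artifacts are plain TSV with the literal string ``NA`` for
missing values.  Expression matrices are assumed to be already
log2-normalized (normalization is upstream of this package).  Networks are
exported as SIF, GraphML, or an edge TSV; signatures additionally as GMT.

Every writer/reader pair is a lossless round trip on valid inputs: probe and
sample identifiers compare as exact strings and numeric values are written
with full ``repr`` precision.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "NA"

DESIGNS = ("one_color", "two_color_direct", "two_color_reference")
ROLES = ("treated", "control", "reference")

SAMPLE_COLUMNS = (
    "sample_id",
    "experiment_id",
    "platform_id",
    "chemical",
    "dose",
    "tissue",
    "sex",
    "duration",
    "role",
    "control_group_id",
    "design",
    "pair_id",
    "dye_swap",
)


class FishCmapError(Exception):
    """Base class for all package errors."""


class ValidationError(FishCmapError):
    """An input violated a structural invariant."""


class FormatError(FishCmapError):
    """A file could not be parsed as the expected format."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A probe x sample matrix of log2-scale intensities or ratios.

    ``data`` is indexed by probe ID with sample IDs as columns; missing
    measurements are ``NaN``.  ``platform_id`` labels the microarray design
    the probes belong to (e.g. ``ZF21K``); its probe count N is the
    denominator for relative transcriptome impact and the maximum rank of a
    rank-ordered gene list.
    """

    data: pd.DataFrame
    platform_id: str = ""

    def __post_init__(self) -> None:
        idx = pd.Index(self.data.index.astype(str))
        cols = pd.Index(self.data.columns.astype(str))
        for name, ids in (("probe", idx), ("sample", cols)):
            dup = ids[ids.duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {name} ID(s): {sorted(set(dup))}")
        self.data = self.data.copy()
        self.data.index = idx
        self.data.columns = cols
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]


def read_expression_matrix(path: str | os.PathLike, platform_id: str = "") -> ExpressionMatrix:
    """Read a TSV with a header row of sample IDs and probe IDs in column 1.

    Missing cells must be the literal ``NA``.  Duplicate probe/sample IDs and
    non-numeric cells are hard errors naming the offender.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected a header with at least one sample column")
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample ID in header: {sid!r}")
        seen.add(sid)
    raw = pd.read_csv(
        path,
        sep="\t",
        skiprows=1,
        header=None,
        index_col=0,
        na_values=[MISSING],
        keep_default_na=False,
        dtype=str,
    )
    raw.columns = sample_ids
    raw.index = raw.index.astype(str)
    raw.index.name = None
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate probe ID(s): {sorted(set(dup))}")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at probe "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    return ExpressionMatrix(numeric, platform_id=platform_id)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = matrix.data
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(df.columns) + "\n")
        for pid, row in zip(df.index, df.to_numpy()):
            cells = [MISSING if not math.isfinite(v) else repr(float(v)) for v in row]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Per-sample experimental metadata.

    Each treated sample must resolve to at least one control/reference sample
    under its design: one-color and two-color-with-common-reference designs
    resolve through ``control_group_id``; two-color direct designs resolve
    through ``pair_id`` to exactly one control hybridized on the same array.
    Extra columns are preserved as opaque annotations.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in SAMPLE_COLUMNS[:11] if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing column(s): {missing}")
        if "pair_id" not in df.columns:
            df["pair_id"] = ""
        if "dye_swap" not in df.columns:
            df["dye_swap"] = False
        for col in df.columns:
            if col == "dye_swap":
                df[col] = df[col].map(_parse_bool)
            else:
                df[col] = df[col].astype(str).replace("nan", "").replace(MISSING, "")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample ID(s): {sorted(set(dup))}")
        df = df.set_index("sample_id", drop=False)
        bad_design = sorted(set(df["design"]) - set(DESIGNS))
        if bad_design:
            raise ValidationError(
                f"unknown design value(s) {bad_design}; allowed: {list(DESIGNS)}"
            )
        bad_role = sorted(set(df["role"]) - set(ROLES))
        if bad_role:
            raise ValidationError(f"unknown role value(s) {bad_role}; allowed: {list(ROLES)}")
        empty_exp = df.index[df["experiment_id"] == ""]
        if len(empty_exp):
            raise ValidationError(f"empty experiment_id for sample(s): {list(empty_exp)}")
        self.data = df
        unresolved = [
            sid for sid in self.treated_ids() if len(self.controls_for(sid, strict=False)) == 0
        ]
        if unresolved:
            raise ValidationError(
                f"treated sample(s) with unresolvable control group: {unresolved}"
            )

    def __len__(self) -> int:
        return len(self.data)

    def treated_ids(self) -> list[str]:
        return list(self.data.index[self.data["role"] == "treated"])

    def row(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.index:
            raise ValidationError(f"unknown sample ID: {sample_id!r}")
        return self.data.loc[sample_id]

    def controls_for(self, sample_id: str, strict: bool = True) -> list[str]:
        """Control/reference sample IDs for a treated sample under its design."""
        row = self.row(sample_id)
        df = self.data
        if row["design"] == "two_color_direct":
            hits = df.index[
                (df["pair_id"] == row["pair_id"])
                & (df["pair_id"] != "")
                & (df["role"] == "control")
            ]
            if strict and len(hits) != 1:
                raise ValidationError(
                    f"two_color_direct sample {sample_id!r} must pair with exactly one "
                    f"control via pair_id {row['pair_id']!r}; found {len(hits)}"
                )
            return list(hits)
        hits = df.index[
            (df["control_group_id"] == row["control_group_id"])
            & (df["control_group_id"] != "")
            & (df["role"].isin(("control", "reference")))
        ]
        return list(hits)

    def condition(self, sample_id: str) -> dict[str, str]:
        row = self.row(sample_id)
        return {
            k: str(row[k])
            for k in ("chemical", "dose", "sex", "tissue", "duration", "experiment_id")
        }


def _parse_bool(v: object) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    return s in ("1", "true", "yes", "t")


def read_sample_table(path: str | os.PathLike) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    return SampleTable(df.fillna(""))


def write_sample_table(samples: SampleTable, path: str | os.PathLike) -> None:
    df = samples.data.copy()
    df["dye_swap"] = df["dye_swap"].map(lambda b: "1" if b else "0")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Chemical MOA annotations
# ---------------------------------------------------------------------------


@dataclass
class MOATable:
    """Chemical -> mechanism-of-action class labels, plus free-text MIE.

    ``similar`` holds unordered pairs of class labels declared functionally
    similar (e.g. anti-androgens vs ER agonists); two chemicals count as
    sharing a class if they have a label in common or a declared-similar pair
    of labels.
    """

    classes: dict[str, frozenset[str]]
    mie: dict[str, str] = field(default_factory=dict)
    similar: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for chem, cls in self.classes.items():
            if not cls:
                raise ValidationError(f"chemical {chem!r} has no MOA class")

    def classes_for(self, chemical: str) -> frozenset[str]:
        return self.classes.get(chemical, frozenset())

    def share_class(self, chem_a: str, chem_b: str) -> bool:
        a, b = self.classes_for(chem_a), self.classes_for(chem_b)
        if a & b:
            return True
        return any(frozenset((x, y)) in self.similar for x in a for y in b)


def read_moa_table(
    path: str | os.PathLike, similarity_path: str | os.PathLike | None = None
) -> MOATable:
    """Read a TSV with columns chemical, moa_class (``;``-separated), [mie].

    ``similarity_path`` optionally names a two-column TSV (class_a, class_b)
    of class labels to treat as similar.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    for col in ("chemical", "moa_class"):
        if col not in df.columns:
            raise ValidationError(f"{path}: MOA table missing column {col!r}")
    dup = df["chemical"][df["chemical"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate chemical(s): {sorted(set(dup))}")
    classes: dict[str, frozenset[str]] = {}
    mie: dict[str, str] = {}
    for _, row in df.iterrows():
        labels = frozenset(s.strip() for s in str(row["moa_class"]).split(";") if s.strip())
        if not labels:
            raise ValidationError(f"{path}: chemical {row['chemical']!r} has no MOA class")
        classes[str(row["chemical"])] = labels
        if "mie" in df.columns and str(row.get("mie", "")):
            mie[str(row["chemical"])] = str(row["mie"])
    similar: set[frozenset[str]] = set()
    if similarity_path is not None:
        sim = pd.read_csv(similarity_path, sep="\t", dtype=str)
        for col in ("class_a", "class_b"):
            if col not in sim.columns:
                raise ValidationError(f"{similarity_path}: missing column {col!r}")
        for _, row in sim.iterrows():
            similar.add(frozenset((str(row["class_a"]), str(row["class_b"]))))
    return MOATable(classes=classes, mie=mie, similar=similar)


def write_moa_table(moa: MOATable, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chemical\tmoa_class\tmie\n")
        for chem in sorted(moa.classes):
            fh.write(
                f"{chem}\t{';'.join(sorted(moa.classes[chem]))}\t{moa.mie.get(chem, '')}\n"
            )


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------


def write_signature(sig, path: str | os.PathLike) -> None:
    """Write a signature TSV: ``#`` header lines then probe rows."""
    meta = sig.meta
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#name\t{sig.name}\n")
        fh.write(f"#platform\t{sig.platform_id}\n")
        fh.write(f"#m\t{sig.m}\n")
        if meta is not None:
            fh.write(
                "#condition\t"
                + "\t".join(
                    str(getattr(meta, k))
                    for k in ("chemical", "dose", "sex", "tissue", "duration", "experiment_id")
                )
                + "\n"
            )
        fh.write("probe_id\tsign\tlogfc\tfdr\n")
        for pid, sign, lfc, fdr in zip(sig.probe_ids, sig.signs, sig.logfc, sig.fdr):
            fdr_s = MISSING if not math.isfinite(fdr) else repr(float(fdr))
            fh.write(f"{pid}\t{int(sign):+d}\t{float(lfc)!r}\t{fdr_s}\n")


def read_signature(path: str | os.PathLike):
    from .signature import Signature
    from .rogl import ConditionMeta

    name = platform = ""
    meta = None
    rows: list[tuple[str, int, float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts[0] == "name":
                    name = parts[1]
                elif parts[0] == "platform":
                    platform = parts[1] if len(parts) > 1 else ""
                elif parts[0] == "condition" and len(parts) >= 7:
                    meta = ConditionMeta(*parts[1:7])
                continue
            if not header_seen:
                if line.split("\t")[0] != "probe_id":
                    raise FormatError(f"{path}: expected signature column header, got {line!r}")
                header_seen = True
                continue
            pid, sign, lfc, fdr = line.split("\t")[:4]
            rows.append(
                (
                    pid,
                    int(sign),
                    float(lfc),
                    math.nan if fdr == MISSING else float(fdr),
                )
            )
    if not rows:
        raise FormatError(f"{path}: signature file contains no probes")
    return Signature(
        name=name,
        platform_id=platform,
        probe_ids=np.array([r[0] for r in rows], dtype=object),
        signs=np.array([r[1] for r in rows], dtype=int),
        logfc=np.array([r[2] for r in rows], dtype=float),
        fdr=np.array([r[3] for r in rows], dtype=float),
        meta=meta,
    )


def write_signatures_gmt(signatures: Iterable, path: str | os.PathLike) -> None:
    """GMT export: one set per line — name, description, probes with +/- suffix."""
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            probes = [
                f"{pid}{'+' if s > 0 else '-'}" for pid, s in zip(sig.probe_ids, sig.signs)
            ]
            fh.write("\t".join([sig.name, f"platform={sig.platform_id}"] + probes) + "\n")


# ---------------------------------------------------------------------------
# ROGL stores
# ---------------------------------------------------------------------------


def write_rogl_store(rogl_sets: Sequence, out_dir: str | os.PathLike) -> None:
    """Write a directory store: index.json plus one TSV per ROGL.

    The index records the set structure, per-ROGL condition metadata, the
    number of sets S (the denominator of the significance cutoff) and each
    ROGL's probe count N.  Individual ROGL files are sorted by descending
    absolute signed rank for human inspection.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    index: dict = {"sets": [], "S": len(rogl_sets)}
    counter = 0
    for rset in rogl_sets:
        entry = {"set_id": rset.set_id, "key_values": dict(rset.key_values), "members": []}
        for rogl in rset.members:
            fname = f"rogl_{counter:05d}.tsv"
            counter += 1
            order = np.argsort(-np.abs(rogl.signed_rank), kind="stable")
            with open(os.path.join(out_dir, fname), "w", encoding="utf-8") as fh:
                fh.write("probe_id\tsigned_rank\n")
                for i in order:
                    fh.write(f"{rogl.probe_ids[i]}\t{int(rogl.signed_rank[i]):+d}\n")
            m = rogl.meta
            entry["members"].append(
                {
                    "file": fname,
                    "sample_id": rogl.sample_id,
                    "platform_id": rogl.platform_id,
                    "n": int(rogl.n),
                    "condition": {
                        "chemical": m.chemical,
                        "dose": m.dose,
                        "sex": m.sex,
                        "tissue": m.tissue,
                        "duration": m.duration,
                        "experiment_id": m.experiment_id,
                    },
                }
            )
        index["sets"].append(entry)
    with open(os.path.join(out_dir, "index.json"), "w", encoding="utf-8") as fh:
        json.dump(index, fh, indent=1, sort_keys=True)


def read_rogl_store(in_dir: str | os.PathLike) -> list:
    from .rogl import ConditionMeta, ROGL, ROGLSet

    in_dir = os.fspath(in_dir)
    with open(os.path.join(in_dir, "index.json"), "r", encoding="utf-8") as fh:
        index = json.load(fh)
    sets: list[ROGLSet] = []
    for entry in index["sets"]:
        members = []
        for mem in entry["members"]:
            df = pd.read_csv(os.path.join(in_dir, mem["file"]), sep="\t", dtype=str)
            members.append(
                ROGL(
                    probe_ids=df["probe_id"].to_numpy(dtype=object),
                    signed_rank=df["signed_rank"].astype(int).to_numpy(),
                    meta=ConditionMeta(**mem["condition"]),
                    sample_id=mem["sample_id"],
                    platform_id=mem.get("platform_id", ""),
                )
            )
        sets.append(
            ROGLSet(set_id=entry["set_id"], members=members, key_values=entry["key_values"])
        )
    return sets


# ---------------------------------------------------------------------------
# Connection results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "signature",
    "set_id",
    "n_rogls",
    "m",
    "score",
    "p_value",
    "critical_p",
    "significant",
    "self",
    "rank",
)


def write_results_table(results: Sequence, path: str | os.PathLike) -> None:
    """Write connection results, sorted by score descending then set_id."""
    rows = sorted(results, key=lambda r: (-r.score, r.signature, r.set_id))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.signature,
                        r.set_id,
                        str(r.n_rogls),
                        str(r.m),
                        repr(float(r.score)),
                        repr(float(r.p_value)),
                        repr(float(r.critical_p)),
                        "1" if r.significant else "0",
                        "1" if r.self else "0",
                        str(r.rank),
                    ]
                )
                + "\n"
            )


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"signature": str, "set_id": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: results table missing column(s): {missing}")
    return df


# ---------------------------------------------------------------------------
# Mapping tables
# ---------------------------------------------------------------------------


def read_mapping_table(
    path: str | os.PathLike, source_platform: str = "", target_platform: str = ""
):
    from .crossmap import MappingTable

    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    for col in ("source_probe", "target_probe", "gene_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: mapping table missing column {col!r}")
    return MappingTable(
        table=df[["source_probe", "target_probe", "gene_id"]],
        source_platform=source_platform,
        target_platform=target_platform,
    )


def write_mapping_table(mapping, path: str | os.PathLike) -> None:
    mapping.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def _sorted_edges(graph) -> list[tuple[str, str, dict]]:
    edges = []
    for a, b, attrs in graph.edges(data=True):
        a, b = sorted((a, b))
        edges.append((a, b, attrs))
    edges.sort(key=lambda e: (-float(e[2].get("weight", 0.0)), e[0], e[1]))
    return edges


def export_network(network, path: str | os.PathLike, fmt: str = "tsv") -> None:
    """Export a chemical network as SIF, GraphML, or an edge TSV.

    Row/edge order is deterministic: weight descending, then lexicographic
    node pair.  GraphML carries the edge weight attribute.
    """
    import networkx as nx

    graph = getattr(network, "graph", network)
    fmt = fmt.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValidationError(f"unknown network format {fmt!r}; allowed: {list(NETWORK_FORMATS)}")
    edges = _sorted_edges(graph)
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, attrs in edges:
                fh.write(f"{a}\t{float(attrs.get('weight', 0.0)):g}\t{b}\n")
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\tp_value\tsignature\tset_id\n")
            for a, b, attrs in edges:
                fh.write(
                    "\t".join(
                        [
                            a,
                            b,
                            repr(float(attrs.get("weight", 0.0))),
                            repr(float(attrs.get("p_value", math.nan))),
                            str(attrs.get("signature", "")),
                            str(attrs.get("set_id", "")),
                        ]
                    )
                    + "\n"
                )
    else:
        ordered = nx.Graph()
        ordered.add_nodes_from(sorted(graph.nodes()))
        for a, b, attrs in edges:
            ordered.add_edge(a, b, **attrs)
        nx.write_graphml(ordered, path)


def read_network_tsv(path: str | os.PathLike):
    """Read an edge TSV written by :func:`export_network` back into a network."""
    import networkx as nx

    from .network import ChemicalNetwork

    graph = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["source", "target", "weight"]:
            raise FormatError(f"{path}: not a network edge TSV")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            attrs = {"weight": float(parts[2])}
            if len(parts) >= 6:
                attrs.update(
                    p_value=float(parts[3]), signature=parts[4], set_id=parts[5]
                )
            graph.add_edge(parts[0], parts[1], **attrs)
    return ChemicalNetwork(graph=graph)
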