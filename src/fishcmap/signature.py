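"""Differential expression and query-signature assembly.

Differential probes are called with an empirical-Bayes moderated t-test:
probe-wise residual variances are shrunk toward a pooled prior variance
``s0^2`` with prior degrees of freedom ``d0``, both estimated by fitting a
scaled F distribution to the observed variances via method-of-moments on the
log scale.  With ``d0 = 0`` the statistic reduces to the ordinary two-sample
t; as ``d0 -> inf`` every posterior variance collapses to the prior.  A
plain Welch t is available as a fallback.  Multiple testing is corrected by
Benjamini-Hochberg FDR.

A query signature is the FDR-ranked head of the differential probes: at
least ``min_size`` (default 4) probes are required — conditions below that
are usable only as ROGLs — and at most ``max_size`` (typically 100 within a
platform, 500 across platforms) are retained, each carrying a +/-1 sign and
its source LogFC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .iodata import ExpressionMatrix, FishCmapError, SampleTable, ValidationError
from .rogl import ConditionMeta


class NoSignatureError(FishCmapError):
    """Too few probes pass the cutoff to form a signature."""


@dataclass
class ProbeStats:
    """Per-probe differential statistics for one treatment condition.

    ``table`` is indexed by probe ID with columns logfc, t, p_value, fdr,
    n_treated, n_control.  ``n_probes`` is the platform probe count N used as
    the denominator of relative transcriptome impact.
    """

    table: pd.DataFrame
    n_probes: int
    method: str
    prior_df: float
    prior_var: float
    meta: ConditionMeta | None = None


@dataclass
class Signature:
    """An unordered set of differential probes with direction signs.

    Probes are stored in FDR-ascending order (the selection order), each with
    its +/-1 sign, source log2 fold-change and FDR.
    """

    name: str
    platform_id: str
    probe_ids: np.ndarray
    signs: np.ndarray
    logfc: np.ndarray
    fdr: np.ndarray
    meta: ConditionMeta | None = None

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.signs = np.asarray(self.signs, dtype=int)
        self.logfc = np.asarray(self.logfc, dtype=float)
        self.fdr = np.asarray(self.fdr, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError(f"signature {self.name!r}: duplicate probe IDs")
        if np.any(self.signs == 0):
            raise ValidationError(f"signature {self.name!r}: zero sign")

    @property
    def m(self) -> int:
        return len(self.probe_ids)


@dataclass
class ImpactMetrics:
    """Condition-level summary of transcriptomic impact."""

    n_deg: int
    rti: float
    mean_abs_logfc: float | None


# ---------------------------------------------------------------------------
# Empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_prior_variance(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate (prior_df d0, prior_var s0^2) from probe-wise sample variances.

    Method of moments on log(s^2): under the hierarchical model the residuals
    ``log(s^2) - digamma(df/2) + log(df/2)`` have a variance equal to
    ``trigamma(df/2) + trigamma(d0/2)``, which is inverted for d0; the mean
    then gives s0^2.  A non-positive excess variance means the probe-wise
    variances are no more dispersed than chance, so d0 = inf (complete
    shrinkage to the pooled variance).
    """
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        return math.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_2 = math.exp(emean)
    return d0, s0_2


def _posterior_variance(
    s2: np.ndarray, df: np.ndarray, d0: float, s0_2: float
) -> tuple[np.ndarray, np.ndarray]:
    if math.isinf(d0):
        return np.full_like(s2, s0_2), np.full_like(df, math.inf)
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, df + d0


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaN inputs stay NaN."""
    p = np.asarray(p, dtype=float)
    fdr = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return fdr


# ---------------------------------------------------------------------------
# Differential statistics
# ---------------------------------------------------------------------------


def treated_ids_for_condition(samples: SampleTable, **fields: str) -> list[str]:
    """Treated sample IDs whose metadata matches all given field values."""
    df = samples.data
    mask = df["role"] == "treated"
    for k, v in fields.items():
        if k not in df.columns:
            raise ValidationError(f"unknown sample field {k!r}")
        mask &= df[k] == v
    return list(df.index[mask])


def differential_stats(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    treated_ids: Sequence[str],
    method: str = "moderated",
    prior_df: float | None = None,
    control_average: str = "log",
) -> ProbeStats:
    """Per-probe differential statistics for one treatment condition.

    One-color and common-reference designs are analyzed as a two-group
    comparison of the treated samples against the union of their control/
    reference groups (>= 2 samples each).  Two-color direct designs are
    analyzed as a one-sample t on the (dye-swap-corrected) pair LogFCs
    (>= 2 pairs).  ``prior_df`` overrides the estimated prior degrees of
    freedom of the moderated test (0 recovers the ordinary t).
    """
    if method not in ("moderated", "welch"):
        raise ValidationError(f"unknown method {method!r}")
    treated_ids = list(treated_ids)
    if not treated_ids:
        raise ValidationError("no treated samples given")
    designs = {samples.row(t)["design"] for t in treated_ids}
    if len(designs) != 1:
        raise ValidationError(f"treated samples mix designs: {sorted(designs)}")
    design = designs.pop()
    meta = ConditionMeta.from_sample(samples, treated_ids[0])

    if design == "two_color_direct":
        diffs = []
        for t in treated_ids:
            (ctrl,) = samples.controls_for(t)
            d = matrix.data[t].to_numpy(float) - matrix.data[ctrl].to_numpy(float)
            if samples.row(t)["dye_swap"]:
                d = -d
            diffs.append(d)
        if len(diffs) < 2:
            raise ValidationError(
                "two_color_direct requires >= 2 treated/control pairs for variance estimation"
            )
        d = np.column_stack(diffs)
        n = np.sum(np.isfinite(d), axis=1).astype(float)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(d, axis=1)
            s2 = np.nanvar(d, axis=1, ddof=1)
        df = n - 1.0
        stderr_scale = 1.0 / np.sqrt(n)
        n_treated, n_control = n, n
    else:
        control_ids = sorted(
            {c for t in treated_ids for c in samples.controls_for(t) if c in matrix.sample_ids}
        )
        if len(treated_ids) < 2 or len(control_ids) < 2:
            raise ValidationError(
                "need >= 2 treated and >= 2 control samples for variance estimation; "
                f"got {len(treated_ids)} treated, {len(control_ids)} control"
            )
        x = matrix.data[treated_ids].to_numpy(float)
        y = matrix.data[control_ids].to_numpy(float)
        n1 = np.sum(np.isfinite(x), axis=1).astype(float)
        n2 = np.sum(np.isfinite(y), axis=1).astype(float)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1, m2 = np.nanmean(x, axis=1), np.nanmean(y, axis=1)
            v1 = np.nanvar(x, axis=1, ddof=1)
            v2 = np.nanvar(y, axis=1, ddof=1)
        mean = m1 - m2
        if method == "welch":
            with np.errstate(invalid="ignore", divide="ignore"):
                se2 = v1 / n1 + v2 / n2
                t_stat = mean / np.sqrt(se2)
                df_w = se2**2 / (
                    (v1 / n1) ** 2 / (n1 - 1.0) + (v2 / n2) ** 2 / (n2 - 1.0)
                )
                p = 2.0 * stats.t.sf(np.abs(t_stat), df_w)
            return _assemble(
                matrix, mean, t_stat, p, n1, n2, "welch", math.nan, math.nan, meta
            )
        df = n1 + n2 - 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = ((n1 - 1.0) * v1 + (n2 - 1.0) * v2) / df
        stderr_scale = np.sqrt(1.0 / n1 + 1.0 / n2)
        n_treated, n_control = n1, n2

    valid = np.isfinite(mean) & np.isfinite(s2) & (df > 0)
    d0, s0_2 = fit_prior_variance(s2[valid], df[valid])
    if prior_df is not None:
        d0 = float(prior_df)
    post_var, post_df = _posterior_variance(s2, df, d0, s0_2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = mean / (np.sqrt(post_var) * stderr_scale)
        p = 2.0 * stats.t.sf(np.abs(t_stat), post_df)
    t_stat = np.where(valid, t_stat, np.nan)
    p = np.where(valid, p, np.nan)
    return _assemble(matrix, mean, t_stat, p, n_treated, n_control, "moderated", d0, s0_2, meta)


def _assemble(matrix, mean, t_stat, p, n1, n2, method, d0, s0_2, meta) -> ProbeStats:
    table = pd.DataFrame(
        {
            "logfc": mean,
            "t": t_stat,
            "p_value": p,
            "fdr": benjamini_hochberg(p),
            "n_treated": n1,
            "n_control": n2,
        },
        index=matrix.probe_ids,
    )
    return ProbeStats(
        table=table,
        n_probes=matrix.n_probes,
        method=method,
        prior_df=d0,
        prior_var=s0_2,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Signature selection and impact metrics
# ---------------------------------------------------------------------------


def select_signature(
    stats_: ProbeStats,
    name: str | None = None,
    min_size: int = 4,
    max_size: int = 100,
    fdr_cutoff: float = 0.05,
    platform_id: str = "",
) -> Signature:
    """FDR-ranked head of the differential probes, signed by LogFC direction.

    Probes with FDR <= cutoff are ordered by FDR ascending (ties: smaller raw
    p, then larger |logfc|, then probe ID) and truncated at ``max_size``.
    Fewer than ``min_size`` qualifying probes raises :class:`NoSignatureError`
    — the condition then contributes ROGLs only.
    """
    if min_size < 1 or max_size < min_size:
        raise ValidationError("require 1 <= min_size <= max_size")
    t = stats_.table
    qual = t[t["fdr"] <= fdr_cutoff].copy()
    if len(qual) < min_size:
        raise NoSignatureError(
            f"{len(qual)} probes at FDR <= {fdr_cutoff}; minimum signature size is {min_size}"
        )
    qual["_abs"] = -qual["logfc"].abs()
    qual["_pid"] = qual.index.astype(str)
    qual = qual.sort_values(["fdr", "p_value", "_abs", "_pid"], kind="stable").head(max_size)
    if name is None:
        name = stats_.meta.label() if stats_.meta is not None else "signature"
    signs = np.where(qual["logfc"].to_numpy() < 0, -1, 1)
    return Signature(
        name=name,
        platform_id=platform_id,
        probe_ids=qual.index.to_numpy(dtype=object),
        signs=signs,
        logfc=qual["logfc"].to_numpy(),
        fdr=qual["fdr"].to_numpy(),
        meta=stats_.meta,
    )


def impact_metrics(stats_: ProbeStats, fdr_cutoff: float = 0.05) -> ImpactMetrics:
    """Relative transcriptome impact (RTI), mean |LogFC| over DEGs, DEG count.

    RTI is the fraction of the platform's N probes called differentially
    expressed at the FDR cutoff.  With zero DEGs the mean |LogFC| is
    undefined and reported as None.
    """
    t = stats_.table
    deg = t[t["fdr"] <= fdr_cutoff]
    n_deg = len(deg)
    rti = n_deg / stats_.n_probes
    mean_abs = float(deg["logfc"].abs().mean()) if n_deg else None
    return ImpactMetrics(n_deg=n_deg, rti=rti, mean_abs_logfc=mean_abs)
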