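"""Signature-ROGL connectivity scoring with an empirical permutation null.

The raw connectivity score of a signature against a ROGL is the sum over
signature probes of ``sign_i * signed_rank_i``: it is maximized when the
signature's probes occupy the top absolute ranks with matching signs, and
minimized when all signs oppose.  Normalizing by the best attainable sum
(the top-m ranks, ``sum_{j=N-m+1}^{N} j``) puts the score in [-1, 1] and
makes it comparable across signature and platform sizes.  A ROGL set is
scored by the arithmetic mean of its members' normalized scores.

Significance is assessed against a null of simulated signatures of the same
size m: probes drawn uniformly without replacement from the platform's
probes, each with an independent uniform +/-1 sign.  The p-value is the
proportion of simulated signatures whose set score is greater than or equal
to the observed one (by default 10,000 simulations; exact enumeration is
auto-selected when the null space ``C(N, m) * 2^m`` is small).  Across a
collection of S ROGL sets, connections with p <= 1/S are flagged
significant, which controls the expected number of false connections per
query at one.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .iodata import ValidationError
from .rogl import ROGL, ROGLSet
from .signature import Signature

EXHAUSTIVE_LIMIT = 100_000


@dataclass
class ConnectionResult:
    """One signature x ROGL-set connection."""

    signature: str
    set_id: str
    n_rogls: int
    m: int
    score: float
    p_value: float
    n_sim: int
    critical_p: float
    significant: bool
    self: bool
    rank: int = 0
    signature_meta: object = None
    set_condition: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def max_score(m: int, n: int) -> int:
    """Largest attainable raw score: a sign-matched signature in the top m ranks."""
    if not 1 <= m <= n:
        raise ValidationError(f"require 1 <= m <= N; got m={m}, N={n}")
    return m * n - (m * (m - 1)) // 2


def _align(sig: Signature, rogl: ROGL) -> tuple[np.ndarray, np.ndarray]:
    """(signs, signed ranks) for signature probes present in the ROGL."""
    lookup = {pid: int(r) for pid, r in zip(rogl.probe_ids, rogl.signed_rank)}
    signs, ranks = [], []
    for pid, s in zip(sig.probe_ids, sig.signs):
        r = lookup.get(pid)
        if r is not None:
            signs.append(int(s))
            ranks.append(r)
    return np.array(signs, dtype=int), np.array(ranks, dtype=int)


def raw_score(sig: Signature, rogl: ROGL, min_size: int = 1) -> int:
    """Summed signed ranks of the signature probes in one ROGL.

    Signature probes absent from the ROGL are dropped; if fewer than
    ``min_size`` remain the score is undefined and an error is raised.
    """
    signs, ranks = _align(sig, rogl)
    if len(signs) < len(sig.probe_ids):
        warnings.warn(
            f"signature {sig.name!r}: {len(sig.probe_ids) - len(signs)} probe(s) "
            f"absent from ROGL {rogl.sample_id!r} dropped",
            stacklevel=2,
        )
    if len(signs) < min_size:
        raise ValidationError(
            f"signature {sig.name!r} retains {len(signs)} probe(s) in ROGL "
            f"{rogl.sample_id!r}; minimum is {min_size}"
        )
    return int(np.sum(signs * ranks))


def normalized_score(sig: Signature, rogl: ROGL, min_size: int = 1) -> float:
    """Raw score divided by the ROGL-specific maximum; lies in [-1, 1]."""
    signs, ranks = _align(sig, rogl)
    if len(signs) < min_size:
        raise ValidationError(
            f"signature {sig.name!r} retains {len(signs)} probe(s) in ROGL "
            f"{rogl.sample_id!r}; minimum is {min_size}"
        )
    return float(np.sum(signs * ranks)) / max_score(len(signs), rogl.n)


def set_score(sig: Signature, rogl_set: ROGLSet, min_size: int = 1) -> float:
    """Arithmetic mean of the normalized scores over the set's members."""
    return float(
        np.mean([normalized_score(sig, r, min_size=min_size) for r in rogl_set.members])
    )


# ---------------------------------------------------------------------------
# Null distribution
# ---------------------------------------------------------------------------


def _set_universe(rogl_set: ROGLSet) -> np.ndarray:
    """The platform probe universe a null signature is drawn from."""
    universe: set = set()
    for r in rogl_set.members:
        universe.update(r.probe_ids)
    return np.array(sorted(universe), dtype=object)


def _member_arrays(rogl_set: ROGLSet, universe: np.ndarray):
    """Per-member signed-rank vectors aligned to the universe (0 = absent)."""
    pos = {pid: i for i, pid in enumerate(universe)}
    ranks, ns = [], []
    for r in rogl_set.members:
        vec = np.zeros(len(universe), dtype=np.int64)
        for pid, sr in zip(r.probe_ids, r.signed_rank):
            vec[pos[pid]] = int(sr)
        ranks.append(vec)
        ns.append(r.n)
    return np.stack(ranks), np.array(ns, dtype=np.int64)


def _score_index_matrix(
    idx: np.ndarray, signs: np.ndarray, rank_mat: np.ndarray, member_n: np.ndarray
) -> np.ndarray:
    """Mean normalized set score for each row of sampled probe indices."""
    total = np.zeros(idx.shape[0], dtype=float)
    for j in range(rank_mat.shape[0]):
        r = rank_mat[j][idx]
        present = r != 0
        mp = present.sum(axis=1)
        denom = mp * member_n[j] - mp * (mp - 1) / 2.0
        raw = (signs * r).sum(axis=1)
        total += np.where(mp > 0, raw / np.maximum(denom, 1.0), 0.0)
    return total / rank_mat.shape[0]


def simulate_null_scores(
    rogl_set: ROGLSet,
    m: int,
    n_sim: int,
    rng: np.random.Generator,
    signed: bool = True,
    chunk: int = 1024,
) -> np.ndarray:
    """Set scores of ``n_sim`` random signatures of size m.

    Each simulated signature is m distinct probes drawn uniformly from the
    platform universe; with ``signed`` each probe gets an independent uniform
    +/-1 sign (the sign-symmetric null with mean score zero), otherwise all
    signs are +1 (the probes-only variant compared on |score|).
    """
    universe = _set_universe(rogl_set)
    if not 1 <= m <= len(universe):
        raise ValidationError(f"require 1 <= m <= N; got m={m}, N={len(universe)}")
    rank_mat, member_n = _member_arrays(rogl_set, universe)
    n = len(universe)
    out = np.empty(n_sim, dtype=float)
    done = 0
    while done < n_sim:
        c = min(chunk, n_sim - done)
        idx = _sample_without_replacement(rng, c, n, m)
        signs = rng.integers(0, 2, size=(c, m)) * 2 - 1 if signed else np.ones((c, m), int)
        out[done : done + c] = _score_index_matrix(idx, signs, rank_mat, member_n)
        done += c
    return out


def _sample_without_replacement(
    rng: np.random.Generator, rows: int, n: int, m: int
) -> np.ndarray:
    """``rows`` independent uniform m-subsets of range(n), as index rows.

    Rejection sampling (redraw rows containing a duplicate) when collisions
    are rare, otherwise a random-key argpartition; both draw uniformly."""
    if m * m <= n:  # expected collision rate m^2/2n <= 50%
        idx = rng.integers(0, n, size=(rows, m))
        for _ in range(200):
            s = np.sort(idx, axis=1)
            bad = (s[:, 1:] == s[:, :-1]).any(axis=1) if m > 1 else np.zeros(rows, bool)
            if not bad.any():
                return idx
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), m))
    keys = rng.random((rows, n))
    return np.argpartition(keys, m - 1, axis=1)[:, :m] if m < n else np.tile(
        np.arange(n), (rows, 1)
    )


def exhaustive_null_scores(rogl_set: ROGLSet, m: int, signed: bool = True) -> np.ndarray:
    """Set scores of every possible signature of size m (enumeration oracle)."""
    universe = _set_universe(rogl_set)
    n = len(universe)
    if not 1 <= m <= n:
        raise ValidationError(f"require 1 <= m <= N; got m={m}, N={n}")
    rank_mat, member_n = _member_arrays(rogl_set, universe)
    sign_space = list(itertools.product((1, -1), repeat=m)) if signed else [(1,) * m]
    scores = []
    for combo in itertools.combinations(range(n), m):
        idx = np.array([combo], dtype=int)
        for signs in sign_space:
            scores.append(
                float(
                    _score_index_matrix(
                        idx, np.array([signs], dtype=int), rank_mat, member_n
                    )[0]
                )
            )
    return np.array(scores)


def null_space_size(n: int, m: int, signed: bool = True) -> int:
    return math.comb(n, m) * (2**m if signed else 1)


def empirical_pvalue(
    sig: Signature,
    rogl_set: ROGLSet,
    n_sim: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    signed_null: bool = True,
    smoothing: bool = False,
    method: str = "auto",
    min_size: int = 1,
    null_scores: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """(observed set score, p-value, effective n_sim) for one signature/set.

    p is the proportion of null signatures whose set score is >= the
    observed score (on |score| for the unsigned null).  ``method`` is
    ``"auto"`` (exact enumeration when the null space is <= 100,000, else
    Monte Carlo), ``"exhaustive"``, or ``"montecarlo"``.  Monte Carlo
    requires an explicit ``seed`` or ``rng``; ``smoothing`` applies the
    (k+1)/(n+1) estimator to avoid literal zero p-values.  Precomputed
    ``null_scores`` (e.g. shared across equally-sized signatures) bypass
    sampling.
    """
    if method not in ("auto", "exhaustive", "montecarlo"):
        raise ValidationError(f"unknown p-value method {method!r}")
    observed = set_score(sig, rogl_set, min_size=min_size)
    m = sig.m
    if null_scores is None:
        universe_n = len(_set_universe(rogl_set))
        exact = method == "exhaustive" or (
            method == "auto" and null_space_size(universe_n, m, signed_null) <= EXHAUSTIVE_LIMIT
        )
        if exact:
            null_scores = exhaustive_null_scores(rogl_set, m, signed=signed_null)
            smoothing = False
        else:
            if rng is None:
                if seed is None:
                    raise ValidationError("Monte Carlo p-value requires an explicit seed or rng")
                rng = np.random.default_rng(seed)
            if n_sim < 100:
                warnings.warn(
                    f"n_sim={n_sim} gives a minimum nonzero p of {1.0 / n_sim:.3g}; "
                    "p-value resolution will be poor",
                    stacklevel=2,
                )
            null_scores = simulate_null_scores(rogl_set, m, n_sim, rng, signed=signed_null)
    n_eff = len(null_scores)
    if signed_null:
        k = int(np.sum(null_scores >= observed - 1e-12))
    else:
        k = int(np.sum(np.abs(null_scores) >= abs(observed) - 1e-12))
    p = (k + 1) / (n_eff + 1) if smoothing else k / n_eff
    return observed, float(p), n_eff


# ---------------------------------------------------------------------------
# Critical p-value and query
# ---------------------------------------------------------------------------


def critical_pvalue(s: int) -> float:
    """The significance cutoff 1/S for a collection of S ROGL sets."""
    if s < 1:
        raise ValidationError(f"require S >= 1; got {s}")
    return 1.0 / s


def round_sigfigs(x: float, sig_figs: int = 2) -> float:
    """Display rounding to ``sig_figs`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig_figs - 1)


def query(
    sig: Signature,
    collection: Sequence[ROGLSet],
    n_sim: int = 10_000,
    seed: int | None = None,
    signed_null: bool = True,
    smoothing: bool = False,
    method: str = "auto",
    min_size: int = 1,
    null_cache: Mapping | None = None,
) -> list[ConnectionResult]:
    """Rank a collection of ROGL sets by connectivity to a query signature.

    One result per set, ranked by set score descending (ties: smaller p,
    then lexicographic set_id); ``significant`` flags p <= 1/S and ``self``
    flags sets sharing the signature's experiment of origin.  ``null_cache``,
    a mutable mapping, memoizes Monte-Carlo null scores per (set_id, m) so a
    batch of equally-sized signatures reuses the same simulated-signature
    draws.
    """
    if not collection:
        raise ValidationError("empty ROGL-set collection")
    set_ids = [s.set_id for s in collection]
    if len(set(set_ids)) != len(set_ids):
        raise ValidationError("duplicate set_id in collection")
    s_count = len(collection)
    crit = critical_pvalue(s_count)
    ss = np.random.SeedSequence(seed) if seed is not None else None
    children = ss.spawn(s_count) if ss is not None else [None] * s_count
    order = np.argsort(np.array(set_ids, dtype=object))
    results = []
    for child, i in zip(children, order):
        rogl_set = collection[i]
        key = (rogl_set.set_id, sig.m, signed_null)
        null = null_cache.get(key) if null_cache is not None else None
        smooth = smoothing
        if null is None:
            universe_n = len(_set_universe(rogl_set))
            exact = method == "exhaustive" or (
                method == "auto"
                and null_space_size(universe_n, sig.m, signed_null) <= EXHAUSTIVE_LIMIT
            )
            if exact:
                null = exhaustive_null_scores(rogl_set, sig.m, signed=signed_null)
                smooth = False
            else:
                if child is None and seed is None:
                    raise ValidationError("Monte Carlo p-value requires an explicit seed")
                rng = np.random.default_rng(child if child is not None else seed)
                null = simulate_null_scores(rogl_set, sig.m, n_sim, rng, signed=signed_null)
            if null_cache is not None:
                null_cache[key] = null
        observed, p, n_eff = empirical_pvalue(
            sig,
            rogl_set,
            signed_null=signed_null,
            smoothing=smooth,
            min_size=min_size,
            null_scores=null,
        )
        self_flag = (
            sig.meta is not None
            and sig.meta.experiment_id != ""
            and sig.meta.experiment_id in rogl_set.experiment_ids()
        )
        results.append(
            ConnectionResult(
                signature=sig.name,
                set_id=rogl_set.set_id,
                n_rogls=rogl_set.size,
                m=sig.m,
                score=observed,
                p_value=p,
                n_sim=n_eff,
                critical_p=crit,
                significant=p <= crit + 1e-12,
                self=self_flag,
                signature_meta=sig.meta,
                set_condition={
                    k: rogl_set.consensus(k) for k in ("chemical", "dose", "tissue")
                },
            )
        )
    results.sort(key=lambda r: (-r.score, r.p_value, r.set_id))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results
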