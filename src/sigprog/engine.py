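"""Signed-rank connection scoring with permutation significance testing.

The connection score between a query signature of length ``m`` and a
reference profile over ``N_ref`` probes is a normalized inner product

    c = ( sum_i w_i * r(g_i) ) / c_max

where ``r(g)`` is the profile's signed rank of gene ``g`` and the signature
weight is ``w_i = sign_i * (m - rank_i + 1)`` in *ordered* mode (the top
signature gene carries weight ``m``) or ``w_i = sign_i`` in *unordered*
mode. The normalizer ``c_max`` is the largest attainable raw score, so
``c`` is always in [-1, 1]: +1 means the signature picks out the profile's
most extreme probes with concordant signs, -1 the same with opposite signs.

Significance is assessed by scoring random signatures of the same length —
genes sampled without replacement from the reference universe, signs
assigned uniformly at random — against the same reference set, and locating
the observed score in that null. The left-sided p-value uses a
zero-avoiding correction, ``p = (#{null < observed} + 0.5) / n_perm``, so
the smallest reportable p at 1e5 permutations is 5.0e-6. Null score
distributions are cached per (signature length, compound) within a run, and
the random stream for each (length, compound) pair is derived
deterministically from the root seed so results are reproducible and
independent of evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConfigError, FLOAT_FMT, ReferenceDatabase, ReferenceProfile, ReferenceSet, SigprogError
from .signature import QuerySignature

ORDERED = "ordered"
UNORDERED = "unordered"

LEFT = "left"
RIGHT = "right"
TWO = "two"

#: memory cap (in floats) for one vectorized null-generation chunk
_CHUNK_BUDGET = 4_000_000


@dataclass
class ScoringConfig:
    """Parameters of the permutation test.

    Attributes
    ----------
    mode
        ``"ordered"`` (rank-weighted, default) or ``"unordered"``.
    n_perm
        Number of random signatures per null distribution (>= 1000).
    sidedness
        ``"left"`` for negative (reversal) connections, ``"right"`` for
        positive ones, ``"two"`` for both.
    rng_seed
        Root seed; every null stream is derived from it.
    threshold_n_fp
        Tolerated false connections per query; the per-compound
        significance threshold is ``threshold_n_fp / N_sets``.
    """

    mode: str = ORDERED
    n_perm: int = 100_000
    sidedness: str = LEFT
    rng_seed: int = 0
    threshold_n_fp: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in (ORDERED, UNORDERED):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.sidedness not in (LEFT, RIGHT, TWO):
            raise ConfigError(f"unknown sidedness {self.sidedness!r}")
        if self.n_perm < 1000:
            raise ConfigError("n_perm must be at least 1000")
        if self.threshold_n_fp <= 0:
            raise ConfigError("threshold_n_fp must be positive")

    def sm_threshold(self, n_sets: int) -> float:
        return self.threshold_n_fp / n_sets


@dataclass
class ConnectionResult:
    """One row of a connectivity-mapping result table."""

    compound: str
    n_replicates: int
    cscore: float
    p_value: float
    z_score: float | None
    sm: int
    ps: float | None = None


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def signature_weights(m: int, mode: str) -> np.ndarray:
    """Unsigned weights for signature positions 1..m."""
    if mode == ORDERED:
        return np.arange(m, 0, -1, dtype=float)
    return np.ones(m, dtype=float)


def max_raw_score(m: int, n_ref: int, mode: str) -> float:
    """Largest attainable |raw score|: top weights paired with top ranks."""
    j = np.arange(m, dtype=float)
    if mode == ORDERED:
        return float(np.sum((m - j) * (n_ref - j)))
    return float(np.sum(n_ref - j))


def connection_score(sig: QuerySignature, prof: ReferenceProfile, mode: str = ORDERED) -> float:
    """Normalized connection score of one signature against one profile."""
    idx = _signature_indices(sig, {p: i for i, p in enumerate(prof.universe)})
    w = signature_weights(sig.m, mode) * sig.signs
    raw = float(np.dot(w, prof.signed_rank[idx]))
    return raw / max_raw_score(sig.m, prof.n_ref, mode)


def set_score(sig: QuerySignature, rs: ReferenceSet, mode: str = ORDERED) -> float:
    """Mean connection score over a compound's replicate profiles."""
    if rs.n_replicates == 0:
        raise SigprogError(f"reference set {rs.compound!r} is empty")
    idx = _signature_indices(sig, {p: i for i, p in enumerate(rs.universe)})
    w = signature_weights(sig.m, mode) * sig.signs
    raw = rs.rank_matrix()[:, idx] @ w
    return float(raw.mean()) / max_raw_score(sig.m, len(rs.universe), mode)


def _signature_indices(sig: QuerySignature, index: dict[str, int]) -> np.ndarray:
    if sig.m == 0:
        raise SigprogError("signature is empty")
    try:
        return np.array([index[p] for p in sig.probe_ids], dtype=np.intp)
    except KeyError as exc:
        raise SigprogError(
            f"signature probe {exc.args[0]!r} is not in the reference universe; "
            "restrict the signature to the universe first (restrict_to_universe)"
        ) from None


# ---------------------------------------------------------------------------
# random signatures and null distributions
# ---------------------------------------------------------------------------


def random_signature(m: int, universe: list[str] | tuple[str, ...],
                     rng: np.random.Generator) -> QuerySignature:
    """Draw one random signature: ``m`` distinct probes, random +-1 signs.

    Probes are sampled without replacement; in ordered mode the sampled
    order is the rank order.
    """
    if m > len(universe):
        raise ConfigError(f"m={m} exceeds the universe size {len(universe)}")
    idx = rng.choice(len(universe), size=m, replace=False)
    signs = rng.integers(0, 2, size=m) * 2 - 1
    return QuerySignature.from_lists([universe[i] for i in idx], signs.tolist())


def _sample_index_matrix(rng: np.random.Generator, n: int, m: int, n_ref: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of ``n`` random signatures over ``n_ref`` probes.

    Each row of the returned index matrix is a uniformly random ordered
    m-subset (sorting iid uniform keys yields a uniform subset in uniform
    order); signs are iid +-1.
    """
    keys = rng.random((n, n_ref))
    if m < n_ref:
        part = np.argpartition(keys, m - 1, axis=1)[:, :m] if m > 1 else np.argmin(keys, axis=1)[:, None]
        kv = np.take_along_axis(keys, part, axis=1)
        order = np.argsort(kv, axis=1)
        idx = np.take_along_axis(part, order, axis=1)
    else:
        idx = np.argsort(keys, axis=1)
    signs = rng.integers(0, 2, size=(n, m)) * 2 - 1
    return idx, signs


def _null_rng(seed: int, compound: str, m: int) -> np.random.Generator:
    """Deterministic sub-stream for one (signature length, compound) pair."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(compound.encode("utf-8")), int(m)])
    )


def null_scores(m: int, rs: ReferenceSet, cfg: ScoringConfig,
                cache: dict | None = None) -> np.ndarray:
    """Null distribution of set-level scores for random signatures of length m.

    Each random signature is scored against *all* replicates of the set and
    the replicate-mean taken, exactly as for an observed signature.
    """
    key = (m, rs.compound, cfg.mode, cfg.n_perm, cfg.rng_seed)
    if cache is not None and key in cache:
        return cache[key]
    mat = rs.rank_matrix()
    n_rep, n_ref = mat.shape
    if m > n_ref:
        raise ConfigError(f"m={m} exceeds the universe size {n_ref}")
    rng = _null_rng(cfg.rng_seed, rs.compound, m)
    w = signature_weights(m, cfg.mode)
    c_max = max_raw_score(m, n_ref, cfg.mode)
    out = np.empty(cfg.n_perm)
    chunk = max(1, _CHUNK_BUDGET // max(n_ref, n_rep * m))
    pos = 0
    while pos < cfg.n_perm:
        c = min(chunk, cfg.n_perm - pos)
        idx, signs = _sample_index_matrix(rng, c, m, n_ref)
        sw = signs * w
        raw = np.einsum("rcm,cm->c", mat[:, idx], sw) / n_rep
        out[pos:pos + c] = raw / c_max
        pos += c
    if cache is not None:
        cache[key] = out
    return out


@dataclass
class PermutationResult:
    p_value: float
    z_score: float | None
    null_mean: float
    null_sd: float
    observed: float
    degenerate_null: bool = False


def permutation_p(sig: QuerySignature, rs: ReferenceSet, cfg: ScoringConfig,
                  cache: dict | None = None) -> PermutationResult:
    """Permutation p-value and z-score of a signature/compound connection.

    Left-sided ``p = (#{null < observed} + 0.5) / n_perm`` (ties with the
    observed score count as not-less-than, which is conservative);
    right-sided analogously with ``>``; two-sided is twice the smaller of
    the two, capped at 1.
    """
    observed = set_score(sig, rs, cfg.mode)
    null = null_scores(sig.m, rs, cfg, cache)
    n = cfg.n_perm
    p_left = (np.count_nonzero(null < observed) + 0.5) / n
    p_right = (np.count_nonzero(null > observed) + 0.5) / n
    if cfg.sidedness == LEFT:
        p = p_left
    elif cfg.sidedness == RIGHT:
        p = p_right
    else:
        p = min(1.0, 2.0 * min(p_left, p_right))
    mu = float(null.mean())
    sd = float(null.std(ddof=0))
    if sd == 0.0:
        return PermutationResult(float(p), None, mu, sd, observed, degenerate_null=True)
    z = (observed - mu) / sd
    return PermutationResult(float(p), float(z), mu, sd, observed)


# ---------------------------------------------------------------------------
# database-level query
# ---------------------------------------------------------------------------


def query_database(sig: QuerySignature, db: ReferenceDatabase, cfg: ScoringConfig,
                   cache: dict | None = None) -> list[ConnectionResult]:
    """Score a signature against every reference set in the database.

    Returns one :class:`ConnectionResult` per compound, sorted by z-score
    with the most significant connection for the configured sidedness
    first (most negative z for left-sided tests, most positive for
    right-sided, largest |z| for two-sided).
    """
    if db.n_sets == 0:
        raise SigprogError("reference database is empty")
    if sig.m == 0:
        raise SigprogError("signature is empty")
    threshold = cfg.sm_threshold(db.n_sets)
    results = []
    for rs in db.sets:
        perm = permutation_p(sig, rs, cfg, cache)
        results.append(
            ConnectionResult(
                compound=rs.compound,
                n_replicates=rs.n_replicates,
                cscore=perm.observed,
                p_value=perm.p_value,
                z_score=perm.z_score,
                sm=int(perm.p_value < threshold),
            )
        )
    if cfg.sidedness == LEFT:
        keyf = lambda r: r.z_score if r.z_score is not None else np.inf
        results.sort(key=keyf)
    elif cfg.sidedness == RIGHT:
        keyf = lambda r: -(r.z_score if r.z_score is not None else -np.inf)
        results.sort(key=keyf)
    else:
        keyf = lambda r: -abs(r.z_score) if r.z_score is not None else 0.0
        results.sort(key=keyf)
    return results


def perturbation_stability(sig: QuerySignature, rs: ReferenceSet, n_sets: int,
                           cfg: ScoringConfig, cache: dict | None = None) -> float | None:
    """Leave-one-out stability of a compound's significant connection.

    For each signature gene in turn, the gene is removed, the remaining
    ranks are closed up to ``1..m-1``, and significance is re-assessed at
    the same per-compound threshold. The returned stability is the fraction
    of the ``m`` perturbed signatures under which the connection stays
    significant. Undefined (``None``) for signatures of length 1.
    """
    if sig.m < 2:
        return None
    threshold = cfg.sm_threshold(n_sets)
    ids, signs = sig.probe_ids, [g.sign for g in sig.genes]
    n_stable = 0
    for i in range(sig.m):
        loo = QuerySignature.from_lists(ids[:i] + ids[i + 1:], signs[:i] + signs[i + 1:])
        if permutation_p(loo, rs, cfg, cache).p_value < threshold:
            n_stable += 1
    return n_stable / sig.m


# ---------------------------------------------------------------------------
# result table I/O (compound, replicates, cscore, p value, zscore, SM, PS)
# ---------------------------------------------------------------------------


def results_to_frame(results: list[ConnectionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound": r.compound,
                "replicates": r.n_replicates,
                "cscore": r.cscore,
                "p_value": r.p_value,
                "z_score": r.z_score if r.z_score is not None else np.nan,
                "SM": r.sm,
                "PS": r.ps if r.ps is not None else np.nan,
            }
            for r in results
        ]
    )


def write_results(results: list[ConnectionResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
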