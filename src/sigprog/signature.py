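"""Stage 2a: ranking differentially expressed genes into query signatures.

A query signature is a short ordered list of genes with signed ranks: the
absolute rank (1 = most important) times +1 or -1 for the direction of
regulation. Two base orderings are supported — by statistical significance
(ascending p-value, ``M1``) and by biological effect (descending absolute
log2 difference, ``M2``) — plus a weighted combination of the two rank
vectors, ``R = w_p * R_p + w_e * R_e`` with ``w_p + w_e = 1``.

This module also combines several reference profiles into a single query
signature by summing their signed ranks per probe, the procedure used to
build a drug-class signature from the class members' own profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexp import DiffExpRecord
from .io import ConfigError, FLOAT_FMT, ReferenceProfile, SigprogError, UniverseError, logger

M1 = "M1"
M2 = "M2"
WEIGHTED = "WEIGHTED"


@dataclass
class RankingConfig:
    """How to order the selected genes before slicing signatures.

    ``method`` is ``"M1"`` (ascending p-value), ``"M2"`` (descending
    absolute log2 difference) or ``"WEIGHTED"``; for the latter, ``w_p``
    and ``w_e`` weight the p-value rank and the effect rank and must sum
    to 1.
    """

    method: str = M1
    w_p: float = 0.5
    w_e: float = 0.5

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in (M1, M2, WEIGHTED):
            raise ConfigError(f"unknown ranking method {self.method!r}")
        if self.method == WEIGHTED:
            if self.w_p < 0 or self.w_e < 0 or abs(self.w_p + self.w_e - 1.0) > 1e-9:
                raise ConfigError("weighted ranking requires w_p, w_e >= 0 with w_p + w_e = 1")


@dataclass(frozen=True)
class RankedGene:
    probe_id: str
    abs_rank: int
    sign: int

    @property
    def signed_rank(self) -> int:
        return self.sign * self.abs_rank


@dataclass
class QuerySignature:
    """An ordered list of ranked genes; ``genes[0]`` has absolute rank 1."""

    genes: list[RankedGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [g.probe_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise SigprogError("signature probe_ids are not unique")
        for i, g in enumerate(self.genes):
            if g.abs_rank != i + 1:
                raise SigprogError(f"abs_ranks must be 1..m with no gaps; position {i} has {g.abs_rank}")
            if g.sign not in (-1, 1):
                raise SigprogError(f"sign of {g.probe_id!r} must be +1 or -1")

    @property
    def m(self) -> int:
        return len(self.genes)

    @property
    def probe_ids(self) -> list[str]:
        return [g.probe_id for g in self.genes]

    @property
    def signs(self) -> np.ndarray:
        return np.array([g.sign for g in self.genes], dtype=np.int64)

    @classmethod
    def from_lists(cls, probe_ids: Sequence[str], signs: Sequence[int]) -> "QuerySignature":
        return cls([RankedGene(str(p), i + 1, int(s)) for i, (p, s) in enumerate(zip(probe_ids, signs))])

    def negated(self) -> "QuerySignature":
        return QuerySignature.from_lists(self.probe_ids, [-g.sign for g in self.genes])


def rank_genes(deg: list[DiffExpRecord], cfg: RankingConfig | None = None) -> QuerySignature:
    """Order the selected genes and attach signed ranks (full length n).

    Ties are broken deterministically: M1 falls back to descending
    ``|mean_diff|`` then probe_id; M2 falls back to ascending p-value then
    probe_id; weighted combinations fall back to ascending p-value then
    probe_id. The sign of each ranked gene is the record's direction of
    regulation (treatment relative to control).
    """
    cfg = cfg or RankingConfig()
    if not deg:
        raise ConfigError("cannot rank an empty gene list")
    if cfg.method == M1:
        ordered = sorted(deg, key=lambda r: (r.p_value, -abs(r.mean_diff), r.probe_id))
    elif cfg.method == M2:
        ordered = sorted(deg, key=lambda r: (-abs(r.mean_diff), r.p_value, r.probe_id))
    else:
        r_p = {r.probe_id: i + 1 for i, r in enumerate(
            sorted(deg, key=lambda r: (r.p_value, -abs(r.mean_diff), r.probe_id)))}
        r_e = {r.probe_id: i + 1 for i, r in enumerate(
            sorted(deg, key=lambda r: (-abs(r.mean_diff), r.p_value, r.probe_id)))}
        combined = {r.probe_id: cfg.w_p * r_p[r.probe_id] + cfg.w_e * r_e[r.probe_id] for r in deg}
        ordered = sorted(deg, key=lambda r: (combined[r.probe_id], r.p_value, r.probe_id))
    return QuerySignature.from_lists([r.probe_id for r in ordered], [r.direction for r in ordered])


def slice_signature(full: QuerySignature, k: int) -> QuerySignature:
    """The progression signature s_k: the top ``k`` ranked genes."""
    if not 1 <= k <= full.m:
        raise ConfigError(f"k must be in 1..{full.m}, got {k}")
    return QuerySignature(list(full.genes[:k]))


def restrict_to_universe(sig: QuerySignature, universe: Sequence[str]) -> tuple[QuerySignature, int]:
    """Drop signature probes absent from a reference universe.

    Ranks of the survivors are closed up to 1..m'. Returns the restricted
    signature and the number of probes dropped (also logged).
    """
    known = set(universe)
    kept = [g for g in sig.genes if g.probe_id in known]
    dropped = sig.m - len(kept)
    if dropped:
        logger.info("restrict_to_universe: dropped %d of %d signature probes", dropped, sig.m)
    return QuerySignature.from_lists([g.probe_id for g in kept], [g.sign for g in kept]), dropped


# ---------------------------------------------------------------------------
# combining reference profiles into a signature
# ---------------------------------------------------------------------------


def combine_profiles_to_signature(
    profiles: list[ReferenceProfile],
    policy: str = "null",
    level: float = 0.01,
    top_fraction: float | None = None,
    n_null: int = 20000,
    rng: np.random.Generator | None = None,
) -> QuerySignature:
    """Merge several profiles into one signature by summing signed ranks.

    Per probe, ``sum_rank`` is the sum of the probe's signed ranks across
    all profiles; probes are ordered by descending ``|sum_rank|`` (ties
    broken by probe_id) and signed by ``sign(sum_rank)``. Probes whose
    signed ranks cancel exactly (``sum_rank == 0``) are excluded.

    Selection policy:

    * ``"null"`` (default) — keep probes whose ``|sum_rank|`` exceeds the
      ``1 - level`` quantile of a Monte-Carlo null in which each profile
      contributes an independent uniform signed rank.
    * ``"top_fraction"`` — keep the top ``top_fraction`` of probes.
    * ``"all"`` — keep every probe with a nonzero sum.
    """
    if not profiles:
        raise ConfigError("need at least one profile to combine")
    universe = profiles[0].universe
    for prof in profiles[1:]:
        if prof.universe != universe:
            prof_set = set(prof.universe)
            if prof_set != set(universe):
                raise UniverseError("profiles do not share a probe universe")
    aligned = [p if p.universe == universe else p.reindexed(universe) for p in profiles]
    sums = np.sum([p.signed_rank for p in aligned], axis=0)

    order = sorted(range(len(universe)), key=lambda i: (-abs(sums[i]), universe[i]))
    order = [i for i in order if sums[i] != 0]

    if policy == "all":
        keep = order
    elif policy == "top_fraction":
        if top_fraction is None or not 0 < top_fraction <= 1:
            raise ConfigError("top_fraction policy requires 0 < top_fraction <= 1")
        keep = order[: max(1, int(round(top_fraction * len(universe))))]
    elif policy == "null":
        rng = rng if rng is not None else np.random.default_rng(0)
        n_ref = len(universe)
        draws = rng.integers(1, n_ref + 1, size=(n_null, len(aligned)))
        signs = rng.integers(0, 2, size=(n_null, len(aligned))) * 2 - 1
        null = np.abs((draws * signs).sum(axis=1))
        cut = float(np.quantile(null, 1.0 - level))
        keep = [i for i in order if abs(sums[i]) > cut]
    else:
        raise ConfigError(f"unknown selection policy {policy!r}")

    if not keep:
        raise SigprogError("no probe survived the combination selection policy")
    return QuerySignature.from_lists(
        [universe[i] for i in keep], [1 if sums[i] > 0 else -1 for i in keep]
    )


# ---------------------------------------------------------------------------
# signature file I/O (probe_id, sign; one row per gene, rank order)
# ---------------------------------------------------------------------------


def write_signature(sig: QuerySignature, path) -> None:
    pd.DataFrame({"probe_id": sig.probe_ids, "sign": [g.sign for g in sig.genes]}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_signature(path) -> QuerySignature:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str})
    if not {"probe_id", "sign"}.issubset(df.columns):
        raise SigprogError("signature file must have columns probe_id, sign")
    return QuerySignature.from_lists(df["probe_id"].tolist(), df["sign"].astype(int).tolist())
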