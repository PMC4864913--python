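"""Domain types and file I/O for expression matrices and reference databases.

All on-disk formats are plain UTF-8 tab-delimited text. Lines starting with
``#`` are comments and are ignored on read; floats are written with six
significant digits.

The three file formats handled here:

* **Expression matrix** — header row of sample identifiers, first column of
  probe identifiers, numeric body of log2-scale expression values. A paired
  design is described by a separate *pairs* table with columns
  ``sample_id``, ``condition`` (``control``/``treatment``) and ``pair_id``.
* **Reference database** — a directory containing ``manifest.tsv`` with
  columns ``compound`` and ``profile_file`` (one row per replicate profile)
  plus one two-column table (``probe_id``, ``signed_rank``) per profile.
* **Signature** — handled in :mod:`sigprog.signature` (two columns,
  ``probe_id`` and ``sign``, in rank order).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sigprog")

CONTROL = "control"
TREATMENT = "treatment"

#: printf-style format used for every float written by this package
FLOAT_FMT = "%.6g"


class SigprogError(Exception):
    """Base class for all package errors."""


class ParseError(SigprogError):
    """A file could not be parsed; the message names the offending cell."""


class PairingError(SigprogError):
    """The sample pairing does not describe a valid paired design."""


class IntegrityError(SigprogError):
    """A reference profile violates the signed-rank permutation invariant."""


class UniverseError(SigprogError):
    """Probe universes disagree where they are required to match."""


class ConfigError(SigprogError):
    """An invalid configuration value."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A log2-scale probe x sample expression matrix with a paired design.

    Parameters
    ----------
    probe_ids
        Unique probe identifiers, one per matrix row.
    sample_ids
        Unique sample identifiers, one per matrix column.
    values
        Array of shape ``(len(probe_ids), len(sample_ids))`` holding log2
        expression values. Values are taken as-is; no transformation is
        applied on input or output.
    condition
        Per-sample label, each ``"control"`` or ``"treatment"``.
    pair_id
        Per-sample subject identifier; every pair identifier must occur
        exactly twice, once per condition.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition: list[str]
    pair_id: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n_probes, n_samples = len(self.probe_ids), len(self.sample_ids)
        if self.values.shape != (n_probes, n_samples):
            raise ParseError(
                f"values shape {self.values.shape} does not match "
                f"({n_probes} probes, {n_samples} samples)"
            )
        if len(set(self.probe_ids)) != n_probes:
            dupes = _duplicates(self.probe_ids)
            raise ParseError(f"duplicate probe identifiers: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != n_samples:
            raise ParseError(f"duplicate sample identifiers: {sorted(_duplicates(self.sample_ids))[:5]}")
        if len(self.condition) != n_samples or len(self.pair_id) != n_samples:
            raise PairingError("condition/pair_id length does not match sample count")
        bad = set(self.condition) - {CONTROL, TREATMENT}
        if bad:
            raise PairingError(f"unknown condition labels: {sorted(bad)}")
        seen: dict[str, set[str]] = {}
        for pid, cond in zip(self.pair_id, self.condition):
            seen.setdefault(pid, set())
            if cond in seen[pid]:
                raise PairingError(f"pair {pid!r} has more than one {cond} sample")
            seen[pid].add(cond)
        for pid, conds in seen.items():
            if conds != {CONTROL, TREATMENT}:
                missing = ({CONTROL, TREATMENT} - conds).pop()
                raise PairingError(f"pair {pid!r} has no {missing} sample")

    # -- convenience -------------------------------------------------------
    @property
    def n_probes(self) -> int:
        """Total number of probes tested (the multiple-testing universe size)."""
        return len(self.probe_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.sample_ids) // 2

    def paired_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (control, treatment) arrays with columns aligned by pair.

        Both arrays have shape ``(n_probes, n_pairs)``; column ``j`` of each
        belongs to the same subject. The returned list gives the pair order.
        """
        order = sorted(set(self.pair_id))
        col_of = {(pid, cond): i for i, (pid, cond) in enumerate(zip(self.pair_id, self.condition))}
        ctrl = self.values[:, [col_of[(p, CONTROL)] for p in order]]
        trt = self.values[:, [col_of[(p, TREATMENT)] for p in order]]
        return ctrl, trt, order


def read_expression_matrix(path: str | os.PathLike, pairs: str | os.PathLike | pd.DataFrame) -> ExpressionMatrix:
    """Read an expression matrix TSV plus its sample-pairing table.

    ``pairs`` may be a path to a TSV with columns ``sample_id``,
    ``condition``, ``pair_id`` or an equivalent DataFrame. Samples present
    in the matrix but absent from the pairing table are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna().to_numpy()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[i]!r} at probe "
                f"{probe_ids[i]!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()

    if isinstance(pairs, pd.DataFrame):
        pdf = pairs
    else:
        pdf = pd.read_csv(pairs, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "condition", "pair_id"}
    if not required.issubset(pdf.columns):
        raise ParseError(f"pairs table must have columns {sorted(required)}")
    meta = pdf.set_index("sample_id")
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise PairingError(f"samples missing from pairs table: {missing[:5]}")
    condition = [str(meta.loc[s, "condition"]) for s in sample_ids]
    pair_id = [str(meta.loc[s, "pair_id"]) for s in sample_ids]
    return ExpressionMatrix(probe_ids, sample_ids, values, condition, pair_id)


def write_expression_matrix(em: ExpressionMatrix, path: str | os.PathLike,
                            pairs_path: str | os.PathLike | None = None) -> None:
    df = pd.DataFrame(em.values, index=em.probe_ids, columns=em.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    if pairs_path is not None:
        pd.DataFrame(
            {"sample_id": em.sample_ids, "condition": em.condition, "pair_id": em.pair_id}
        ).to_csv(pairs_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference profiles / database
# ---------------------------------------------------------------------------


@dataclass
class ReferenceProfile:
    """One drug-treatment instance as a signed-rank permutation.

    ``signed_rank[i]`` is the signed rank of ``universe[i]``: the absolute
    values form a permutation of ``1..N_ref`` where ``N_ref`` is the universe
    size, the probe with the largest absolute log expression ratio carrying
    ``N_ref`` and the least-changed probe carrying ``1``; the sign gives the
    direction of regulation.
    """

    treatment_id: str
    universe: tuple[str, ...]
    signed_rank: np.ndarray

    def __post_init__(self) -> None:
        self.universe = tuple(self.universe)
        self.signed_rank = np.asarray(self.signed_rank, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n = len(self.universe)
        if n == 0:
            raise UniverseError("empty probe universe")
        if self.signed_rank.shape != (n,):
            raise IntegrityError("signed_rank length does not match universe")
        mags = np.sort(np.abs(self.signed_rank))
        if not np.array_equal(mags, np.arange(1, n + 1)):
            raise IntegrityError(
                f"profile {self.treatment_id!r}: |signed ranks| are not a "
                f"permutation of 1..{n}"
            )

    @property
    def n_ref(self) -> int:
        return len(self.universe)

    def rank_of(self) -> dict[str, int]:
        return dict(zip(self.universe, self.signed_rank.tolist()))

    def reindexed(self, universe: Sequence[str]) -> "ReferenceProfile":
        """Return a copy aligned to another ordering of the same probe set."""
        if set(universe) != set(self.universe):
            raise UniverseError(
                f"profile {self.treatment_id!r} universe differs from target"
            )
        lookup = self.rank_of()
        ranks = np.fromiter((lookup[p] for p in universe), dtype=np.int64, count=len(lookup))
        return ReferenceProfile(self.treatment_id, tuple(universe), ranks)


@dataclass
class ReferenceSet:
    """All replicate profiles of one compound, over a common universe."""

    compound: str
    profiles: list[ReferenceProfile]
    _rank_matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.profiles:
            raise IntegrityError(f"reference set {self.compound!r} has no profiles")
        u0 = self.profiles[0].universe
        for prof in self.profiles[1:]:
            if prof.universe != u0:
                raise UniverseError(
                    f"set {self.compound!r}: profiles do not share a universe"
                )

    @property
    def n_replicates(self) -> int:
        return len(self.profiles)

    @property
    def universe(self) -> tuple[str, ...]:
        return self.profiles[0].universe

    def rank_matrix(self) -> np.ndarray:
        """Stacked signed ranks, shape (n_replicates, N_ref). Cached."""
        if self._rank_matrix is None:
            self._rank_matrix = np.vstack([p.signed_rank for p in self.profiles]).astype(float)
        return self._rank_matrix


@dataclass
class ReferenceDatabase:
    """A collection of reference sets sharing one probe universe."""

    sets: list[ReferenceSet]
    probe_universe: tuple[str, ...]

    def __post_init__(self) -> None:
        self.probe_universe = tuple(self.probe_universe)
        names = [s.compound for s in self.sets]
        if len(set(names)) != len(names):
            raise IntegrityError(f"duplicate compound names: {sorted(_duplicates(names))[:5]}")
        aligned = []
        for s in self.sets:
            if s.universe != self.probe_universe:
                s = ReferenceSet(s.compound, [p.reindexed(self.probe_universe) for p in s.profiles])
            aligned.append(s)
        self.sets = aligned

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_ref(self) -> int:
        return len(self.probe_universe)

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_universe)}

    def set_for(self, compound: str) -> ReferenceSet:
        for s in self.sets:
            if s.compound == compound:
                return s
        raise KeyError(compound)


def read_reference_database(directory: str | os.PathLike) -> ReferenceDatabase:
    """Read a reference database directory (manifest + per-profile tables)."""
    directory = os.fspath(directory)
    manifest_path = os.path.join(directory, "manifest.tsv")
    man = pd.read_csv(manifest_path, sep="\t", comment="#", dtype=str)
    if not {"compound", "profile_file"}.issubset(man.columns):
        raise ParseError("manifest must have columns compound, profile_file")
    universe: tuple[str, ...] | None = None
    sets: list[ReferenceSet] = []
    for compound, group in man.groupby("compound", sort=False):
        profiles = []
        for fname in group["profile_file"]:
            tab = pd.read_csv(os.path.join(directory, fname), sep="\t", comment="#", dtype=str)
            if not {"probe_id", "signed_rank"}.issubset(tab.columns):
                raise ParseError(f"{fname}: expected columns probe_id, signed_rank")
            probes = tuple(str(p) for p in tab["probe_id"])
            ranks = pd.to_numeric(tab["signed_rank"], errors="coerce")
            if ranks.isna().any():
                i = int(np.flatnonzero(ranks.isna().to_numpy())[0])
                raise ParseError(f"{fname}: non-integer signed rank at probe {probes[i]!r}")
            prof = ReferenceProfile(str(fname), probes, ranks.to_numpy(dtype=np.int64))
            if universe is None:
                universe = probes
            elif set(probes) != set(universe):
                raise UniverseError(f"{fname}: probe universe differs from the rest of the database")
            profiles.append(prof.reindexed(universe))
        sets.append(ReferenceSet(str(compound), profiles))
    if universe is None:
        raise ParseError("manifest lists no profiles")
    return ReferenceDatabase(sets, universe)


def write_reference_database(db: ReferenceDatabase, directory: str | os.PathLike) -> None:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for s in db.sets:
        for r, prof in enumerate(s.profiles):
            fname = f"{_slug(s.compound)}_rep{r + 1}.tsv"
            rows.append({"compound": s.compound, "profile_file": fname})
            pd.DataFrame(
                {"probe_id": db.probe_universe, "signed_rank": prof.signed_rank}
            ).to_csv(os.path.join(directory, fname), sep="\t", index=False)
    pd.DataFrame(rows).to_csv(os.path.join(directory, "manifest.tsv"), sep="\t", index=False)


def profile_from_log_ratios(treatment_id: str, log_ratio: Mapping[str, float]) -> ReferenceProfile:
    """Build a signed-rank profile from per-probe log expression ratios.

    The probe with the j-th largest ``|log_ratio|`` receives signed rank
    ``sign(log_ratio) * (N_ref - j + 1)``. Ties in magnitude are broken by
    probe identifier (lexicographically earlier probe ranks higher); a zero
    log ratio is assigned sign +1 and noted in the log.
    """
    if not log_ratio:
        raise UniverseError("empty probe universe")
    probes = sorted(log_ratio, key=lambda p: (-abs(log_ratio[p]), p))
    n = len(probes)
    n_zero = sum(1 for v in log_ratio.values() if v == 0)
    if n_zero:
        logger.info("profile %s: %d zero log-ratios assigned sign +1", treatment_id, n_zero)
    ranks = {p: (n - j) * (1 if log_ratio[p] >= 0 else -1) for j, p in enumerate(probes)}
    universe = tuple(log_ratio)
    signed = np.fromiter((ranks[p] for p in universe), dtype=np.int64, count=n)
    return ReferenceProfile(treatment_id, universe, signed)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for it in items:
        if it in seen:
            dupes.add(it)
        seen.add(it)
    return dupes


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in name)
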