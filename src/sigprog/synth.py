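"""Synthetic paired expression matrices and reference databases.

Every stage of the pipeline can be exercised without any external download:

* :func:`generate_paired_expression` emulates a paired tumour/normal
  microarray study on the log2 scale — per-probe baselines, additive
  normal noise within pairs, and a planted subset of differentially
  expressed probes shifted up or down by a fixed effect size.
* :func:`generate_reference_db` emulates a drug-profile reference
  database — unplanted compounds are independent uniform signed-rank
  permutations; planted compounds carry a chosen gene set near the top of
  the ranking with chosen signs, at a tunable planting strength.
* :func:`hdaci_style_fixture` wires the two together in the shape of a
  drug-class recovery experiment: several compounds share a planted
  "theme", a signature is built from a subset of them, and the held-out
  members should be recovered as significant connections.

Both generators return a truth table alongside the data so that recovery
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ConfigError,
    ExpressionMatrix,
    ReferenceDatabase,
    ReferenceProfile,
    ReferenceSet,
    logger,
)

CONCORDANT = "concordant"
ANTI = "anti"


def probe_names(n: int) -> list[str]:
    """Canonical probe naming shared by both generators.

    Using the same names for the expression matrix and the reference
    database makes the two directly queryable against each other.
    """
    return [f"P{i:05d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# paired expression matrices
# ---------------------------------------------------------------------------


@dataclass
class SynthExpressionSpec:
    """Shape and noise model of a synthetic paired expression study.

    Defaults describe a well-powered two-fold-change study on the log2
    scale: 2000 probes, 30 tumour/normal pairs, 100 planted DEGs shifted
    by 2 log2 units (half up, half down), probe baselines around 8 +- 1
    and a within-pair residual standard deviation of 0.3.
    """

    n_probes: int = 2000
    n_pairs: int = 30
    n_deg: int = 100
    effect_size: float = 2.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_deg > self.n_probes:
            raise ConfigError("n_deg cannot exceed n_probes")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")
        if self.n_pairs < 3:
            raise ConfigError("need at least 3 pairs")


def generate_paired_expression(spec: SynthExpressionSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a paired log2 expression matrix with planted DEGs.

    Control values are the per-probe baseline plus noise; treatment values
    are the paired control value plus the planted shift (for DEG probes)
    plus independent noise. Returns the matrix and a truth table with
    columns ``probe_id``, ``is_deg``, ``direction``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xE5]))
    probes = probe_names(spec.n_probes)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_probes)

    deg_idx = rng.choice(spec.n_probes, size=spec.n_deg, replace=False)
    direction = np.zeros(spec.n_probes, dtype=np.int64)
    n_up = spec.n_deg // 2
    direction[deg_idx[:n_up]] = 1
    direction[deg_idx[n_up:]] = -1

    shape = (spec.n_probes, spec.n_pairs)
    ctrl = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=shape)
    trt = ctrl + spec.effect_size * direction[:, None] + rng.normal(0.0, spec.noise_sd, size=shape)

    values = np.empty((spec.n_probes, 2 * spec.n_pairs))
    sample_ids, condition, pair_id = [], [], []
    for j in range(spec.n_pairs):
        values[:, 2 * j] = ctrl[:, j]
        values[:, 2 * j + 1] = trt[:, j]
        sample_ids += [f"S{j + 1:03d}C", f"S{j + 1:03d}T"]
        condition += ["control", "treatment"]
        pair_id += [f"pair{j + 1:03d}"] * 2

    em = ExpressionMatrix(probes, sample_ids, values, condition, pair_id)
    truth = pd.DataFrame(
        {"probe_id": probes, "is_deg": direction != 0, "direction": direction}
    )
    return em, truth


# ---------------------------------------------------------------------------
# reference databases
# ---------------------------------------------------------------------------


@dataclass
class PlantedCompound:
    """A compound whose profiles carry a planted gene theme.

    ``genes``/``signs`` define the theme (the regulation pattern the
    compound induces); ``direction`` is ``"concordant"`` (profiles carry
    the theme signs) or ``"anti"`` (flipped); ``strength`` in (0, 1]
    controls how tightly the theme genes are packed at the top of the
    ranking — at 1 they occupy exactly the top |theme| absolute ranks, at
    lower values they are spread over a proportionally wider top band.
    """

    compound: str
    genes: list[str]
    signs: list[int]
    direction: str = CONCORDANT
    strength: float = 1.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.signs):
            raise ConfigError("genes and signs must have equal length")
        if self.direction not in (CONCORDANT, ANTI):
            raise ConfigError(f"unknown direction {self.direction!r}")
        if not 0 < self.strength <= 1:
            raise ConfigError("strength must be in (0, 1]")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")


@dataclass
class SynthReferenceSpec:
    """Shape of a synthetic reference database.

    ``n_sets`` background compounds are pure noise (independent uniform
    signed-rank permutations, one per replicate); ``planted`` compounds
    additionally carry their theme as described in
    :class:`PlantedCompound`.
    """

    n_probes: int = 500
    n_sets: int = 20
    replicates: int = 1
    planted: list[PlantedCompound] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.n_sets < 0 or self.replicates < 1:
            raise ConfigError("invalid database shape")


def _random_profile(name: str, universe: tuple[str, ...], rng: np.random.Generator) -> ReferenceProfile:
    n = len(universe)
    mags = rng.permutation(n) + 1
    signs = rng.integers(0, 2, size=n) * 2 - 1
    return ReferenceProfile(name, universe, mags * signs)


def _planted_profile(name: str, universe: tuple[str, ...], pc: PlantedCompound,
                     rng: np.random.Generator) -> ReferenceProfile:
    n = len(universe)
    index = {p: i for i, p in enumerate(universe)}
    gene_idx = np.array([index[g] for g in pc.genes], dtype=np.intp)
    g = len(gene_idx)
    if g > n:
        raise ConfigError("planted gene set larger than the universe")
    # top band shrinks to exactly the theme size as strength -> 1
    band = g + int(round((1.0 - pc.strength) * (n - g)))
    top_mags = rng.choice(np.arange(n - band + 1, n + 1), size=g, replace=False)
    flip = 1 if pc.direction == CONCORDANT else -1
    signed = np.zeros(n, dtype=np.int64)
    signed[gene_idx] = top_mags * (flip * np.asarray(pc.signs, dtype=np.int64))
    rest_idx = np.setdiff1d(np.arange(n), gene_idx)
    rest_mags = np.setdiff1d(np.arange(1, n + 1), top_mags)
    rest_mags = rng.permutation(rest_mags)
    rest_signs = rng.integers(0, 2, size=rest_idx.size) * 2 - 1
    signed[rest_idx] = rest_mags * rest_signs
    return ReferenceProfile(name, universe, signed)


def generate_reference_db(spec: SynthReferenceSpec) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Generate a reference database with optional planted compounds.

    Returns the database and a truth table with columns ``compound``,
    ``planted``, ``direction``, ``strength``, ``n_replicates``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xDB]))
    universe = tuple(probe_names(spec.n_probes))

    overlap: dict[str, list[str]] = {}
    for pc in spec.planted:
        for gene in pc.genes:
            overlap.setdefault(gene, []).append(pc.compound)
            if gene not in set(universe):
                raise ConfigError(f"planted gene {gene!r} is not in the universe")
    shared = {g: c for g, c in overlap.items() if len(c) > 1}
    if shared:
        logger.info("planted gene sets overlap across %d genes (allowed)", len(shared))

    sets, rows = [], []
    for pc in spec.planted:
        profiles = [
            _planted_profile(f"{pc.compound}_rep{r + 1}", universe, pc, rng)
            for r in range(pc.n_replicates)
        ]
        sets.append(ReferenceSet(pc.compound, profiles))
        rows.append({"compound": pc.compound, "planted": True, "direction": pc.direction,
                     "strength": pc.strength, "n_replicates": pc.n_replicates})
    for i in range(spec.n_sets):
        name = f"background_{i + 1:03d}"
        profiles = [
            _random_profile(f"{name}_rep{r + 1}", universe, rng)
            for r in range(spec.replicates)
        ]
        sets.append(ReferenceSet(name, profiles))
        rows.append({"compound": name, "planted": False, "direction": "",
                     "strength": 0.0, "n_replicates": spec.replicates})
    db = ReferenceDatabase(sets, universe)
    return db, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# drug-class recovery fixture
# ---------------------------------------------------------------------------


@dataclass
class ClassRecoveryFixture:
    """A database staged for a drug-class signature recovery experiment."""

    db: ReferenceDatabase
    input_compounds: list[str]
    held_out_compounds: list[str]
    background_compounds: list[str]
    theme_genes: list[str]
    theme_signs: list[int]
    truth: pd.DataFrame

    @property
    def theme_compounds(self) -> list[str]:
        return self.input_compounds + self.held_out_compounds


def hdaci_style_fixture(seed: int = 0, n_probes: int = 600, theme_size: int = 60,
                        n_background: int = 100, strength: float = 0.95,
                        input_replicates: tuple[int, ...] = (1, 7, 3, 2),
                        held_out_replicates: tuple[int, ...] = (12, 18, 6),
                        ) -> ClassRecoveryFixture:
    """A seven-compound drug-class database for end-to-end recovery runs.

    Seven compounds share one planted gene theme: four "input" compounds
    (with small replicate counts, from which a class signature is to be
    built) and three "held-out" compounds (which a successful run should
    recover as significant without having contributed to the signature),
    on top of pure-noise background compounds. The replicate counts echo
    a class with a few lightly-replicated members and a few heavily
    profiled ones.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4D]))
    universe = probe_names(n_probes)
    theme_idx = rng.choice(n_probes, size=theme_size, replace=False)
    theme_genes = [universe[i] for i in np.sort(theme_idx)]
    theme_signs = (rng.integers(0, 2, size=theme_size) * 2 - 1).tolist()

    planted = [
        PlantedCompound(f"theme_input_{i + 1}", theme_genes, theme_signs,
                        CONCORDANT, strength, reps)
        for i, reps in enumerate(input_replicates)
    ] + [
        PlantedCompound(f"theme_heldout_{i + 1}", theme_genes, theme_signs,
                        CONCORDANT, strength, reps)
        for i, reps in enumerate(held_out_replicates)
    ]
    spec = SynthReferenceSpec(n_probes=n_probes, n_sets=n_background, replicates=1,
                              planted=planted, seed=seed)
    db, truth = generate_reference_db(spec)
    return ClassRecoveryFixture(
        db=db,
        input_compounds=[f"theme_input_{i + 1}" for i in range(len(input_replicates))],
        held_out_compounds=[f"theme_heldout_{i + 1}" for i in range(len(held_out_replicates))],
        background_compounds=[f"background_{i + 1:03d}" for i in range(n_background)],
        theme_genes=theme_genes,
        theme_signs=theme_signs,
        truth=truth,
    )
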