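"""Stage 2b: the gene signature progression loop.

Given a full ranked DEG list of length ``n``, signatures of increasing
length ``k`` are sliced off the top and queried against the reference
database. At each ``k`` the number of significant connections ``N_p``
yields an empirical false discovery rate ``eFDR = N_fp / N_p``, where
``N_fp`` is the number of false connections expected under the
per-compound significance threshold ``N_fp / N_sets``. The loop stops at
the first ``k`` whose eFDR is at or below the target ``alpha``; that ``k``
is the optimal (minimum sufficient) signature length. If no ``k`` reaches
the target, the ``k`` with the smallest eFDR (earliest on ties) is
reported instead, flagged as not achieved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ConnectionResult, ScoringConfig, perturbation_stability, query_database
from .io import ConfigError, FLOAT_FMT, ReferenceDatabase, SigprogError
from .signature import QuerySignature, slice_signature


@dataclass
class ProgressionConfig:
    """Loop parameters.

    ``alpha`` is the target empirical FDR (default 0.1); ``k_start``,
    ``k_step`` and ``k_max`` bound the lengths examined (``k_max=None``
    means the full list). ``n_fp`` is the number of tolerated false
    connections per query, used both in the per-compound threshold and the
    eFDR numerator. When ``k_step > 1`` and the target is met, the loop
    steps back and rescans with step 1 so the reported optimum is exact.
    """

    alpha: float = 0.1
    k_start: int = 1
    k_step: int = 1
    k_max: int | None = None
    n_fp: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.k_start < 1 or self.k_step < 1:
            raise ConfigError("k_start and k_step must be >= 1")
        if self.n_fp <= 0:
            raise ConfigError("n_fp must be positive")


@dataclass
class ProgressionRecord:
    k: int
    n_p: int
    efdr: float
    significant_compounds: list[str]
    undefined: bool = False  # no significant connection at this k


@dataclass
class ProgressionResult:
    trace: list[ProgressionRecord] = field(default_factory=list)
    k_optimal: int = 0
    achieved: bool = False
    final_results: list[ConnectionResult] = field(default_factory=list)


def empirical_fdr(n_fp: float, n_p: int) -> tuple[float, bool]:
    """eFDR = min(1, n_fp / n_p); (1, flagged) when there are no connections.

    Examples: 1 tolerated false connection among 7 significant compounds
    gives 1/7 ~ 0.14; among 6313 significant probes, 1/6313 ~ 1.6e-4.
    """
    if n_fp <= 0:
        raise ConfigError("n_fp must be positive")
    if n_p < 0:
        raise ConfigError("n_p must be non-negative")
    if n_p == 0:
        return 1.0, True
    return min(1.0, n_fp / n_p), False


def run_progression(full_sig: QuerySignature, db: ReferenceDatabase,
                    scfg: ScoringConfig, pcfg: ProgressionConfig | None = None,
                    with_ps: bool = False) -> ProgressionResult:
    """Iterate signature lengths until the target eFDR is reached.

    The permutation-null cache is shared across the whole run (nulls are
    length-specific, so sharing only saves recomputation at a revisited
    ``k``, e.g. in the final re-query). With ``with_ps=True`` the
    leave-one-out perturbation stability is filled in for the significant
    compounds of the final result table.
    """
    pcfg = pcfg or ProgressionConfig()
    n = full_sig.m
    if n == 0:
        raise SigprogError("full signature is empty")
    scfg = ScoringConfig(scfg.mode, scfg.n_perm, scfg.sidedness, scfg.rng_seed, pcfg.n_fp)
    k_max = min(pcfg.k_max, n) if pcfg.k_max is not None else n
    cache: dict = {}
    trace: list[ProgressionRecord] = []

    def evaluate(k: int) -> ProgressionRecord:
        results = query_database(slice_signature(full_sig, k), db, scfg, cache)
        sig_compounds = [r.compound for r in results if r.sm == 1]
        efdr, undefined = empirical_fdr(pcfg.n_fp, len(sig_compounds))
        rec = ProgressionRecord(k, len(sig_compounds), efdr, sig_compounds, undefined)
        trace.append(rec)
        return rec

    k_break: int | None = None
    prev_k = None
    for k in range(pcfg.k_start, k_max + 1, pcfg.k_step):
        rec = evaluate(k)
        if not rec.undefined and rec.efdr <= pcfg.alpha:
            k_break = k
            break
        prev_k = k

    if k_break is not None and pcfg.k_step > 1 and prev_k is not None:
        # refine: the true minimum may lie strictly between prev_k and k_break
        for k in range(prev_k + 1, k_break):
            rec = evaluate(k)
            if not rec.undefined and rec.efdr <= pcfg.alpha:
                k_break = k
                break

    if k_break is not None:
        k_optimal, achieved = k_break, True
    else:
        achieved = False
        best = min(trace, key=lambda r: (r.efdr, r.k))
        k_optimal = best.k

    final = query_database(slice_signature(full_sig, k_optimal), db, scfg, cache)
    if with_ps:
        threshold_sets = db.n_sets
        final_sig = slice_signature(full_sig, k_optimal)
        for r in final:
            if r.sm == 1:
                r.ps = perturbation_stability(final_sig, db.set_for(r.compound),
                                              threshold_sets, scfg, cache)
    return ProgressionResult(trace, k_optimal, achieved, final)


# ---------------------------------------------------------------------------
# trace output and the progression snapshot figure
# ---------------------------------------------------------------------------


def trace_to_frame(result: ProgressionResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "k": r.k,
                "N_p": r.n_p,
                "eFDR": r.efdr,
                "undefined": int(r.undefined),
                "significant_compounds": ",".join(r.significant_compounds),
            }
            for r in sorted(result.trace, key=lambda r: r.k)
        ]
    )


def write_trace(result: ProgressionResult, path) -> None:
    trace_to_frame(result).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def plot_connections(results: list[ConnectionResult], threshold: float, path,
                     title: str = "") -> None:
    """Scatter of -log10 p per compound with the significance threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.array([r.p_value for r in results])
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(np.arange(len(results)), -np.log10(p), s=12,
               c=["tab:red" if r.sm else "tab:gray" for r in results])
    ax.axhline(-np.log10(threshold), color="k", linestyle="--", linewidth=1,
               label=f"threshold p = {threshold:.2e}")
    ax.set_xlabel("compound (sorted by z-score)")
    ax.set_ylabel("-log10 p")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
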